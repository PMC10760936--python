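"""Cassette insertion-site inference from read-pair alignments.

A cassette insertion produces discordant read pairs with one mate on the
cassette sequence and the other on the genome; the genome-side positions
pile up on both flanks of the insertion point.  Junction positions are
clustered per chromosome by average-linkage hierarchical clustering with a
flat cut at 3000 bp.  A cluster supports a real insertion when it has at
least four reads, reads from both sides of the insertion point, and
(nearly) no concordant genome pairs spanning the consensus position -- the
cassette is far longer than the sequenced fragments, so a real insertion
cannot be spanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fclusterdata

__all__ = [
    "MappingParams",
    "read_sam_records",
    "extract_junctions",
    "cluster_junctions",
    "count_spanning_pairs",
    "assess_insertion",
    "validate_insertions",
]

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

RECORD_COLUMNS = ["query", "flag", "ref", "pos", "mate_ref", "mate_pos", "tlen"]


@dataclass
class MappingParams:
    """Clustering and verdict thresholds.

    ``span_tolerance``: concordant pairs spanning the breakpoint a validated
    cluster may tolerate (sequencing chimeras happen).  ``span_heavy``:
    spanning count at or above which a two-sided cluster is called
    unsupported outright; counts in between are ambiguous and left for
    manual review.  ``read_length`` offsets the breakpoint estimate of
    one-sided clusters (reads stop one read length short of the junction).
    """

    cluster_cutoff: float = 3000.0
    min_cluster_reads: int = 4
    span_tolerance: int = 2
    span_heavy: int = 10
    read_length: int = 150

    def __post_init__(self) -> None:
        if self.cluster_cutoff <= 0:
            raise ValueError("cluster_cutoff must be positive")


def read_sam_records(path: str | Path) -> pd.DataFrame:
    """Load alignment records from a SAM/BAM file into the tabular schema.

    Columns: ``query``, ``flag``, ``ref``, ``pos`` (1-based), ``mate_ref``,
    ``mate_pos`` (1-based), ``tlen``.  Unmapped mates get ``mate_ref`` None.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            rows.append(
                {
                    "query": aln.query_name,
                    "flag": aln.flag,
                    "ref": aln.reference_name,
                    "pos": aln.reference_start + 1,
                    "mate_ref": aln.next_reference_name,
                    "mate_pos": (aln.next_reference_start + 1)
                    if aln.next_reference_id >= 0
                    else None,
                    "tlen": aln.template_length,
                }
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def extract_junctions(records: pd.DataFrame, cassette_ref: str) -> pd.DataFrame:
    """Genome-side junction positions from cassette-discordant primary pairs.

    Keeps primary, paired, non-proper records aligned to the genome whose
    mate maps to the cassette reference.  The junction position is the
    record's own position; ``side`` is 'left' when the genome read is on the
    forward strand (pointing rightwards into the insertion) and 'right'
    otherwise.  Records with missing mate information are skipped; their
    count is stored in ``result.attrs['n_skipped']``.
    """
    rec = records.copy()
    missing = rec["mate_ref"].isna() | (rec["mate_ref"] == "*")
    n_skipped = int(missing.sum())
    rec = rec[~missing]
    flag = rec["flag"].astype(int)
    primary = (flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)) == 0
    discordant = ((flag & FLAG_PAIRED) != 0) & ((flag & FLAG_PROPER) == 0)
    junction = (
        primary & discordant
        & (rec["ref"] != cassette_ref)
        & (rec["mate_ref"] == cassette_ref)
    )
    out = rec.loc[junction, ["query", "ref", "pos", "flag"]].copy()
    out["side"] = np.where(out["flag"].astype(int) & FLAG_REVERSE, "right", "left")
    out = out.rename(columns={"ref": "chrom"}).drop(columns="flag")
    out = out.reset_index(drop=True)
    out.attrs["n_skipped"] = n_skipped
    return out


def cluster_junctions(
    junctions: pd.DataFrame, params: MappingParams | None = None
) -> pd.DataFrame:
    """Cluster junction positions per chromosome (average linkage, flat cut).

    Returns one row per cluster: ``cluster``, ``chrom``, ``support``,
    ``consensus`` (median member position), ``breakpoint`` (estimated
    insertion point: midpoint of the innermost left/right reads for
    two-sided clusters, one read length past the innermost read otherwise),
    ``sides`` (set of flank labels), ``positions`` (sorted member
    positions).  Singletons are allowed.
    """
    params = params or MappingParams()
    rows = []
    cluster_id = 0
    for chrom, grp in junctions.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(dtype=float)
        if len(pos) == 1:
            labels = np.array([1])
        else:
            labels = fclusterdata(
                pos.reshape(-1, 1),
                t=params.cluster_cutoff,
                criterion="distance",
                method="average",
            )
        for lab in np.unique(labels):
            members = grp.iloc[np.flatnonzero(labels == lab)]
            cluster_id += 1
            sides = frozenset(members["side"])
            left = members.loc[members["side"] == "left", "pos"]
            right = members.loc[members["side"] == "right", "pos"]
            if len(left) and len(right):
                breakpoint_ = (left.max() + right.min()) / 2.0
            elif len(left):
                breakpoint_ = float(left.max()) + params.read_length
            else:
                breakpoint_ = float(right.min()) - params.read_length
            rows.append(
                {
                    "cluster": cluster_id,
                    "chrom": chrom,
                    "support": len(members),
                    "consensus": float(np.median(members["pos"])),
                    "breakpoint": float(breakpoint_),
                    "sides": sides,
                    "positions": tuple(sorted(members["pos"])),
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster", "chrom", "support", "consensus",
                       "breakpoint", "sides", "positions"],
    )


def count_spanning_pairs(
    records: pd.DataFrame, chrom: str, position: float, cassette_ref: str
) -> int:
    """Concordant genome pairs whose fragment spans a genomic position.

    Each pair is counted once via its leftmost record (positive template
    length); the fragment interval is [pos, pos + tlen - 1].
    """
    rec = records
    flag = rec["flag"].astype(int)
    concordant = (
        ((flag & FLAG_PROPER) != 0)
        & ((flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)) == 0)
        & (rec["ref"] == chrom)
        & (rec["ref"] != cassette_ref)
        & (rec["tlen"] > 0)
    )
    sub = rec[concordant]
    start = sub["pos"].astype(float)
    end = start + sub["tlen"].astype(float) - 1
    return int(((start < position) & (end > position)).sum())


def assess_insertion(
    cluster: pd.Series, n_spanning: int, params: MappingParams | None = None
) -> str:
    """Verdict for one junction cluster: validated / unsupported / ambiguous.

    Validated: reads from both sides and spanning pairs within tolerance.
    Unsupported: one-sided, or heavily spanned (>= ``span_heavy``).
    Ambiguous: both sides but an intermediate spanning count.
    """
    params = params or MappingParams()
    both_sides = {"left", "right"} <= set(cluster["sides"])
    if not both_sides or n_spanning >= params.span_heavy:
        return "unsupported"
    if n_spanning <= params.span_tolerance:
        return "validated"
    return "ambiguous"


def validate_insertions(
    records: pd.DataFrame,
    cassette_ref: str,
    params: MappingParams | None = None,
) -> pd.DataFrame:
    """Full pipeline: extract junctions, cluster, count spanning, assess.

    Clusters with fewer than ``min_cluster_reads`` members are dropped
    before assessment, mirroring the minimum-read rule.  Returns the cluster
    table with ``n_spanning`` and ``verdict`` columns.
    """
    params = params or MappingParams()
    junctions = extract_junctions(records, cassette_ref)
    clusters = cluster_junctions(junctions, params)
    clusters = clusters[clusters["support"] >= params.min_cluster_reads].copy()
    spanning = []
    verdicts = []
    for _, cl in clusters.iterrows():
        n_span = count_spanning_pairs(records, cl["chrom"], cl["breakpoint"],
                                      cassette_ref)
        spanning.append(n_span)
        verdicts.append(assess_insertion(cl, n_span, params))
    clusters["n_spanning"] = spanning
    clusters["verdict"] = verdicts
    return clusters.reset_index(drop=True)
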