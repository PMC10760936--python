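"""Chloroplast transcript quantification and psaA splice-form analysis.

psaA mRNA matures from separate precursor transcripts that hybridize to form
two group-II introns, which are excised in trans.  Paired-end read placement
is informative about splicing state: when the two mates of a pair lie fully
within adjacent exons (without intron coverage in between), the intervening
intron was spliced out; a mate pair bridging exon 1 and exon 3 comes from a
fully mature message; a mate lying in intron sequence marks an unspliced
precursor.  Mates spanning a splice junction, or pairs confined to a single
exon, are uninformative.

Per-gene expression uses each mate independently: a mate counts once toward
the gene containing its midpoint, non-coding RNA positions are excluded, and
per-gene counts are normalized by the sample's total chloroplast gene reads.
Nuclear expression ratios normalize samples to 50 million reads and compare
geometric means of replicates on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ChloroplastAnnotation",
    "InsertModel",
    "SplicePairCounts",
    "CATEGORIES",
    "MOLECULES",
    "classify_psaA_pairs",
    "count_chloroplast_genes",
    "molecule_positions",
    "category_probabilities",
    "estimate_splice_fractions",
    "relative_and_rescale",
    "nuclear_expression_ratio",
]

#: Per-pair evidence categories.
CATEGORIES = ("intron1_spliced", "intron2_spliced", "mature", "precursor",
              "uninformative")

#: Molecule (splice-form) types for the generative model and the estimator.
MOLECULES = ("precursor", "intron1_only", "intron2_only", "mature")


@dataclass
class ChloroplastAnnotation:
    """Chloroplast gene/exon annotation, 1-based inclusive coordinates.

    ``genes``: DataFrame indexed by gene id with ``start``, ``end``,
    ``kind`` ('gene' or 'ncRNA').  ``exons``: the three psaA exon intervals
    in transcript order; ``introns``: the two intron intervals.
    """

    genes: pd.DataFrame
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.exons) != 3 or len(self.introns) != 2:
            raise ValueError("expected 3 psaA exons and 2 introns")
        spans = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("psaA exons must not overlap")

    @property
    def coding_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["kind"] == "gene"]

    @property
    def ncrna(self) -> pd.DataFrame:
        return self.genes[self.genes["kind"] == "ncRNA"]

    @classmethod
    def from_gff3(cls, path: str | Path, psaA_gene: str = "psaA"
                  ) -> "ChloroplastAnnotation":
        """Load from a GFF3 file (gene / ncRNA_gene features; psaA exons)."""
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
        rows = {}
        for feat in db.all_features():
            if feat.featuretype in ("gene", "ncRNA_gene"):
                gid = feat.attributes.get("ID", [feat.id])[0]
                rows[gid] = {
                    "start": feat.start, "end": feat.end,
                    "kind": "ncRNA" if feat.featuretype == "ncRNA_gene" else "gene",
                }
        genes = pd.DataFrame.from_dict(rows, orient="index")
        genes.index.name = "gene"
        exons = sorted(
            (f.start, f.end)
            for f in db.all_features(featuretype="exon")
            if psaA_gene in (f.attributes.get("Parent", []) + f.attributes.get("gene", []))
        )
        if len(exons) != 3:
            raise ValueError(f"expected 3 exons for {psaA_gene}, got {len(exons)}")
        introns = tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])
        )
        return cls(genes=genes, exons=tuple(exons), introns=introns)

    def to_gff3(self, path: str | Path, seqid: str = "chloroplast") -> None:
        lines = ["##gff-version 3"]
        for gid, row in self.genes.iterrows():
            ftype = "ncRNA_gene" if row["kind"] == "ncRNA" else "gene"
            lines.append(
                f"{seqid}\tphotoscreen\t{ftype}\t{row['start']}\t{row['end']}"
                f"\t.\t+\t.\tID={gid}"
            )
        for i, (s, e) in enumerate(self.exons, start=1):
            lines.append(
                f"{seqid}\tphotoscreen\texon\t{s}\t{e}\t.\t+\t.\t"
                f"ID=psaA.exon{i};Parent=psaA"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class InsertModel:
    """Discrete fragment-length model: round(N(mean, sd)) clipped to bounds.

    The lower bound is twice the read length (mates do not overlap past each
    other); the upper bound is mean + 4 sd.
    """

    read_len: int = 75
    mean: float = 350.0
    sd: float = 60.0

    @property
    def l_min(self) -> int:
        return 2 * self.read_len

    @property
    def l_max(self) -> int:
        return int(round(self.mean + 4 * self.sd))

    def length_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Support and probabilities of the clipped, rounded length draw."""
        ls = np.arange(self.l_min, self.l_max + 1)
        upper = stats.norm.cdf(ls + 0.5, self.mean, self.sd)
        lower = stats.norm.cdf(ls - 0.5, self.mean, self.sd)
        pmf = upper - lower
        pmf[0] = stats.norm.cdf(self.l_min + 0.5, self.mean, self.sd)
        pmf[-1] = 1.0 - stats.norm.cdf(self.l_max - 0.5, self.mean, self.sd)
        return ls, pmf / pmf.sum()


def _mate_exon(gs: np.ndarray, ge: np.ndarray, spliced: np.ndarray,
               ann: ChloroplastAnnotation) -> np.ndarray:
    """Exon index (1..3) of each fully-contained unspliced mate, else 0."""
    out = np.zeros(gs.shape, dtype=int)
    for k, (s, e) in enumerate(ann.exons, start=1):
        inside = (~spliced) & (gs >= s) & (ge <= e)
        out[inside] = k
    return out


def _mate_in_intron(gs: np.ndarray, ge: np.ndarray, spliced: np.ndarray,
                    ann: ChloroplastAnnotation) -> np.ndarray:
    out = np.zeros(gs.shape, dtype=bool)
    for s, e in ann.introns:
        out |= (~spliced) & (gs <= e) & (ge >= s)
    return out


def _classify_arrays(gs1, ge1, sp1, gs2, ge2, sp2,
                     ann: ChloroplastAnnotation) -> np.ndarray:
    """Vectorized pair classification; returns category label array."""
    gs1, ge1, gs2, ge2 = (np.asarray(a, dtype=float) for a in (gs1, ge1, gs2, ge2))
    sp1 = np.asarray(sp1, dtype=bool)
    sp2 = np.asarray(sp2, dtype=bool)
    out = np.full(gs1.shape, "uninformative", dtype=object)

    in_intron = _mate_in_intron(gs1, ge1, sp1, ann) | _mate_in_intron(
        gs2, ge2, sp2, ann
    )
    ex1 = _mate_exon(gs1.astype(int), ge1.astype(int), sp1, ann)
    ex2 = _mate_exon(gs2.astype(int), ge2.astype(int), sp2, ann)
    lo = np.minimum(ex1, ex2)
    hi = np.maximum(ex1, ex2)
    both = (ex1 > 0) & (ex2 > 0)
    out[both & (lo == 1) & (hi == 2)] = "intron1_spliced"
    out[both & (lo == 2) & (hi == 3)] = "intron2_spliced"
    out[both & (lo == 1) & (hi == 3)] = "mature"
    out[in_intron] = "precursor"  # intron coverage overrides exon evidence
    return out


@dataclass
class SplicePairCounts:
    """Per-pair classification summary for a trans-spliced gene."""

    counts: pd.Series
    labels: pd.Series = field(repr=False)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def informative(self) -> pd.Series:
        """Counts of the four evidence categories (excluding uninformative)."""
        return self.counts.drop(["uninformative", "unplaced"], errors="ignore")


def classify_psaA_pairs(
    placements: pd.DataFrame, ann: ChloroplastAnnotation
) -> SplicePairCounts:
    """Classify paired-end placements over the psaA locus.

    ``placements`` columns: ``m1_start``, ``m1_end``, ``m1_spliced``,
    ``m2_start``, ``m2_end``, ``m2_spliced`` (1-based inclusive; ``spliced``
    marks mates whose alignment has a gap, i.e. junction-spanning reads).
    Rows with missing coordinates are counted as ``unplaced``.
    """
    ok = placements[["m1_start", "m1_end", "m2_start", "m2_end"]].notna().all(axis=1)
    labels = pd.Series("unplaced", index=placements.index, dtype=object)
    sub = placements[ok]
    if len(sub):
        labels.loc[ok] = _classify_arrays(
            sub["m1_start"], sub["m1_end"], sub.get("m1_spliced", False),
            sub["m2_start"], sub["m2_end"], sub.get("m2_spliced", False),
            ann,
        )
    order = list(CATEGORIES) + ["unplaced"]
    counts = labels.value_counts().reindex(order, fill_value=0)
    return SplicePairCounts(counts=counts, labels=labels)


def count_chloroplast_genes(
    placements: pd.DataFrame, ann: ChloroplastAnnotation
) -> pd.Series:
    """Normalized per-gene read counts, each mate counted separately.

    A mate counts toward the coding gene containing its midpoint; mates
    overlapping annotated non-coding RNA are excluded, mates in no gene are
    tallied in ``result.attrs['n_uncounted']``.  Counts are divided by the
    sample's total chloroplast gene reads (so they sum to 1).
    """
    mids = []
    for m in ("m1", "m2"):
        sub = placements[[f"{m}_start", f"{m}_end"]].dropna()
        mids.append(((sub[f"{m}_start"] + sub[f"{m}_end"]) / 2).to_numpy())
    mid = np.concatenate(mids) if mids else np.array([])
    if mid.size == 0:
        raise ValueError("no chloroplast reads")

    nc = np.zeros(mid.shape, dtype=bool)
    for _, row in ann.ncrna.iterrows():
        nc = nc | ((mid >= row["start"]) & (mid <= row["end"]))
    mid = mid[~nc]

    genes = ann.coding_genes
    counts = pd.Series(0, index=genes.index, dtype=float)
    assigned = np.zeros(mid.shape, dtype=bool)
    for gid, row in genes.iterrows():
        inside = (mid >= row["start"]) & (mid <= row["end"])
        counts[gid] = int(inside.sum())
        assigned |= inside
    total = counts.sum()
    if total == 0:
        raise ValueError("no chloroplast reads")
    out = counts / total
    out.attrs["n_uncounted"] = int((~assigned).sum())
    out.attrs["total_reads"] = int(total)
    return out


def molecule_positions(ann: ChloroplastAnnotation, molecule: str) -> np.ndarray:
    """Genomic position of every molecule coordinate for a splice form.

    Requires introns to sit exactly between consecutive exons (the synthetic
    contiguous layout).
    """
    (e1s, e1e), (e2s, e2e), (e3s, e3e) = ann.exons
    (i1s, i1e), (i2s, i2e) = ann.introns
    if i1s != e1e + 1 or i1e != e2s - 1 or i2s != e2e + 1 or i2e != e3s - 1:
        raise ValueError("introns must be contiguous with exons")
    blocks = {
        "precursor": [(e1s, e3e)],
        "intron1_only": [(e1s, e1e), (e2s, e3e)],
        "intron2_only": [(e1s, e2e), (e3s, e3e)],
        "mature": [(e1s, e1e), (e2s, e2e), (e3s, e3e)],
    }
    if molecule not in blocks:
        raise ValueError(f"unknown molecule type {molecule!r}")
    return np.concatenate([np.arange(s, e + 1) for s, e in blocks[molecule]])


def category_probabilities(
    ann: ChloroplastAnnotation, model: InsertModel | None = None
) -> pd.DataFrame:
    """Exact P(category | molecule type) under the discrete insert model.

    Enumerates every (fragment length, start) placement on each splice form,
    weighting lengths by the insert-size pmf and starts uniformly.  Columns
    are molecule types, rows the pair categories.
    """
    model = model or InsertModel()
    ls, pmf = model.length_pmf()
    r = model.read_len
    cols = {}
    for mol in MOLECULES:
        gpos = molecule_positions(ann, mol)
        n = gpos.size
        acc = pd.Series(0.0, index=list(CATEGORIES))
        for L, w in zip(ls, pmf):
            if L > n:
                continue
            s = np.arange(0, n - L + 1)
            gs1, ge1 = gpos[s], gpos[s + r - 1]
            gs2, ge2 = gpos[s + L - r], gpos[s + L - 1]
            sp1 = (ge1 - gs1) != (r - 1)
            sp2 = (ge2 - gs2) != (r - 1)
            labels = _classify_arrays(gs1, ge1, sp1, gs2, ge2, sp2, ann)
            vc = pd.Series(labels).value_counts() / len(s)
            acc = acc.add(vc * w, fill_value=0.0)
        cols[mol] = acc / acc.sum()
    return pd.DataFrame(cols).loc[list(CATEGORIES)]


def estimate_splice_fractions(
    counts: pd.Series,
    ann: ChloroplastAnnotation,
    model: InsertModel | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Estimate splice-form fractions from pair-category counts.

    Solves the non-negative least-squares mixture ``M f = y`` where ``M`` is
    the exact category-probability matrix and ``y`` the observed category
    frequencies, then renormalizes ``f`` to sum to 1.  Returns the fraction
    estimates and their (delta-method) covariance.
    """
    model = model or InsertModel()
    m_df = category_probabilities(ann, model)
    y = counts.reindex(m_df.index, fill_value=0).astype(float)
    n = y.sum()
    if n == 0:
        raise ValueError("no classified pairs")
    y_freq = (y / n).to_numpy()
    m = m_df.to_numpy()
    f, _ = optimize.nnls(m, y_freq)
    f = f / f.sum()
    # delta method: cov(y_freq) = (diag(p) - p p^T)/n through the LS inverse
    a = np.linalg.pinv(m)
    sigma_y = (np.diag(y_freq) - np.outer(y_freq, y_freq)) / n
    cov = a @ sigma_y @ a.T
    return (
        pd.Series(f, index=m_df.columns),
        pd.DataFrame(cov, index=m_df.columns, columns=m_df.columns),
    )


def relative_and_rescale(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    wt_strain: str = "WT",
    reference_experiment: str | None = None,
    per_quantity: bool = True,
) -> dict[str, pd.DataFrame]:
    """Express quantities relative to wild type and pool experiments.

    ``values``: quantity x sample; ``meta``: sample-indexed with ``strain``
    and ``experiment``.  Each sample is divided by the mean of its
    experiment's wild-type samples, per quantity (wild-type zero masks that
    quantity).  For pooling absolute profiles across experiments of very
    different coverage, every experiment is additionally rescaled by the
    wild-type ratio to the reference experiment (default: the last one,
    typically the deepest), per quantity by default or by a single global
    factor otherwise.

    Returns ``{"wt_relative", "pooled", "scale_factors"}``.
    """
    experiments = sorted(meta["experiment"].unique())
    ref = reference_experiment or experiments[-1]
    if ref not in experiments:
        raise ValueError(f"unknown reference experiment {ref!r}")

    wt_mean = {}
    for exp in experiments:
        cols = meta.index[(meta["experiment"] == exp) & (meta["strain"] == wt_strain)]
        if len(cols) == 0:
            raise ValueError(f"no wild-type samples in experiment {exp!r}")
        wt_mean[exp] = values[list(cols)].mean(axis=1)

    rel = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    pooled = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    factors = {}
    for exp in experiments:
        denom = wt_mean[exp].replace(0, np.nan)
        factor = wt_mean[ref] / denom
        if not per_quantity:
            factor = pd.Series(factor.median(), index=factor.index)
        factors[exp] = factor
        cols = list(meta.index[meta["experiment"] == exp])
        cols = [c for c in cols if c in values.columns]
        rel[cols] = values[cols].div(denom, axis=0)
        pooled[cols] = values[cols].mul(factor, axis=0)
    return {
        "wt_relative": rel,
        "pooled": pooled,
        "scale_factors": pd.DataFrame(factors),
    }


def nuclear_expression_ratio(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    wt_strain: str = "WT",
    total: float = 50_000_000.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2(mutant / wild type) nuclear expression per transcript.

    Samples are normalized to ``total`` (50 M) reads; each strain's
    replicates are collapsed by geometric mean (zeros replaced by
    ``pseudocount`` first); ratios are log2 against the wild-type geometric
    mean.  Transcripts absent from every sample are masked (NaN).
    """
    scaled = counts * (total / counts.sum(axis=0))
    absent = (counts.sum(axis=1) == 0)
    scaled = scaled.where(scaled > 0, pseudocount)

    geo = {}
    for strain, grp in meta.groupby("strain"):
        cols = [c for c in grp.index if c in scaled.columns]
        geo[strain] = np.exp(np.log(scaled[cols]).mean(axis=1))
    geo_df = pd.DataFrame(geo)
    if wt_strain not in geo_df.columns:
        raise ValueError(f"wild-type strain {wt_strain!r} not in metadata")
    ratios = np.log2(geo_df.drop(columns=wt_strain).div(geo_df[wt_strain], axis=0))
    return ratios.mask(absent, np.nan)
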