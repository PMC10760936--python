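"""Synthetic paired-end placements over a trans-spliced chloroplast gene.

The default annotation lays the three psaA exons and two introns out
contiguously on a synthetic chloroplast coordinate system, together with a
few other chloroplast genes and one non-coding RNA.  Fragments are drawn
from a chosen splice form (precursor, single-intron-spliced, mature) with a
discrete insert-size model; mate coordinates are mapped back to the genome,
and mates that cross a splice junction are marked as spliced (gapped)
alignments.  Intron lengths exceed the maximum insert size, so a precursor
can never mimic an adjacent-exon (spliced) pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..transcripts import (
    MOLECULES,
    ChloroplastAnnotation,
    InsertModel,
    molecule_positions,
)

__all__ = ["default_annotation", "simulate_splice_reads", "simulate_gene_placements"]


def default_annotation() -> ChloroplastAnnotation:
    """Synthetic chloroplast annotation with a contiguous psaA layout.

    Exons of 240/120/900 bp separated by introns of 650/700 bp, plus three
    other coding genes and one ncRNA locus.
    """
    exons = ((2001, 2240), (2891, 3010), (3711, 4610))
    introns = ((2241, 2890), (3011, 3710))
    genes = pd.DataFrame(
        {
            "start": [2001, 6001, 8001, 10001, 12001],
            "end": [4610, 7062, 9428, 11472, 12430],
            "kind": ["gene", "gene", "gene", "gene", "ncRNA"],
        },
        index=pd.Index(["psaA", "psbA", "rbcL", "atpB", "tscA"], name="gene"),
    )
    return ChloroplastAnnotation(genes=genes, exons=exons, introns=introns)


def simulate_splice_reads(
    ann: ChloroplastAnnotation,
    fractions: tuple[float, float, float, float],
    n_pairs: int,
    model: InsertModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw paired-end placements from a mixture of psaA splice forms.

    ``fractions`` gives the molecule-type mixture in the order
    ``(precursor, intron1_only, intron2_only, mature)`` and must sum to 1.
    Returns a placement DataFrame with mate coordinates, spliced flags and
    the generating ``molecule`` truth column.

    Raises if a drawn fragment would be longer than its molecule.
    """
    model = model or InsertModel()
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (4,) or (frac < 0).any() or abs(frac.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    types = rng.choice(len(MOLECULES), size=n_pairs, p=frac)
    r = model.read_len

    rows = {k: np.empty(n_pairs) for k in
            ("m1_start", "m1_end", "m2_start", "m2_end")}
    spliced1 = np.empty(n_pairs, dtype=bool)
    spliced2 = np.empty(n_pairs, dtype=bool)
    molecule = np.empty(n_pairs, dtype=object)

    for ti, mol in enumerate(MOLECULES):
        idx = np.flatnonzero(types == ti)
        if idx.size == 0:
            continue
        gpos = molecule_positions(ann, mol)
        n = gpos.size
        lengths = np.clip(
            np.rint(rng.normal(model.mean, model.sd, size=idx.size)),
            model.l_min, model.l_max,
        ).astype(int)
        if (lengths > n).any():
            raise ValueError("fragment longer than molecule")
        starts = rng.integers(0, n - lengths + 1)
        gs1, ge1 = gpos[starts], gpos[starts + r - 1]
        gs2, ge2 = gpos[starts + lengths - r], gpos[starts + lengths - 1]
        rows["m1_start"][idx], rows["m1_end"][idx] = gs1, ge1
        rows["m2_start"][idx], rows["m2_end"][idx] = gs2, ge2
        spliced1[idx] = (ge1 - gs1) != (r - 1)
        spliced2[idx] = (ge2 - gs2) != (r - 1)
        molecule[idx] = mol

    out = pd.DataFrame(rows)
    out["m1_spliced"] = spliced1
    out["m2_spliced"] = spliced2
    out["molecule"] = molecule
    return out


def simulate_gene_placements(
    ann: ChloroplastAnnotation,
    gene_fractions: dict[str, float],
    n_pairs: int,
    read_len: int = 75,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw read pairs from a known mixture of chloroplast genes.

    Both mates of a pair fall uniformly (and fully) within the chosen gene;
    used as ground truth for per-gene count normalization.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_fractions)
    p = np.array([gene_fractions[g] for g in genes], dtype=float)
    p = p / p.sum()
    choice = rng.choice(len(genes), size=n_pairs, p=p)
    rows = []
    for gi, gene in enumerate(genes):
        idx = np.flatnonzero(choice == gi)
        if idx.size == 0:
            continue
        row = ann.genes.loc[gene]
        lo, hi = int(row["start"]), int(row["end"]) - read_len + 1
        if hi <= lo:
            raise ValueError(f"gene {gene} shorter than a read")
        s1 = rng.integers(lo, hi + 1, size=idx.size)
        s2 = rng.integers(lo, hi + 1, size=idx.size)
        for j, a, b in zip(idx, s1, s2):
            rows.append(
                {"m1_start": a, "m1_end": a + read_len - 1, "m1_spliced": False,
                 "m2_start": b, "m2_end": b + read_len - 1, "m2_spliced": False,
                 "gene": gene}
            )
    return pd.DataFrame(rows).sort_index()
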