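"""Isobaric 11-plex proteome normalization and complex-depletion calls.

Each 11-plex run quantifies ten mutants and one wild-type control.  The
normalization chain is: (1) divide every sample by the wild-type channel of
its plex, per protein; (2) divide every sample by its own median over
observed proteins (corrects channel loading); (3) divide every protein by
its median within each plex (corrects plex-wise batch effects and sets each
protein's per-plex median to 1).  Missing values stay missing -- medians
are over observed values only, nothing is imputed.

A mutant shows a complex-level "proteomic phenotype" only when both of its
replicates (run in different plexes) show it: the replicate-wise complex
score is the median log2 abundance over annotated subunits and a complex is
called depleted when both replicate scores clear the fold-change cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlexDesign",
    "relative_to_wt",
    "sample_median_normalize",
    "plex_median_normalize",
    "normalize_plex_chain",
    "average_replicates",
    "call_complex_phenotypes",
]


@dataclass
class PlexDesign:
    """Channel layout of a TMT experiment.

    ``table`` columns: ``plex``, ``channel``, ``sample``, ``mutant``,
    ``replicate``, ``is_wt``.  Exactly one wild-type channel per plex; each
    mutant's replicates should sit in different plexes.
    """

    table: pd.DataFrame

    REQUIRED = ("plex", "channel", "sample", "mutant", "replicate", "is_wt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"plex design missing columns: {missing}")
        wt_per_plex = self.table.groupby("plex")["is_wt"].sum()
        if (wt_per_plex != 1).any():
            bad = list(wt_per_plex.index[wt_per_plex != 1])
            raise ValueError(f"each plex needs exactly one WT channel; bad: {bad}")
        reps = self.table[~self.table["is_wt"]].groupby("mutant")["plex"].nunique()
        n_reps = self.table[~self.table["is_wt"]].groupby("mutant")["sample"].size()
        if ((n_reps > 1) & (reps < 2)).any():
            warnings.warn("some mutants have replicates within one plex",
                          stacklevel=2)

    @property
    def plexes(self) -> list:
        return sorted(self.table["plex"].unique())

    def samples_of(self, plex) -> list[str]:
        return list(self.table.loc[self.table["plex"] == plex, "sample"])

    def wt_sample(self, plex) -> str:
        t = self.table
        return t.loc[(t["plex"] == plex) & t["is_wt"], "sample"].iloc[0]

    def mutant_samples(self) -> pd.DataFrame:
        """Non-WT samples with their mutant and replicate labels."""
        return self.table.loc[~self.table["is_wt"],
                              ["sample", "mutant", "replicate", "plex"]]


def relative_to_wt(raw: pd.DataFrame, design: PlexDesign) -> pd.DataFrame:
    """Per-protein division by the plex's wild-type channel.

    Proteins missing (or zero) in a plex's WT channel are masked across that
    plex; the per-plex masked-protein counts are stored in
    ``result.attrs['wt_masked']``.  The WT channels themselves become 1.
    """
    out = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    masked: dict = {}
    for plex in design.plexes:
        samples = [s for s in design.samples_of(plex) if s in raw.columns]
        wt = raw[design.wt_sample(plex)]
        bad = wt.isna() | (wt == 0)
        masked[plex] = int(bad.sum())
        out[samples] = raw[samples].div(wt.where(~bad), axis=0)
    out.attrs["wt_masked"] = masked
    return out


def sample_median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide every sample by its median over observed proteins.

    All-missing samples cannot be normalized and are dropped with a warning.
    Idempotent: the medians of the result are all 1.
    """
    med = matrix.median(axis=0, skipna=True)
    dead = list(med.index[med.isna()])
    if dead:
        warnings.warn(f"excluding all-missing samples: {dead}", stacklevel=2)
        matrix = matrix.drop(columns=dead)
        med = med.drop(index=dead)
    out = matrix.div(med, axis=1)
    out.attrs["excluded_samples"] = dead
    return out


def plex_median_normalize(matrix: pd.DataFrame, design: PlexDesign) -> pd.DataFrame:
    """Divide every protein by its median within each plex.

    After this step each protein's per-plex median over observed samples is
    exactly 1 (0 on the log2 scale).  Proteins unobserved in a whole plex
    stay missing there.
    """
    out = matrix.copy()
    for plex in design.plexes:
        samples = [s for s in design.samples_of(plex) if s in matrix.columns]
        med = matrix[samples].median(axis=1, skipna=True)
        out[samples] = matrix[samples].div(med, axis=0)
    return out


def normalize_plex_chain(raw: pd.DataFrame, design: PlexDesign,
                         drop_wt: bool = True) -> pd.DataFrame:
    """Full normalization chain: WT-relative, sample-median, plex-median.

    The WT channels (identically 1 after the first step) stay in place for
    the per-plex medians and are dropped only at the end.
    """
    rel = relative_to_wt(raw, design)
    out = plex_median_normalize(sample_median_normalize(rel), design)
    if drop_wt:
        wt_cols = [design.wt_sample(p) for p in design.plexes]
        out = out.drop(columns=[c for c in wt_cols if c in out.columns])
    return out


def average_replicates(matrix: pd.DataFrame, design: PlexDesign) -> pd.DataFrame:
    """Mean log2 abundance per protein across each mutant's replicates."""
    log2 = np.log2(matrix)
    groups = design.mutant_samples().groupby("mutant")["sample"].apply(list)
    cols = {
        mutant: log2[[s for s in samples if s in log2.columns]].mean(axis=1)
        for mutant, samples in groups.items()
    }
    return pd.DataFrame(cols)


def call_complex_phenotypes(
    matrix: pd.DataFrame,
    design: PlexDesign,
    annotation: pd.DataFrame,
    cutoff: float = 1.0,
) -> pd.DataFrame:
    """Call complex-level depletion per mutant from normalized abundances.

    ``annotation`` columns: ``protein``, ``complex``.  Per mutant, replicate
    and complex, the score is the median log2 abundance over annotated
    subunits.  ``call`` is ``"depleted"`` when both replicate scores are
    <= -cutoff (default 1, i.e. two-fold), empty otherwise; mutants with
    fewer than two replicates are withheld and discordant replicate pairs
    (exactly one score past the cutoff) are flagged for an additional
    repeat.

    Returns one row per (mutant, complex) with replicate scores, the mean
    score, the call and the flag.
    """
    log2 = np.log2(matrix)
    samples = design.mutant_samples()
    prot_complex = annotation.set_index("protein")["complex"]
    complexes = sorted(prot_complex.unique())
    rows = []
    for mutant, grp in samples.groupby("mutant"):
        reps = grp.sort_values("replicate")
        rep_samples = [s for s in reps["sample"] if s in log2.columns]
        for cx in complexes:
            subunits = prot_complex.index[prot_complex == cx]
            sub = log2.loc[log2.index.intersection(subunits), rep_samples]
            scores = sub.median(axis=0, skipna=True)
            row = {"mutant": mutant, "complex": cx,
                   "scores": tuple(np.round(scores, 6)),
                   "mean_log2": float(scores.mean()) if len(scores) else np.nan}
            if len(scores) < 2 or scores.isna().any():
                row["call"] = ""
                row["flag"] = "insufficient-replicates"
            else:
                below = scores <= -cutoff
                if below.all():
                    row["call"] = "depleted"
                    row["flag"] = ""
                elif below.any():
                    row["call"] = ""
                    row["flag"] = "discordant"
                else:
                    row["call"] = ""
                    row["flag"] = ""
            rows.append(row)
    return pd.DataFrame(rows, columns=["mutant", "complex", "scores",
                                       "mean_log2", "call", "flag"])
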