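"""Growth-score computation and hit calling for the pooled backcross screen.

The phenotype of interest is depletion of a barcode in photoautotrophic
light cultures relative to heterotrophic dark cultures.  Per experiment the
signal is ``log2(averaged light reads / averaged dark reads)``; the final
growth score of a barcode is the median of its five strongest (most
negative) valid per-experiment ratios.  A gene is a hit when its strongest
mutant scores below the hit threshold with enough experimental support.

Replicate averaging uses the median with three replicates and the geometric
mean with two.  Experiments whose dark average falls below a per-experiment
read floor (7 in the first experiment, 10 in the rest) are excluded as too
noisy.  Experiments run under conditions that shift the whole relative-growth
distribution (e.g. a re-arrayed pool enriched for mutants with defects) can
be flagged for rescaling of their log2 ratios (factor 0.6 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DARK, LIGHT, BarcodeLibrary, CountMatrix

__all__ = [
    "ScreenParams",
    "SwapReport",
    "detect_swaps",
    "apply_swaps",
    "condition_average",
    "experiment_ratio",
    "growth_score",
    "call_hits",
    "score_screen",
]


@dataclass
class ScreenParams:
    """Tunable parameters of the scoring pipeline.

    ``hit_threshold`` is on the linear light/dark scale (0.34 corresponds to
    -1.55 on the log2 scale).  ``support_rule`` selects what "reads above the
    threshold in at least two experiments" counts: ``"dark_reads"`` (default,
    the literal reading: the dark average clears the read floor in >= 2
    experiments) or ``"below_threshold"`` (the ratio is below the hit
    threshold in >= 2 experiments).
    """

    dark_min_first: float = 7.0
    dark_min_rest: float = 10.0
    first_experiment: str | None = None
    np_scale: float = 0.6
    np_experiments: tuple[str, ...] = ()
    k_strongest: int = 5
    hit_threshold: float = 0.34
    min_support_experiments: int = 2
    support_rule: str = "dark_reads"
    light_pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.hit_threshold < 1.0:
            raise ValueError("hit_threshold must lie in (0, 1)")
        if self.k_strongest < 1:
            raise ValueError("k_strongest must be >= 1")
        if self.support_rule not in ("dark_reads", "below_threshold"):
            raise ValueError("support_rule must be 'dark_reads' or 'below_threshold'")

    def dark_min(self, experiment: str, experiments: Sequence[str]) -> float:
        first = self.first_experiment or sorted(experiments)[0]
        return self.dark_min_first if experiment == first else self.dark_min_rest

    @property
    def log2_threshold(self) -> float:
        return float(np.log2(self.hit_threshold))


@dataclass
class SwapReport:
    """Result of the correlation-based sample-swap check."""

    pairs: pd.DataFrame  # columns: sample_a, sample_b, corr, own_corr_a, own_corr_b
    warnings: list[str] = field(default_factory=list)


def detect_swaps(matrix: CountMatrix, method: str = "pearson",
                 margin: float = 0.05) -> SwapReport:
    """Flag sample pairs that look exchanged between conditions.

    A sample's closest relative (highest-correlating other sample on log1p
    counts) should share its condition: replicates of one culture split are
    near-identical, while light and dark cultures diverge through selection.
    A sample whose best correlate across conditions beats its best
    same-condition correlate by more than ``margin`` is a suspect; suspect
    light/dark samples are then paired (greedily, by the size of their
    combined margins) into candidate swaps.  The margin keeps near-ties --
    e.g. an honest replicate that also correlates highly with a swapped-in
    column of its own condition -- from being flagged.  Correlations span
    all experiments, since swaps can occur between them.

    Constant (uninformative) columns are skipped with a warning, as are
    matrices with fewer than two replicates of a condition.
    """
    cols = ["sample_a", "sample_b", "cross_corr_a", "cross_corr_b"]
    notes: list[str] = []
    counts = np.log1p(matrix.counts)
    meta = matrix.samples.loc[list(counts.columns)]
    constant = [c for c in counts.columns if counts[c].nunique() <= 1]
    if constant:
        notes.append(f"skipping constant columns: {constant}")
        counts = counts.drop(columns=constant)
        meta = meta.drop(index=constant)
    for cond_label in (LIGHT, DARK):
        if (meta["condition"] == cond_label).sum() < 2:
            notes.append(
                f"fewer than 2 replicates for {cond_label}; swap check skipped")
            return SwapReport(pairs=pd.DataFrame(columns=cols), warnings=notes)

    corr = counts.corr(method=method)
    cond = meta["condition"]

    def best_corr(sample: str, condition: str) -> float:
        others = [c for c in corr.columns if c != sample and cond[c] == condition]
        return float(corr.loc[sample, others].max()) if others else np.nan

    own = {s: best_corr(s, cond[s]) for s in corr.columns}
    cross = {
        s: best_corr(s, LIGHT if cond[s] == DARK else DARK) for s in corr.columns
    }
    margins = {s: cross[s] - own[s] for s in corr.columns}
    suspects = [s for s in corr.columns if margins[s] > margin]
    light_s = [s for s in suspects if cond[s] == LIGHT]
    dark_s = [s for s in suspects if cond[s] == DARK]

    rows = []
    used: set[str] = set()
    candidates = sorted(
        ((margins[a] + margins[b], a, b) for a in light_s for b in dark_s),
        reverse=True,
    )
    for _, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        rows.append({"sample_a": a, "sample_b": b,
                     "cross_corr_a": cross[a], "cross_corr_b": cross[b]})
    return SwapReport(pairs=pd.DataFrame(rows, columns=cols), warnings=notes)


def apply_swaps(matrix: CountMatrix, pairs: Iterable[tuple[str, str]]) -> CountMatrix:
    """Exchange the count columns of each listed sample pair (fixes swaps)."""
    out = matrix.copy()
    for a, b in pairs:
        out.counts[[a, b]] = out.counts[[b, a]].to_numpy()
    return out


def condition_average(matrix: CountMatrix) -> pd.DataFrame:
    """Average replicate columns per (experiment, condition).

    Median with three replicates, geometric mean with two (a zero replicate
    makes the geometric mean zero; the downstream dark-read floor then
    governs validity).  One replicate passes through and four or more fall
    back to the median, both with a warning.

    Returns a DataFrame indexed by barcode with MultiIndex columns
    (experiment, condition).
    """
    cols = {}
    for exp in matrix.experiments:
        for cond in (LIGHT, DARK):
            ids = matrix.sample_ids(experiment=exp, condition=cond)
            if not ids:
                continue
            block = matrix.counts[ids]
            n = len(ids)
            if n == 1:
                warnings.warn(f"{exp}/{cond}: single replicate, passing through",
                              stacklevel=2)
                avg = block.iloc[:, 0].astype(float)
            elif n == 2:
                with np.errstate(divide="ignore"):
                    avg = pd.Series(stats.gmean(block.to_numpy(), axis=1),
                                    index=block.index)
            else:
                if n > 3:
                    warnings.warn(f"{exp}/{cond}: {n} replicates, using median",
                                  stacklevel=2)
                avg = block.median(axis=1)
            cols[(exp, cond)] = avg
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["experiment", "condition"])
    return out


def experiment_ratio(
    averages: pd.DataFrame, params: ScreenParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-experiment log2(light/dark) ratios with validity flags.

    An experiment's entry is invalid when its dark average is below the
    experiment's dark-read floor (or a condition is missing entirely).  A
    zero light average gets a 0.5 pseudocount on the light side only, so
    complete depletion stays finite but strongly negative.  Ratios of
    experiments listed in ``params.np_experiments`` are multiplied by
    ``params.np_scale`` on the log2 scale.

    Returns ``(ratios, valid)`` DataFrames indexed by barcode with one
    column per experiment.
    """
    params = params or ScreenParams()
    experiments = sorted(averages.columns.get_level_values("experiment").unique())
    ratios = {}
    valid = {}
    for exp in experiments:
        block = averages[exp]
        if LIGHT not in block.columns or DARK not in block.columns:
            ratios[exp] = pd.Series(np.nan, index=averages.index)
            valid[exp] = pd.Series(False, index=averages.index)
            continue
        light = block[LIGHT].astype(float)
        dark = block[DARK].astype(float)
        ok = dark >= params.dark_min(exp, experiments)
        light_adj = light.where(light > 0, params.light_pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2(light_adj / dark)
        if exp in params.np_experiments:
            r = r * params.np_scale
        ratios[exp] = r.where(ok)
        valid[exp] = ok
    return pd.DataFrame(ratios), pd.DataFrame(valid)


def growth_score(
    ratios: pd.DataFrame, valid: pd.DataFrame, params: ScreenParams | None = None
) -> pd.DataFrame:
    """Aggregate per-experiment ratios into the growth score.

    The score is the median of the ``k_strongest`` (default five) most
    negative valid ratios -- all of them when fewer are valid -- and is
    undefined (NaN) for barcodes with fewer than
    ``min_support_experiments`` valid experiments.
    """
    params = params or ScreenParams()
    vals = ratios.where(valid)
    arr = np.sort(vals.to_numpy(), axis=1)  # NaNs sort to the end

    def median_k_lowest(row: np.ndarray) -> float:
        finite = row[~np.isnan(row)]
        if finite.size < params.min_support_experiments:
            return np.nan
        return float(np.median(finite[: params.k_strongest]))

    scores = np.apply_along_axis(median_k_lowest, 1, arr)
    return pd.DataFrame(
        {"score": scores, "n_valid": valid.sum(axis=1)}, index=ratios.index
    )


def call_hits(
    scores: pd.DataFrame,
    ratios: pd.DataFrame,
    valid: pd.DataFrame,
    library: BarcodeLibrary,
    params: ScreenParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call hits at the mutant and gene level.

    A mutant is a hit when its growth score is below ``log2(hit_threshold)``
    and it has support in at least ``min_support_experiments`` experiments
    (see :class:`ScreenParams.support_rule`).  A gene's score is the
    strongest (minimum) score among its insertions and the gene is a hit
    when any of its mutants is.

    Returns ``(mutant_table, gene_table)``.
    """
    params = params or ScreenParams()
    tau = params.log2_threshold
    if params.support_rule == "dark_reads":
        support = valid.sum(axis=1)
    else:
        support = (ratios.where(valid) < tau).sum(axis=1)
    lib = library.table.set_index("barcode")
    mutant = pd.DataFrame(
        {
            "mutant": lib["mutant"].reindex(scores.index),
            "gene": lib["gene"].reindex(scores.index),
            "score": scores["score"],
            "n_valid": scores["n_valid"],
            "support": support,
            "hit": (scores["score"] < tau)
            & (support >= params.min_support_experiments),
        }
    )
    gene = (
        mutant.dropna(subset=["gene"])
        .groupby("gene")
        .agg(score=("score", "min"), n_mutants=("mutant", "count"),
             hit=("hit", "any"))
        .reset_index()
    )
    return mutant, gene


def score_screen(
    matrix: CountMatrix,
    library: BarcodeLibrary,
    params: ScreenParams | None = None,
) -> dict[str, pd.DataFrame]:
    """Run averaging, ratios, scoring and hit calling on normalized counts.

    Convenience wrapper returning ``{"ratios", "valid", "scores", "mutants",
    "genes"}``.
    """
    params = params or ScreenParams()
    avg = condition_average(matrix)
    ratios, valid = experiment_ratio(avg, params)
    scores = growth_score(ratios, valid, params)
    mutants, genes = call_hits(scores, ratios, valid, library, params)
    return {"ratios": ratios, "valid": valid, "scores": scores,
            "mutants": mutants, "genes": genes}
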