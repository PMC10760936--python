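"""Empirical FDR estimation from a negative-control gene set.

The estimator calibrates hit calls against genes whose disruption likely
does not cause a photosynthesis defect (GNRPD): genes that were hit many
times in a prior insertion survey with almost no phenotypic mutants.  If a
fraction ``g/G`` of the GNRPD set slips below the hit threshold, the same
fraction of all not-required genes in the starting set is assumed to do so,
giving

    FDR = (g / G) * N * (1 - frac_required) / H

where ``N`` is the number of starting genes, ``frac_required`` the estimated
fraction of them truly required for photosynthesis, and ``H`` the number of
hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FdrParams", "FdrResult", "define_gnrpd", "estimate_fdr", "threshold_sweep"]


@dataclass
class FdrParams:
    """Constants of the GNRPD FDR estimator.

    ``frac_required`` is the estimated fraction of starting genes required
    for photosynthesis (a literature prevalence of 6.25% doubled to account
    for yet-undiscovered genes).  GNRPD membership requires strictly more
    than ``gnrpd_min_insertions`` prior insertions with at most
    ``gnrpd_max_phenotypic`` phenotypic mutants among them.
    """

    frac_required: float = 0.125
    gnrpd_min_insertions: int = 20
    gnrpd_max_phenotypic: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_required < 1.0:
            raise ValueError("frac_required must lie in (0, 1)")


@dataclass
class FdrResult:
    threshold: float | None
    n_hits: int
    n_gnrpd_hits: int
    gnrpd_size: int
    n_start_genes: int
    n_not_required: float
    fdr: float


def define_gnrpd(prior: pd.DataFrame, params: FdrParams | None = None) -> set[str]:
    """Select the negative-control gene set from a prior insertion table.

    ``prior`` columns: ``gene``, ``n_insertions``, ``n_phenotypic``.  A gene
    qualifies with strictly more than ``gnrpd_min_insertions`` insertions of
    which at most ``gnrpd_max_phenotypic`` were phenotypic.
    """
    params = params or FdrParams()
    if len(prior) == 0:
        raise ValueError("empty prior insertion table")
    keep = (prior["n_insertions"] > params.gnrpd_min_insertions) & (
        prior["n_phenotypic"] <= params.gnrpd_max_phenotypic
    )
    return set(prior.loc[keep, "gene"])


def estimate_fdr(
    n_hits: int,
    n_gnrpd_hits: int,
    gnrpd_size: int,
    n_start_genes: int,
    params: FdrParams | None = None,
    threshold: float | None = None,
) -> FdrResult:
    """Estimate the FDR of a hit list from GNRPD prevalence among hits.

    Raises if there are no negative controls.  A zero-hit list has an
    undefined (NaN) FDR.  Estimates above 1 are reported unclipped with a
    warning.
    """
    params = params or FdrParams()
    if gnrpd_size == 0:
        raise ValueError("no negative controls: GNRPD set is empty")
    if not 0 <= n_gnrpd_hits <= gnrpd_size:
        raise ValueError("n_gnrpd_hits must lie in [0, gnrpd_size]")
    n_not_required = n_start_genes * (1.0 - params.frac_required)
    if n_hits == 0:
        fdr = float("nan")
    else:
        fdr = (n_gnrpd_hits / gnrpd_size) * n_not_required / n_hits
        if fdr > 1.0:
            warnings.warn(f"FDR estimate {fdr:.3g} exceeds 1 (reported unclipped)",
                          stacklevel=2)
    return FdrResult(
        threshold=threshold,
        n_hits=n_hits,
        n_gnrpd_hits=n_gnrpd_hits,
        gnrpd_size=gnrpd_size,
        n_start_genes=n_start_genes,
        n_not_required=n_not_required,
        fdr=fdr,
    )


def threshold_sweep(
    gene_table: pd.DataFrame,
    gnrpd: set[str],
    n_start_genes: int,
    params: FdrParams | None = None,
    thresholds: np.ndarray | None = None,
    support: pd.Series | None = None,
) -> pd.DataFrame:
    """FDR and hit counts over a grid of linear hit thresholds.

    ``gene_table`` needs ``gene`` and ``score`` (log2) columns, as produced
    by :func:`photoscreen.scoring.call_hits`.  ``support`` optionally maps
    gene -> bool for the experiment-support requirement; genes without
    support never count as hits at any threshold.
    """
    params = params or FdrParams()
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 1.0, 0.05), 2)
    scores = gene_table.set_index("gene")["score"]
    if support is not None:
        scores = scores.where(support.reindex(scores.index, fill_value=False))
    in_gnrpd = scores.index.isin(list(gnrpd))
    rows = []
    for tau in np.asarray(thresholds, dtype=float):
        below = scores < np.log2(tau)
        res = estimate_fdr(
            n_hits=int(below.sum()),
            n_gnrpd_hits=int((below & in_gnrpd).sum()),
            gnrpd_size=len(gnrpd),
            n_start_genes=n_start_genes,
            params=params,
            threshold=float(tau),
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)
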