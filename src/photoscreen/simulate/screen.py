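"""Generative model of a pooled backcross barcode screen.

Each mutant strain carries one barcoded cassette insertion plus a random
number of unmarked second-site lesions.  Backcrossing to wild type makes every
lesion segregate into the progeny independently with probability 1/2, except
lesions genetically linked to the insertion, which co-segregate with
probability ``1 - recomb_fraction``.  Only progeny that inherit the cassette
are observed (the barcode is the cassette).

The progeny pool then grows competitively for ``n_doublings`` doublings.  In
the dark everyone doubles at rate 1; in the light, genotypes carrying any
photosynthesis-breaking (causal) lesion double at rate ``1 - s``.  Growth is
modeled as deterministic exponential amplification of each genotype class,
after which reads are sampled per sample at the requested depth -- a plain
multinomial when ``dispersion == 0``, Dirichlet-multinomial otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..containers import (
    DARK,
    LIGHT,
    BarcodeLibrary,
    CountMatrix,
    make_sample_sheet,
    random_barcodes,
)

__all__ = [
    "TruthConfig",
    "TruthTable",
    "simulate_backcross_screen",
    "simulate_prior_insertions",
    "expected_light_dark_ratio",
]


@dataclass
class TruthConfig:
    """Study conditions for :func:`simulate_backcross_screen`.

    Parameters
    ----------
    n_mutants
        Number of barcoded strains in the pool (one barcode each).
    mean_second_site
        Poisson mean of unmarked second-site lesions per strain.
    p_insertion_causal
        Probability that the barcoded insertion itself disrupts a gene
        required for photosynthesis.
    p_second_site_causal
        Probability that a given second-site lesion is photosynthesis-breaking.
    p_linked
        Probability that a second-site lesion is genetically linked to the
        insertion (nearby on the same chromosome).
    recomb_fraction
        Recombination fraction for linked lesions, in [0, 0.5]; 0 means
        perfect linkage.
    light_fitness_deficit
        ``s``: growth-rate reduction per doubling in the light for genotypes
        carrying any causal lesion.  Must be < 1 (s = 1 is extinction).
    n_doublings
        Doublings of competitive growth before harvest.
    depth
        Reads sampled per sample.
    dispersion
        Overdispersion of read sampling; 0 degenerates to multinomial,
        otherwise counts are Dirichlet-multinomial with concentration
        ``p / dispersion``.
    abundance_sigma
        Log-normal sigma (natural log) of per-experiment starting barcode
        abundances, emulating uneven pooling at mating.
    n_experiments, n_replicates
        Independent backcross experiments and replicate cultures per
        condition within each experiment.
    """

    n_mutants: int = 500
    mean_second_site: float = 2.0
    p_insertion_causal: float = 0.125
    p_second_site_causal: float = 0.125
    p_linked: float = 0.05
    recomb_fraction: float = 0.1
    light_fitness_deficit: float = 0.5
    n_doublings: int = 10
    depth: int = 1_000_000
    dispersion: float = 0.0
    abundance_sigma: float = 0.5
    n_experiments: int = 3
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_mutants <= 0:
            raise ValueError("n_mutants must be positive")
        for name in ("p_insertion_causal", "p_second_site_causal", "p_linked"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ValueError("recomb_fraction must lie in [0, 0.5]")
        if self.light_fitness_deficit >= 1.0:
            raise ValueError("light_fitness_deficit >= 1 drives carriers extinct")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class TruthTable:
    """Ground truth for a simulated screen.

    ``mutants`` (one row per strain): ``mutant``, ``barcode``, ``gene``,
    ``insertion_causal``, ``n_second_sites``, ``p_affected`` (probability a
    barcode-carrying progeny cell carries any causal lesion) and
    ``expected_light_ratio`` (expected light/dark abundance ratio before
    normalization across the pool).

    ``lesions`` (one row per second-site lesion): ``mutant``, ``lesion``,
    ``causal``, ``linked``, ``recomb_fraction``.
    """

    mutants: pd.DataFrame
    lesions: pd.DataFrame

    @property
    def causal_genes(self) -> set[str]:
        """Genes whose barcoded insertion is the causal lesion."""
        m = self.mutants
        return set(m.loc[m["insertion_causal"], "gene"])


def _p_unaffected(insertion_causal: bool, lesions: pd.DataFrame,
                  recomb_fraction: float) -> float:
    """P(no causal lesion) for progeny that inherited the barcode.

    The insertion is always present in observed progeny.  Each causal
    second-site lesion is absent with probability ``recomb_fraction`` if
    linked, 1/2 if unlinked; lesions segregate independently.
    """
    if insertion_causal:
        return 0.0
    p = 1.0
    for _, row in lesions.iterrows():
        if not row["causal"]:
            continue
        p *= recomb_fraction if row["linked"] else 0.5
    return p


def expected_light_dark_ratio(p_affected: np.ndarray, s: float, t: int) -> np.ndarray:
    """Expected per-barcode light/dark abundance ratio (pre-normalization).

    Affected genotype classes grow as ``2**((1-s) t)`` in the light versus
    ``2**t`` in the dark, so relative to dark the barcode retains
    ``(1 - p_affected) + p_affected * 2**(-s t)`` of its abundance.
    """
    return (1.0 - p_affected) + p_affected * 2.0 ** (-s * t)


def simulate_backcross_screen(
    config: TruthConfig,
) -> tuple[BarcodeLibrary, CountMatrix, TruthTable]:
    """Simulate a pooled backcross screen with known ground truth.

    Returns the barcode library, the raw count matrix over all
    experiment/condition/replicate samples, and the truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mutants
    s = config.light_fitness_deficit
    t = config.n_doublings

    mutant_ids = [f"m{i:05d}" for i in range(n)]
    gene_ids = [f"g{i:05d}" for i in range(n)]
    barcodes = random_barcodes(n, 22, rng)

    insertion_causal = rng.random(n) < config.p_insertion_causal
    n_second = rng.poisson(config.mean_second_site, size=n)

    lesion_rows = []
    p_aff = np.empty(n)
    for i in range(n):
        k = n_second[i]
        causal = rng.random(k) < config.p_second_site_causal
        linked = rng.random(k) < config.p_linked
        for j in range(k):
            lesion_rows.append(
                {"mutant": mutant_ids[i], "lesion": j, "causal": bool(causal[j]),
                 "linked": bool(linked[j]),
                 "recomb_fraction": config.recomb_fraction}
            )
        # P(absent) per causal lesion: recomb fraction if linked, 1/2 otherwise.
        if insertion_causal[i]:
            p_un = 0.0
        else:
            absent = np.where(linked, config.recomb_fraction, 0.5)
            p_un = float(np.prod(absent[causal])) if causal.any() else 1.0
        p_aff[i] = 1.0 - p_un

    lesions = pd.DataFrame(
        lesion_rows,
        columns=["mutant", "lesion", "causal", "linked", "recomb_fraction"],
    )
    light_weight = expected_light_dark_ratio(p_aff, s, t)

    mutants = pd.DataFrame(
        {
            "mutant": mutant_ids,
            "barcode": barcodes,
            "gene": gene_ids,
            "insertion_causal": insertion_causal,
            "n_second_sites": n_second,
            "p_affected": p_aff,
            "expected_light_ratio": light_weight,
        }
    )
    truth = TruthTable(mutants=mutants, lesions=lesions)

    library = BarcodeLibrary(
        pd.DataFrame(
            {"barcode": barcodes, "mutant": mutant_ids, "gene": gene_ids,
             "confidence": 1}
        )
    )

    samples = make_sample_sheet(config.n_experiments, config.n_replicates)
    counts = pd.DataFrame(0, index=pd.Index(barcodes, name="barcode"),
                          columns=samples.index, dtype=np.int64)

    for e in range(1, config.n_experiments + 1):
        if config.abundance_sigma > 0:
            start = rng.lognormal(0.0, config.abundance_sigma, size=n)
        else:
            start = np.ones(n)
        freq = {LIGHT: start * light_weight, DARK: start}
        for cond, weights in freq.items():
            p = weights / weights.sum()
            cond_samples = samples.index[
                (samples["experiment"] == f"exp{e}") & (samples["condition"] == cond)
            ]
            for sample in cond_samples:
                if config.dispersion > 0:
                    p_rep = rng.dirichlet(p / config.dispersion)
                else:
                    p_rep = p
                counts[sample] = rng.multinomial(config.depth, p_rep)

    return library, CountMatrix(counts, samples), truth


def simulate_prior_insertions(
    truth: TruthTable,
    seed: int = 0,
    mean_insertions: float = 25.0,
    phenotypic_rate_causal: float = 0.75,
    phenotypic_rate_neutral: float = 0.02,
) -> pd.DataFrame:
    """Emulate a prior large-scale insertion survey of the screened genes.

    For each gene, draws the number of independent insertion mutants observed
    previously (Poisson) and how many of them showed a photosynthetic defect:
    a high phenotypic rate if the gene is truly required, a low background
    rate (second-site artifacts in the prior study) otherwise.  The result is
    the input expected by :func:`photoscreen.fdr.define_gnrpd`.
    """
    rng = np.random.default_rng(seed)
    genes = truth.mutants["gene"].to_numpy()
    required = truth.mutants["insertion_causal"].to_numpy()
    n_ins = rng.poisson(mean_insertions, size=len(genes))
    rate = np.where(required, phenotypic_rate_causal, phenotypic_rate_neutral)
    n_phen = rng.binomial(n_ins, rate)
    return pd.DataFrame(
        {"gene": genes, "n_insertions": n_ins, "n_phenotypic": n_phen}
    )
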