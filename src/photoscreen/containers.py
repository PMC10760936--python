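"""Shared data containers for the pooled-screen pipeline.

The pipeline moves barcode read counts through normalization, per-experiment
light/dark ratios and a final growth score.  Two light regimes define the
phenotype: photoautotrophic growth on minimal medium in the light (``TP-light``)
and heterotrophic growth on acetate in the dark (``TAP-dark``).  Only the former
requires photosynthesis, so the light/dark abundance ratio of a barcoded mutant
measures its photosynthetic fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Condition labels used throughout the package.
LIGHT = "TP-light"
DARK = "TAP-dark"

CONDITIONS = (LIGHT, DARK)


@dataclass
class BarcodeLibrary:
    """The known barcode -> mutant -> gene mapping of an insertion library.

    ``table`` columns: ``barcode`` (DNA, 21-23 nt), ``mutant``, ``gene``,
    ``confidence`` (insertion-mapping confidence level, 1-4; level 4 is the
    least reliable).  Barcode sequences must be unique.
    """

    table: pd.DataFrame

    REQUIRED = ("barcode", "mutant", "gene", "confidence")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"library table missing columns: {missing}")
        bc = self.table["barcode"]
        if bc.duplicated().any():
            raise ValueError("barcode sequences must be unique")
        lengths = bc.str.len()
        if ((lengths < 21) | (lengths > 23)).any():
            raise ValueError("barcode lengths must lie in [21, 23]")

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.table["barcode"])

    def genes_of(self, barcodes: pd.Index | list[str]) -> pd.Series:
        """Map barcode sequences to gene ids."""
        return self.table.set_index("barcode")["gene"].reindex(barcodes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Barcode x sample read counts plus the sample sheet.

    ``counts``: DataFrame indexed by barcode with one column per sample.
    Values are non-negative; integer for raw counts, float after
    normalization.

    ``samples``: DataFrame indexed by sample id with columns ``experiment``,
    ``condition`` (one of :data:`LIGHT`/:data:`DARK`) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("experiment", "condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        unknown = [c for c in self.counts.columns if c not in self.samples.index]
        if unknown:
            raise ValueError(f"samples absent from sample sheet: {unknown}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions in sample sheet: {sorted(bad)}")

    def sample_ids(self, experiment: str | None = None,
                   condition: str | None = None) -> list[str]:
        meta = self.samples.loc[list(self.counts.columns)]
        keep = pd.Series(True, index=meta.index)
        if experiment is not None:
            keep &= meta["experiment"] == experiment
        if condition is not None:
            keep &= meta["condition"] == condition
        return list(meta.index[keep])

    @property
    def experiments(self) -> list[str]:
        return sorted(self.samples["experiment"].unique())

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.samples.copy())

    @classmethod
    def from_files(cls, counts_tsv: str | Path, samples_csv: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(samples_csv, index_col=0)
        return cls(counts, samples)

    def to_files(self, counts_tsv: str | Path, samples_csv: str | Path) -> None:
        self.counts.to_csv(counts_tsv, sep="\t")
        self.samples.to_csv(samples_csv)


def make_sample_sheet(n_experiments: int, n_replicates: int) -> pd.DataFrame:
    """Build the default fully-crossed sample sheet.

    Samples are named ``exp{e}_{cond}_r{r}`` with ``cond`` in ``{light, dark}``.
    """
    rows = []
    for e in range(1, n_experiments + 1):
        for cond, short in ((LIGHT, "light"), (DARK, "dark")):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {"sample": f"exp{e}_{short}_r{r}", "experiment": f"exp{e}",
                     "condition": cond, "replicate": r}
                )
    return pd.DataFrame(rows).set_index("sample")


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` unique random DNA barcodes of the given length."""
    seen: set[str] = set()
    alphabet = np.array(list("ACGT"))
    while len(seen) < n:
        block = rng.integers(0, 4, size=(n - len(seen), length))
        for row in block:
            seen.add("".join(alphabet[row]))
    return sorted(seen)[:n]
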