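"""Barcode extraction, counting and per-million normalization.

Barcodes sit immediately 5' of a fixed adapter context in the sequencing
read: ``GGCAAG`` for libraries read from the 5' side of the cassette and
``TAGCGC`` for the 3' side.  Extraction mirrors a zero-error-rate 3'-adapter
trim with a quality floor of 33 and retained-length bounds of 21-23 nt:
reads are quality-trimmed from the 3' end, the first exact adapter occurrence
and everything after it is removed, and the remaining prefix is the barcode
if its length lies within bounds.  Anything else yields ``None``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import BarcodeLibrary, CountMatrix

ADAPTERS = {"5p": "GGCAAG", "3p": "TAGCGC"}

DEFAULT_QUALITY_FLOOR = 33
MIN_LEN = 21
MAX_LEN = 23


def quality_trim_3p(quals: list[int] | np.ndarray, cutoff: int) -> int:
    """Return the 3' trim point for the partial-sum quality algorithm.

    Starting from the 3' end, accumulate ``cutoff - q``; the read is cut at
    the position where the running sum is maximal (and positive).  Returns
    the retained length.
    """
    quals = np.asarray(quals)
    if quals.size == 0:
        return 0
    deltas = cutoff - quals[::-1]
    sums = np.cumsum(deltas)
    best = sums.max()
    if best <= 0:
        return quals.size
    # cut after the last position (from the end) achieving the max sum
    k = int(np.flatnonzero(sums == best)[-1]) + 1
    return quals.size - k


def extract_barcode(seq: str, quals: list[int] | None, adapter: str,
                    quality_floor: int = DEFAULT_QUALITY_FLOOR,
                    min_len: int = MIN_LEN, max_len: int = MAX_LEN) -> str | None:
    """Extract the barcode from one read, or ``None`` if it fails any filter."""
    if quals is not None:
        seq = seq[: quality_trim_3p(quals, quality_floor)]
    idx = seq.find(adapter)
    if idx < 0:
        return None
    barcode = seq[:idx]
    if not (min_len <= len(barcode) <= max_len):
        return None
    return barcode


def extract_barcodes(reads: str | Path | Iterable, side: str = "5p",
                     quality_floor: int = DEFAULT_QUALITY_FLOOR) -> list[str | None]:
    """Extract barcodes from a FASTQ file (or SeqRecord iterable).

    Parameters
    ----------
    reads
        Path to a FASTQ file, or an iterable of ``Bio.SeqRecord`` objects.
    side
        ``"5p"`` or ``"3p"``; selects the adapter context.

    Returns one entry per read: the barcode string, or ``None`` for reads
    failing adapter match, quality trimming or the length bounds.
    """
    if side not in ADAPTERS:
        raise ValueError(f"side must be one of {sorted(ADAPTERS)}")
    adapter = ADAPTERS[side]
    if isinstance(reads, (str, Path)):
        records = SeqIO.parse(str(reads), "fastq")
    else:
        records = reads
    out: list[str | None] = []
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        out.append(extract_barcode(str(rec.seq), quals, adapter,
                                   quality_floor=quality_floor))
    return out


@dataclass
class CountQC:
    """Per-sample extraction/filter tallies."""

    non_library: dict[str, int] = field(default_factory=dict)
    failed_extraction: dict[str, int] = field(default_factory=dict)


def count_and_filter(
    barcodes_per_sample: Mapping[str, Iterable[str | None]],
    library: BarcodeLibrary,
    samples: pd.DataFrame,
) -> tuple[CountMatrix, CountQC]:
    """Count exact library matches per sample; drop everything else.

    Non-library barcodes are excluded from the matrix and tallied in the QC
    report, as are reads whose extraction failed (``None`` entries).
    """
    lib_index = library.barcodes
    lib_set = set(lib_index)
    qc = CountQC()
    columns = {}
    for sample, barcodes in barcodes_per_sample.items():
        tally: dict[str, int] = {}
        non_lib = failed = 0
        for bc in barcodes:
            if bc is None:
                failed += 1
            elif bc in lib_set:
                tally[bc] = tally.get(bc, 0) + 1
            else:
                non_lib += 1
        qc.non_library[sample] = non_lib
        qc.failed_extraction[sample] = failed
        columns[sample] = pd.Series(tally, dtype=np.int64)
    counts = pd.DataFrame(columns, index=lib_index).fillna(0).astype(np.int64)
    counts.index.name = "barcode"
    return CountMatrix(counts, samples), qc


def normalize_per_million(matrix: CountMatrix) -> CountMatrix:
    """Scale every sample column to a total of one million reads.

    All-zero samples cannot be normalized; they are dropped with a warning
    (their ids are recorded in ``counts.attrs['excluded_samples']``).
    """
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=0)
    dead = list(totals.index[totals == 0])
    if dead:
        warnings.warn(f"excluding all-zero samples: {dead}", stacklevel=2)
        counts = counts.drop(columns=dead)
        totals = totals.drop(index=dead)
    normed = counts * (1_000_000.0 / totals)
    normed.attrs["excluded_samples"] = dead
    out = CountMatrix(normed, matrix.samples)
    out.counts.attrs["excluded_samples"] = dead
    return out
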