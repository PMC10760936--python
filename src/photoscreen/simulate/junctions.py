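"""Synthetic read-pair alignment records around cassette insertions.

Produces the tabular SAM-like records consumed by
:mod:`photoscreen.insertions`: discordant cassette/genome pairs scattered on
both flanks of each true insertion, optional one-sided decoy clusters (junk
fragments carrying cassette sequence), and concordant genome pairs that span
decoy positions (impossible for a real insertion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..insertions import (
    FLAG_PAIRED,
    FLAG_PROPER,
    FLAG_REVERSE,
    RECORD_COLUMNS,
)

__all__ = ["Decoy", "simulate_junction_reads"]

CASSETTE_REF = "cassette"


@dataclass
class Decoy:
    """A junk-fragment cluster: one-sided junction reads at a position."""

    chrom: str
    pos: int
    n_reads: int
    side: str = "left"
    n_spanning: int = 0  # concordant pairs spanning the decoy position


def _junction_pair(rows: list, query: str, chrom: str, gpos: int, side: str,
                   read_len: int) -> None:
    genome_flag = FLAG_PAIRED | (0 if side == "left" else FLAG_REVERSE)
    cassette_pos = 1
    rows.append({"query": query, "flag": genome_flag, "ref": chrom, "pos": gpos,
                 "mate_ref": CASSETTE_REF, "mate_pos": cassette_pos, "tlen": 0})
    rows.append({"query": query, "flag": FLAG_PAIRED | FLAG_REVERSE,
                 "ref": CASSETTE_REF, "pos": cassette_pos, "mate_ref": chrom,
                 "mate_pos": gpos, "tlen": 0})


def _spanning_pair(rows: list, query: str, chrom: str, center: int,
                   frag_len: int, read_len: int) -> None:
    start = center - frag_len // 2
    end = start + frag_len - 1
    flags = FLAG_PAIRED | FLAG_PROPER
    rows.append({"query": query, "flag": flags, "ref": chrom, "pos": start,
                 "mate_ref": chrom, "mate_pos": end - read_len + 1,
                 "tlen": frag_len})
    rows.append({"query": query, "flag": flags | FLAG_REVERSE, "ref": chrom,
                 "pos": end - read_len + 1, "mate_ref": chrom, "mate_pos": start,
                 "tlen": -frag_len})


def simulate_junction_reads(
    true_positions: list[tuple[str, int]],
    n_junction_reads: int = 10,
    n_concordant_spanning: int = 0,
    scatter_sd: float = 150.0,
    decoys: list[Decoy] | None = None,
    read_len: int = 150,
    frag_len: int = 400,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate alignment records for a set of true cassette insertions.

    For each true insertion, ``n_junction_reads`` discordant pairs are drawn
    with sides split ~evenly and genome-side positions offset outwards from
    the insertion point by |N(0, scatter_sd)| plus the read length, and
    ``n_concordant_spanning`` concordant genome pairs are laid across the
    position (a real insertion has none; nonzero values model junk
    junction fragments at an intact locus).  Decoys add one-sided junction
    clusters and concordant pairs spanning them.

    Returns ``(records, truth)`` where truth lists the planted insertions.
    """
    if n_junction_reads < 0 or n_concordant_spanning < 0:
        raise ValueError("read counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    truth_rows = []
    q = 0
    for chrom, pos in true_positions:
        truth_rows.append({"chrom": chrom, "pos": pos, "kind": "insertion"})
        sides = rng.permutation(
            ["left"] * (n_junction_reads // 2)
            + ["right"] * (n_junction_reads - n_junction_reads // 2)
        )
        for side in sides:
            offset = int(abs(rng.normal(0, scatter_sd))) + read_len
            gpos = pos - offset if side == "left" else pos + offset
            q += 1
            _junction_pair(rows, f"jr{q:06d}", chrom, max(1, gpos), side, read_len)
        for _ in range(n_concordant_spanning):
            q += 1
            _spanning_pair(rows, f"sp{q:06d}", chrom, pos, frag_len, read_len)
    for decoy in decoys or []:
        if decoy.n_reads < 0 or decoy.n_spanning < 0:
            raise ValueError("decoy counts must be non-negative")
        truth_rows.append({"chrom": decoy.chrom, "pos": decoy.pos, "kind": "decoy"})
        for _ in range(decoy.n_reads):
            offset = int(abs(rng.normal(0, scatter_sd))) + read_len
            gpos = (decoy.pos - offset if decoy.side == "left"
                    else decoy.pos + offset)
            q += 1
            _junction_pair(rows, f"jr{q:06d}", decoy.chrom, max(1, gpos),
                           decoy.side, read_len)
        for _ in range(decoy.n_spanning):
            q += 1
            _spanning_pair(rows, f"sp{q:06d}", decoy.chrom, decoy.pos, frag_len,
                           read_len)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, pd.DataFrame(truth_rows, columns=["chrom", "pos", "kind"])
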