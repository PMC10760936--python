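"""Synthetic TMT 11-plex abundance matrices with planted complex effects.

Raw reporter abundance of protein i in sample j is modeled as

    base_i * 2**effect(mutant_j, complex_i) * bias_j * exp(noise)

where ``effect`` is the planted per-mutant log2 effect on the protein's
complex, ``bias_j`` a channel loading factor, and noise is log-normal.
Replicates of each mutant are placed in different plexes, each plex holding
up to ten mutants plus one wild-type control channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..proteome import PlexDesign

__all__ = ["simulate_plex", "default_complex_annotation"]

DEFAULT_COMPLEXES = {
    "PSII": 12, "cytb6f": 8, "PSI": 10, "ATPase": 9, "LHC-I": 6,
    "LHC-II": 8, "Rubisco": 4, "ribosome": 20, "CCM": 6, "other": 40,
}


def default_complex_annotation(
    complexes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Protein -> complex annotation with the given subunit counts."""
    complexes = complexes or DEFAULT_COMPLEXES
    rows = []
    for cx, n in complexes.items():
        for i in range(n):
            rows.append({"protein": f"{cx}_p{i:02d}", "complex": cx})
    return pd.DataFrame(rows)


def _build_design(mutants: list[str], n_replicates: int,
                  rng: np.random.Generator, plex_size: int = 10) -> PlexDesign:
    rows = []
    plex_id = 0
    for rep in range(1, n_replicates + 1):
        order = list(rng.permutation(mutants))
        for start in range(0, len(order), plex_size):
            plex_id += 1
            group = order[start : start + plex_size]
            for ch, mutant in enumerate(group, start=1):
                rows.append({"plex": f"plex{plex_id:02d}", "channel": ch,
                             "sample": f"{mutant}_r{rep}", "mutant": mutant,
                             "replicate": rep, "is_wt": False})
            rows.append({"plex": f"plex{plex_id:02d}", "channel": 11,
                         "sample": f"WT_plex{plex_id:02d}", "mutant": "WT",
                         "replicate": rep, "is_wt": True})
    return PlexDesign(pd.DataFrame(rows))


def simulate_plex(
    effects: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    n_replicates: int = 2,
    channel_bias: dict[str, float] | float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlexDesign, pd.DataFrame]:
    """Simulate raw plexed abundances with known complex effects.

    Parameters
    ----------
    effects
        DataFrame indexed by mutant with one column per complex, holding the
        planted log2 effect (0 = unchanged).  Missing complexes default to 0.
    annotation
        Protein -> complex table; defaults to
        :func:`default_complex_annotation`.
    channel_bias
        Either a per-sample multiplicative loading factor mapping, or a
        log-normal sigma from which per-sample factors are drawn.
    noise_sd
        Log-normal measurement noise sigma (natural log scale).

    Returns ``(raw, design, truth)`` where truth is the dense effect matrix.
    """
    rng = np.random.default_rng(seed)
    annotation = annotation if annotation is not None else default_complex_annotation()
    mutants = [str(m) for m in effects.index]
    if "WT" in mutants:
        raise ValueError("'WT' is reserved for the control channel")
    design = _build_design(mutants, n_replicates, rng)

    proteins = annotation["protein"].tolist()
    prot_complex = annotation.set_index("protein")["complex"]
    complexes = sorted(prot_complex.unique())
    truth = effects.reindex(columns=complexes, fill_value=0.0).fillna(0.0)

    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=len(proteins))
    sample_meta = design.table.set_index("sample")
    samples = list(sample_meta.index)

    if isinstance(channel_bias, dict):
        bias = np.array([channel_bias.get(s, 1.0) for s in samples])
    elif channel_bias > 0:
        bias = rng.lognormal(0.0, channel_bias, size=len(samples))
    else:
        bias = np.ones(len(samples))

    effect_log2 = np.zeros((len(proteins), len(samples)))
    for j, s in enumerate(samples):
        mutant = sample_meta.loc[s, "mutant"]
        if mutant == "WT":
            continue
        per_complex = truth.loc[mutant]
        effect_log2[:, j] = per_complex[prot_complex.loc[proteins]].to_numpy()

    noise = (rng.normal(0.0, noise_sd, size=effect_log2.shape)
             if noise_sd > 0 else 0.0)
    raw = base[:, None] * 2.0 ** effect_log2 * bias[None, :] * np.exp(noise)
    raw_df = pd.DataFrame(raw, index=pd.Index(proteins, name="protein"),
                          columns=samples)
    return raw_df, design, truth
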