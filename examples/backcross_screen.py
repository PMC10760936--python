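"""Simulate a pooled backcross screen, score it, and estimate the FDR.

Generates a 500-strain pool in which 12.5% of barcoded insertions disrupt a
gene truly required for photosynthesis, runs the per-million normalization,
light/dark growth scoring and hit calling, and compares the GNRPD
negative-control FDR estimate against the ground truth.
"""

from photoscreen.barcodes import normalize_per_million
from photoscreen.fdr import define_gnrpd, estimate_fdr
from photoscreen.scoring import score_screen
from photoscreen.simulate import (
    TruthConfig,
    simulate_backcross_screen,
    simulate_prior_insertions,
)

config = TruthConfig(n_mutants=500, p_insertion_causal=0.125,
                     light_fitness_deficit=0.5, depth=1_000_000, seed=1)
library, counts, truth = simulate_backcross_screen(config)
result = score_screen(normalize_per_million(counts), library)

genes = result["genes"].set_index("gene")
hits = set(genes.index[genes["hit"]])
causal = truth.causal_genes

prior = simulate_prior_insertions(truth, seed=2)
gnrpd = define_gnrpd(prior)
fdr = estimate_fdr(len(hits), len(hits & gnrpd), len(gnrpd), config.n_mutants)

print(f"hit genes at the 0.34 threshold : {len(hits)}")
print(f"truly required genes recovered  : {len(hits & causal)}/{len(causal)}")
print(f"empirical FDR (from truth)      : {len(hits - causal) / len(hits):.3f}")
print(f"GNRPD-estimated FDR             : {fdr.fdr:.3f} "
      f"({fdr.n_gnrpd_hits}/{fdr.gnrpd_size} negative controls among hits)")
# A well-calibrated estimate tracks the empirical rate: most false hits come
# from second-site lesions genetically linked to the barcoded insertion.
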