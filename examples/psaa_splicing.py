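"""Quantify psaA splice forms from paired-end read placements.

Simulates a wild type dominated by mature message and a splicing-factor
mutant in which intron-2-spliced forms are almost absent, classifies every
read pair by the adjacent-exon rules, and recovers the underlying
splice-form mixture.
"""

from photoscreen.simulate import default_annotation, simulate_splice_reads
from photoscreen.transcripts import classify_psaA_pairs, estimate_splice_fractions

ann = default_annotation()
n = 40_000

wt = simulate_splice_reads(ann, (0.10, 0.10, 0.15, 0.65), n, seed=21)
mut = simulate_splice_reads(ann, (0.75, 0.20, 0.02, 0.03), n, seed=22)

for name, placements in (("wild type", wt), ("intron-2 factor mutant", mut)):
    counts = classify_psaA_pairs(placements, ann)
    fractions, _ = estimate_splice_fractions(counts.counts, ann)
    print(f"{name}:")
    print("  pair categories:", dict(counts.informative))
    print("  estimated splice-form mix:",
          {k: round(v, 3) for k, v in fractions.items()})
# Pairs bridging exon 1 and exon 3 witness fully mature mRNA; their collapse
# in the mutant, with precursor evidence rising, is the M-factor signature.
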