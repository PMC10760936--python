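# Methods

## The screen and its statistical model

The package analyzes a pooled backcross screen for photosynthesis genes in
*Chlamydomonas reinhardtii*. Each mutant strain carries one barcoded cassette
insertion and, typically, additional unmarked second-site mutations. Mating
the mutant to wild type makes each lesion segregate into the progeny
independently (probability 1/2), except lesions genetically linked to the
insertion, which co-segregate with probability 1 − r where r is the
recombination fraction. Only progeny that inherit the cassette are observed,
because the barcode *is* the cassette. The progeny pool is then grown
competitively under two regimes — photoautotrophic (minimal medium, high
light; requires photosynthesis) and heterotrophic (acetate, dark; does not) —
and strain abundances are read out by barcode sequencing. An insertion whose
barcode is depleted in the light relative to the dark is genetically linked
to a photosynthesis defect.

### Synthetic screen generator (`photoscreen.simulate.screen`)

The generator is the package's definition of the study conditions; its
defaults are fixed once and the tests run against them.

| parameter | default | meaning |
|---|---|---|
| `n_mutants` | 500 | barcoded strains (one gene each) |
| `mean_second_site` | 2.0 | Poisson mean of unmarked lesions per strain |
| `p_insertion_causal` | 0.125 | insertion disrupts a truly required gene |
| `p_second_site_causal` | 0.125 | a second-site lesion is photosynthesis-breaking |
| `p_linked` | 0.05 | a second-site lesion is linked to the insertion |
| `recomb_fraction` | 0.1 | recombination fraction for linked pairs |
| `light_fitness_deficit` (s) | 0.5 | per-doubling growth loss in the light |
| `n_doublings` (t) | 10 | competitive growth before harvest |
| `depth` | 10⁶ | reads per sample |
| `dispersion` | 0 | Dirichlet-multinomial overdispersion (0 = multinomial) |
| `abundance_sigma` | 0.5 | log-normal spread of starting pool frequencies |
| `n_experiments` × `n_replicates` | 3 × 3 | independent backcrosses × cultures per condition |

The 12.5% prevalence of truly required genes follows the screen's own
estimate (a 6.25% literature prevalence doubled for undiscovered genes); the
same rate is used for second-site lesions, treating them as random insertions
elsewhere in the genome. The second-site count distribution, the linkage
probability and the fitness deficit are assumptions of this package — the
underlying biology gives no parametric form — and were chosen to reproduce
the qualitative facts that most strains carry multiple mutations and that
linked second-site lesions are the dominant source of false positives.
Growth is deterministic exponential per genotype class (expected class
frequencies are computed exactly from the segregation probabilities),
followed by multinomial read sampling. Culture stochasticity, mating
efficiency differences, diploid carry-over and barcode PCR bias are *not*
modeled, so passing tests demonstrate correctness of the analysis under the
stated sampling model, not robustness to every artifact of the wet protocol.

### Growth score (`photoscreen.scoring`)

Per experiment, replicate counts (normalized to one million per sample) are
collapsed with the median (3 replicates) or geometric mean (2); the signal is
log2(light/dark). Entries with dark average below a read floor (7 in the
first experiment, 10 otherwise — earlier experiments were sequenced
shallower) are invalid. A culture format whose whole relative-growth
distribution is shifted (a re-arrayed pool of mostly-deficient mutants) can
be flagged for rescaling of its log2 ratios by 0.6. The growth score is the
median of the five strongest (most negative) valid ratios — robust to
occasional experiments where diploid contamination masks the phenotype — and
is undefined with fewer than two valid experiments. A gene is a hit when its
strongest insertion scores below log2(0.34) ≈ −1.55 with support in at least
two experiments.

Numerical choices: a 0.5 pseudocount is applied on the light side only when
the light average is zero, preserving strong-depletion signal without
infinities; a geometric mean containing a zero replicate is 0, and the dark
read floor then decides validity. "Support in two experiments" is read
literally as the dark-read floor being met in ≥ 2 experiments
(`support_rule="dark_reads"`); the alternative reading (ratio below
threshold in ≥ 2 experiments) is available as
`support_rule="below_threshold"`. Gene-level aggregation takes the minimum
(strongest) mutant score.

Sample-swap detection compares each sample's best correlate within its
labeled condition against its best correlate in the other condition (log1p
counts, Pearson); a margin of 0.05 suppresses near-ties created by the
swapped-in column itself. Pairing of multiple simultaneous swaps is greedy
by margin and intended for review, not blind correction.

### Empirical FDR (`photoscreen.fdr`)

Negative controls are genes whose disruption likely does not cause a
photosynthesis defect (GNRPD): genes with more than 20 insertions in a prior
survey of which at most two were phenotypic. If g of G such genes fall below
the hit threshold, the estimator assumes the same rate applies to all
N·(1 − 0.125) not-required starting genes:

    FDR = (g / G) · N (1 − frac_required) / H

with H the number of hits. The estimate is reported unclipped (with a
warning above 1) rather than silently truncated. On the synthetic screen the
estimate tracks the truth-computed FDR because GNRPD mutants are generated
by the same segregation-and-linkage process as every other non-required
gene; the acceptance suite checks agreement of the two means within 0.05
over 20 replicate screens.

## Colony phenotyping (`photoscreen.colonies`)

Colony arrays (16 × 24) are segmented by a green-dominance color rule
(G ≥ R + 10 and G ≥ B + 10); connected components are assigned to the
nearest grid position by centroid. Colony size is the green-pixel count
multiplied by a darkness factor: the mean green intensity is mapped linearly
from a pale reference (200 → factor 0) to a dark reference (60 → factor 1)
and clamped to [0.5, 1], so color can at most halve a colony's weight —
denser colonies are darker green, but area remains the primary growth
readout. Sizes are normalized per plate by the median of the ten largest
colonies (all nonzero colonies if fewer, with a warning), and photosynthetic
growth is the light/dark ratio of matched positions, median over replicate
plate pairs. Positions absent in the dark are undefined rather than zero.
The pixel classifier and the darkness map are configurable; grid positions
are fixed from plate geometry, not detected adaptively.

## Insertion-site validation (`photoscreen.insertions`)

Discordant primary read pairs with one mate on the cassette and one on the
genome mark insertion junctions. Genome-side positions are clustered per
chromosome with average-linkage hierarchical clustering cut at 3000 bp
(`scipy.cluster.hierarchy.fclusterdata`, criterion "distance"); the test
suite checks this against a from-scratch O(n³) UPGMA. Clusters with fewer
than four reads are dropped. A cluster is *validated* when reads come from
both flanks and at most 2 concordant pairs span the estimated breakpoint
(the cassette is far longer than a sequencing fragment, so a real insertion
cannot be spanned); one-sided or heavily spanned (≥ 10) clusters are
*unsupported*; intermediate spanning counts are *ambiguous* for manual
review. The breakpoint is the midpoint of the innermost left/right reads,
or one read length past the innermost read for one-sided clusters. The
numeric verdict thresholds codify what was originally a qualitative manual
evaluation; only the four-read floor is inherited as stated.

## Plexed proteome profiles (`photoscreen.proteome`)

Each 11-plex quantifies ten mutants plus one wild-type control channel.
Normalization: (1) per protein, divide by the plex's wild-type channel;
(2) per sample, divide by the sample's median over observed proteins
(channel loading); (3) per protein and plex, divide by the within-plex
median (batch effects; also re-centers proteins systematically off in the
shared frozen control). After step 3 every protein's per-plex median is
exactly 1. Missing values are masked, never imputed; all medians are over
observed values. The replicate of each mutant sits in a different plex with
a different random set of co-mutants, which is what makes the plex median a
valid null.

A complex score is the median log2 abundance over annotated subunits —
median, because multi-peptide proteins are individually reliable but single
subunits can still misbehave. A mutant has a complex phenotype only when
both replicates score ≤ −1 (two-fold, configurable); exactly one replicate
past the cutoff is flagged "discordant" (the policy being to add another
repeat rather than call). These numeric rules codify calls that were
originally made by heatmap inspection.

## psaA splice forms (`photoscreen.transcripts`)

psaA matures from separate chloroplast transcripts whose pairing forms two
group-II introns, excised in trans. Read pairs are classified by mate
placement: mates fully contained in adjacent exons ⇒ the intervening intron
is spliced; exon 1 + exon 3 ⇒ fully mature; any unspliced mate overlapping
intron sequence ⇒ precursor; junction-spanning (gapped) mates and
single-exon pairs are uninformative. Coordinates are 1-based inclusive
(GFF3). The synthetic annotation lays exons (240/120/900 bp) and introns
(650/700 bp) contiguously — a simplification of the real separated loci
that preserves all interval relations the classifier uses — and the insert
model (75 nt reads, fragment ~N(350, 60²) clipped to [150, 590]) keeps
introns longer than any fragment, so an unspliced molecule can never fake
an adjacent-exon pair.

Splice-form *fractions* are recovered from category counts by non-negative
least squares against the exact category-probability matrix, computed by
enumerating every (length, start) placement on each splice form under the
discrete insert model; the estimator's covariance follows from the
multinomial covariance of category frequencies by the delta method.

Per-gene chloroplast expression counts each mate once toward the gene
containing its midpoint, excludes non-coding RNA positions, and normalizes
by total chloroplast gene reads. Cross-experiment pooling rescales the
shallower experiment by the wild-type ratio between experiments, per
quantity by default (globally if requested). Nuclear expression normalizes
samples to 50 million reads, collapses replicates by geometric mean (zeros
replaced by 0.5 first), and reports log2(mutant/wild type).

## Curation ledger (`photoscreen.curation`)

Post-screen edits are data-driven tables, not hard-coded gene lists:
removals (mapping-unvalidated, co-occurring-with-established,
dual-hit-collapsed, expression-unaffected) and additions
(confidence4-validated, manual-reinstated), each with a reason and note.
Replaying the ledger reproduces the final list exactly, and the arithmetic
|final| = |start| − removals + additions is asserted on every pass.

## Problem sizes and determinism

Every generator takes an explicit seed and is bit-reproducible. The test
suite uses 300–500-gene screens at 0.5–1 M reads per sample, 20-replicate
calibration runs, 40 000 read pairs for splice recovery and 200 random
clustering instances; these sizes keep each property's sampling error an
order of magnitude below its tolerance while the whole suite runs in under
a minute on one core.

## Known limitations

- The segregation model treats lesions as independent except for pairwise
  linkage to the insertion; linkage among second-site lesions themselves is
  not modeled.
- Colony segmentation assumes a uniform, non-green background and
  non-overlapping colonies; it does not reproduce any particular historical
  script pixel-for-pixel.
- The spanning-pair verdict thresholds and the two-fold/two-replicate
  proteomic rule are this package's codifications of manual judgments and
  should be revisited for datasets with very different coverage.
- Barcode extraction is exact-match only (no mismatch rescue), by design:
  the library's barcodes are unique and the zero-error trim policy keeps
  counting deterministic.
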