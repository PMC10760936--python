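# photoscreen

Analysis toolkit for pooled backcross barcode screens and the multi-omics
follow-up used to identify photosynthesis genes in *Chlamydomonas
reinhardtii*.

Forward-genetic insertion libraries have a chronic confounder: most strains
carry second-site mutations, so a growth phenotype cannot be attributed to
the barcoded insertion directly. Backcrossing to wild type lets every lesion
segregate; pooled competitive growth of the progeny in photoautotrophic
light (TP, high light) versus heterotrophic dark (TAP, acetate) conditions
then measures, per barcode, whether the *insertion* is genetically linked to
a photosynthesis defect. This package implements that analysis end to end,
together with the orthogonal assays used to validate and characterize hits —
and a synthetic-data layer that generates every input with known ground
truth.

## What it computes

- **Barcode quantification** (`photoscreen.barcodes`): barcode extraction
  from FASTQ (fixed adapter context, quality floor 33, 21–23 nt), exact
  library filtering, per-million normalization.
- **Growth score and hits** (`photoscreen.scoring`): per-experiment
  log₂(light/dark) with dark-read floors, replicate averaging
  (median of 3 / geometric mean of 2), sample-swap detection, and the
  growth score — the median of the five strongest per-experiment ratios.
  A gene is a hit when its score falls below log₂ τ with τ = 0.34
  (−1.55 log₂) and ≥ 2 supporting experiments.
- **Empirical FDR** (`photoscreen.fdr`): calibration against GNRPD genes
  (negative controls with > 20 prior insertions, ≤ 2 phenotypic):

      FDR = (g/G) · N(1 − f_req) / H,  f_req = 0.125

- **Colony phenotyping** (`photoscreen.colonies`): green-pixel colony size
  with a 0.5–1 darkness adjustment, per-plate normalization by the median
  of the 10 largest colonies, light/dark growth ratio.
- **Insertion validation** (`photoscreen.insertions`): cassette junction
  extraction from discordant read pairs, average-linkage clustering at
  3 kb, verdicts from read support (≥ 4), two-sided flanking and absence of
  spanning concordant pairs.
- **Proteome profiles** (`photoscreen.proteome`): TMT 11-plex normalization
  (wild-type channel → sample median → plex median) and complex-depletion
  calls requiring both replicates below a two-fold cutoff.
- **psaA splice forms** (`photoscreen.transcripts`): paired-end
  classification of the trans-spliced psaA message (adjacent exons ⇒ intron
  spliced; exon 1 + exon 3 ⇒ mature), splice-form mixture estimation,
  chloroplast per-gene counts and nuclear log₂ expression ratios.
- **Hit curation** (`photoscreen.curation`): auditable removal/addition
  ledgers that replay deterministically.
- **Synthetic data** (`photoscreen.simulate`): generators for all of the
  above — segregation + competitive growth + multinomial sequencing, plate
  images, plexed abundances, splice-form read pairs, junction alignments —
  each returning the ground truth alongside the data.

## Worked example

```sh
python examples/backcross_screen.py
```

```
hit genes at the 0.34 threshold : 65
truly required genes recovered  : 58/58
empirical FDR (from truth)      : 0.108
GNRPD-estimated FDR             : 0.134 (7/352 negative controls among hits)
```

A 500-strain pool (12.5% of insertions truly required, fitness deficit
s = 0.5 over 10 doublings, 10⁶ reads/sample) is simulated, scored and
thresholded. All 58 truly required genes are recovered; the 7 extra hits are
insertions linked to causal second-site lesions — exactly the error mode the
GNRPD estimate quantifies, which is why the estimated FDR (0.134) tracks the
truth-computed one (0.108). The other scripts in `examples/` demonstrate
colony phenotyping, insertion-site verdicts, proteome depletion calls, psaA
splice-form recovery and the curation ledger, one capability each.

## Layout

```
src/photoscreen/        library modules (one per pipeline stage)
src/photoscreen/simulate/  ground-truth data generators
examples/               one narrative script per capability
tests/                  pytest suite (unit, property and acceptance tests)
scripts/acceptance.py   recomputes the headline statistic as JSON
docs/methods.md         model assumptions, parameters, numerical choices
```
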