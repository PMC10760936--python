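"""Splice-pair classification, gene counting and expression ratios."""

import numpy as np
import pandas as pd
import pytest

from photoscreen.simulate import (
    default_annotation,
    simulate_gene_placements,
    simulate_splice_reads,
)
from photoscreen.transcripts import (
    ChloroplastAnnotation,
    category_probabilities,
    classify_psaA_pairs,
    count_chloroplast_genes,
    estimate_splice_fractions,
    nuclear_expression_ratio,
    relative_and_rescale,
)


def pair(m1, m2, spliced1=False, spliced2=False):
    return {"m1_start": m1[0], "m1_end": m1[1], "m1_spliced": spliced1,
            "m2_start": m2[0], "m2_end": m2[1], "m2_spliced": spliced2}


class TestClassificationRules:
    """Hand-constructed placements exercising the stated pair rules.

    Default annotation: exon1 2001-2240, intron1 2241-2890, exon2 2891-3010,
    intron2 3011-3710, exon3 3711-4610.
    """

    @pytest.fixture()
    def ann(self):
        return default_annotation()

    @pytest.mark.parametrize(
        "m1,m2,expected",
        [
            ((2010, 2084), (2900, 2974), "intron1_spliced"),  # exon1 & exon2
            ((2900, 2974), (3800, 3874), "intron2_spliced"),  # exon2 & exon3
            ((2010, 2084), (3800, 3874), "mature"),  # exon1 & exon3
            ((2300, 2374), (2900, 2974), "precursor"),  # mate in intron 1
            ((2010, 2084), (3100, 3174), "precursor"),  # mate in intron 2
            ((2900, 2930), (2940, 3010), "uninformative"),  # single exon
            ((1500, 1574), (2010, 2084), "uninformative"),  # outside psaA
        ],
    )
    def test_pair_rules(self, ann, m1, m2, expected):
        counts = classify_psaA_pairs(pd.DataFrame([pair(m1, m2)]), ann)
        assert counts.labels.iloc[0] == expected

    def test_junction_spanning_mate_uninformative(self, ann):
        # gapped mate across intron 1 (spliced alignment)
        placements = pd.DataFrame([pair((2200, 2930), (2940, 3010),
                                        spliced1=True)])
        counts = classify_psaA_pairs(placements, ann)
        assert counts.labels.iloc[0] == "uninformative"

    def test_unplaced_rows_counted(self, ann):
        placements = pd.DataFrame([pair((2010, 2084), (np.nan, np.nan))])
        counts = classify_psaA_pairs(placements, ann)
        assert counts.counts["unplaced"] == 1

    def test_category_conservation(self, ann):
        placements = simulate_splice_reads(ann, (0.3, 0.2, 0.2, 0.3), 5000,
                                           seed=0)
        counts = classify_psaA_pairs(placements, ann)
        assert counts.counts.sum() == len(placements)


class TestGeneratorEdgeCases:
    @pytest.fixture()
    def ann(self):
        return default_annotation()

    def test_all_mature_yields_no_precursor_pairs(self, ann):
        placements = simulate_splice_reads(ann, (0, 0, 0, 1), 8000, seed=1)
        counts = classify_psaA_pairs(placements, ann)
        assert counts.counts["precursor"] == 0
        # exon1/exon3 pairs exist and are called mature
        assert counts.counts["mature"] > 0

    def test_pure_precursor_never_fakes_splicing(self, ann):
        """Introns exceed the maximum insert, so an unspliced molecule can
        never produce an adjacent-exon pair without intron coverage."""
        placements = simulate_splice_reads(ann, (1, 0, 0, 0), 8000, seed=2)
        counts = classify_psaA_pairs(placements, ann)
        assert counts.counts["intron1_spliced"] == 0
        assert counts.counts["intron2_spliced"] == 0
        assert counts.counts["mature"] == 0

    def test_fraction_validation(self, ann):
        with pytest.raises(ValueError, match="summing to 1"):
            simulate_splice_reads(ann, (0.5, 0.5, 0.5, 0.5), 10)

    def test_reproducible(self, ann):
        a = simulate_splice_reads(ann, (0.25, 0.25, 0.25, 0.25), 500, seed=5)
        b = simulate_splice_reads(ann, (0.25, 0.25, 0.25, 0.25), 500, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestFractionRecovery:
    def test_category_probabilities_columns_normalized(self, chloro_annotation):
        m = category_probabilities(chloro_annotation)
        assert np.allclose(m.sum(axis=0), 1.0)
        # diagnostic structure: precursor molecules never produce spliced
        # or mature evidence
        assert m.loc["intron1_spliced", "precursor"] == 0
        assert m.loc["mature", "precursor"] == 0

    def test_planted_mixture_recovered(self, chloro_annotation):
        planted = np.array([0.4, 0.1, 0.2, 0.3])
        placements = simulate_splice_reads(chloro_annotation, tuple(planted),
                                           30_000, seed=7)
        counts = classify_psaA_pairs(placements, chloro_annotation)
        frac, cov = estimate_splice_fractions(counts.counts, chloro_annotation)
        half_width = 2.576 * np.sqrt(np.diag(cov))
        assert (np.abs(frac.to_numpy() - planted) <= half_width).all()


class TestGeneCounts:
    def test_forced_arithmetic(self, chloro_annotation):
        placements = pd.DataFrame([
            pair((6101, 6175), (6301, 6375)),  # psbA
            pair((6501, 6575), (6701, 6775)),  # psbA
            pair((8101, 8175), (8301, 8375)),  # rbcL
            pair((8501, 8575), (8701, 8775)),  # rbcL
        ])
        counts = count_chloroplast_genes(placements, chloro_annotation)
        assert counts["psbA"] == pytest.approx(0.5)
        assert counts["rbcL"] == pytest.approx(0.5)
        assert counts.sum() == pytest.approx(1.0)

    def test_ncrna_mates_excluded(self, chloro_annotation):
        placements = pd.DataFrame([
            pair((6101, 6175), (12101, 12175)),  # psbA + tscA (ncRNA)
        ])
        counts = count_chloroplast_genes(placements, chloro_annotation)
        assert counts["psbA"] == 1.0
        assert counts.attrs["total_reads"] == 1

    def test_empty_sample_errors(self, chloro_annotation):
        with pytest.raises(ValueError, match="no chloroplast reads"):
            count_chloroplast_genes(pd.DataFrame(
                columns=["m1_start", "m1_end", "m2_start", "m2_end"]),
                chloro_annotation)

    def test_known_mixture_recovered(self, chloro_annotation):
        mixture = {"psaA": 0.5, "psbA": 0.3, "rbcL": 0.2}
        placements = simulate_gene_placements(chloro_annotation, mixture,
                                              20_000, seed=3)
        counts = count_chloroplast_genes(placements, chloro_annotation)
        for gene, frac in mixture.items():
            ci = 2.576 * np.sqrt(frac * (1 - frac) / 40_000)
            assert abs(counts[gene] - frac) < ci + 0.005


class TestWtRelativeRescale:
    def _inputs(self):
        values = pd.DataFrame(
            {"wt_e1": [0.2], "mut_e1": [0.02], "wt_e2": [1.0],
             "mut_e2": [0.1]}, index=["mature_psaA"])
        meta = pd.DataFrame(
            {"strain": ["WT", "mut", "WT", "mut"],
             "experiment": ["e1", "e1", "e2", "e2"]},
            index=["wt_e1", "mut_e1", "wt_e2", "mut_e2"])
        return values, meta

    def test_wt_relative_readout(self):
        values, meta = self._inputs()
        out = relative_and_rescale(values, meta)
        assert out["wt_relative"].loc["mature_psaA", "mut_e1"] == \
            pytest.approx(0.1)
        assert out["wt_relative"].loc["mature_psaA", "wt_e2"] == \
            pytest.approx(1.0)

    def test_cross_experiment_scaling_aligns_wt(self):
        values, meta = self._inputs()
        out = relative_and_rescale(values, meta, reference_experiment="e2")
        pooled = out["pooled"]
        assert pooled.loc["mature_psaA", "wt_e1"] == pytest.approx(1.0)
        assert pooled.loc["mature_psaA", "mut_e1"] == pytest.approx(0.1)

    def test_wt_zero_masks_quantity(self):
        values, meta = self._inputs()
        values.loc["mature_psaA", "wt_e1"] = 0.0
        out = relative_and_rescale(values, meta)
        assert np.isnan(out["wt_relative"].loc["mature_psaA", "mut_e1"])

    def test_planted_intron2_depletion_recovered(self, chloro_annotation):
        """A 96% loss of intron-2-spliced forms reads out as ~0.04 of WT."""
        wt_frac = (0.2, 0.1, 0.2, 0.5)
        mut_frac = (0.2 / 0.3, 0.1 / 0.3, 0.2 * 0.04 / 0.3, 0.5 * 0.04 / 0.3)
        mut_frac = tuple(np.array(mut_frac) / np.sum(mut_frac))
        n = 50_000
        wt = classify_psaA_pairs(
            simulate_splice_reads(chloro_annotation, wt_frac, n, seed=8),
            chloro_annotation).counts
        mut = classify_psaA_pairs(
            simulate_splice_reads(chloro_annotation, mut_frac, n, seed=9),
            chloro_annotation).counts
        # intron-2-spliced evidence per sequenced pair, relative to WT
        values = pd.DataFrame({"wt_s": wt / n, "mut_s": mut / n}).loc[
            ["intron2_spliced", "mature"]]
        meta = pd.DataFrame({"strain": ["WT", "mut"],
                             "experiment": ["e1", "e1"]},
                            index=["wt_s", "mut_s"])
        out = relative_and_rescale(values, meta)
        rel = out["wt_relative"]["mut_s"]
        # the depleted forms are at a few percent of WT, with the caveat
        # that renormalization of the mutant mixture inflates them slightly
        assert rel["intron2_spliced"] < 0.15
        assert rel["mature"] < 0.15


class TestNuclearRatios:
    def _run(self, mut_reps, wt_reps):
        counts = pd.DataFrame(
            {"m1": [mut_reps[0]], "m2": [mut_reps[1]],
             "w1": [wt_reps[0]], "w2": [wt_reps[1]]}, index=["t1"])
        # pad with a filler transcript keeping per-sample totals equal
        counts.loc["t2"] = 1400 - counts.loc["t1"]
        meta = pd.DataFrame({"strain": ["mut", "mut", "WT", "WT"],
                             "replicate": [1, 2, 1, 2]},
                            index=["m1", "m2", "w1", "w2"])
        return nuclear_expression_ratio(counts, meta)

    def test_equal_geomeans_give_zero(self):
        out = self._run((100, 400), (200, 200))
        assert out.loc["t1", "mut"] == pytest.approx(0.0, abs=0.02)

    def test_fourfold_depletion(self):
        out = self._run((50, 50), (200, 200))
        assert out.loc["t1", "mut"] == pytest.approx(-2.0, abs=0.02)

    def test_absent_transcript_masked(self):
        out = self._run((0, 0), (0, 0))
        assert np.isnan(out.loc["t1", "mut"])


class TestAnnotationIO:
    def test_gff3_roundtrip(self, tmp_path, chloro_annotation):
        path = tmp_path / "chloro.gff3"
        chloro_annotation.to_gff3(path)
        loaded = ChloroplastAnnotation.from_gff3(path)
        assert loaded.exons == chloro_annotation.exons
        assert loaded.introns == chloro_annotation.introns
        pd.testing.assert_frame_equal(
            loaded.genes.sort_index(),
            chloro_annotation.genes.sort_index(), check_like=True)

    def test_exon_overlap_rejected(self):
        genes = pd.DataFrame({"start": [1], "end": [100], "kind": ["gene"]},
                             index=["psaA"])
        with pytest.raises(ValueError, match="overlap"):
            ChloroplastAnnotation(genes=genes,
                                  exons=((1, 50), (40, 60), (70, 100)),
                                  introns=((51, 39), (61, 69)))
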