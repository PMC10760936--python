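"""Growth-score pipeline: averaging, ratios, scores, hit calling, swaps."""

import numpy as np
import pandas as pd
import pytest

from photoscreen.barcodes import normalize_per_million
from photoscreen.containers import DARK, LIGHT, BarcodeLibrary, CountMatrix, \
    make_sample_sheet
from photoscreen.scoring import (
    ScreenParams,
    apply_swaps,
    call_hits,
    condition_average,
    detect_swaps,
    experiment_ratio,
    growth_score,
    score_screen,
)


def make_matrix(columns: dict, samples: pd.DataFrame) -> CountMatrix:
    counts = pd.DataFrame(columns)
    counts.index = [f"b{i}" for i in range(len(counts))]
    return CountMatrix(counts, samples)


class TestConditionAverage:
    def test_geometric_mean_of_two(self):
        samples = make_sample_sheet(1, 2)
        cm = make_matrix({s: v for s, v in zip(samples.index, [[4], [9], [4], [9]])},
                         samples)
        avg = condition_average(cm)
        assert avg[("exp1", LIGHT)].iloc[0] == pytest.approx(6.0)

    def test_median_of_three(self):
        samples = make_sample_sheet(1, 3)
        vals = {s: [v] for s, v in zip(samples.index, [1, 5, 100, 1, 5, 100])}
        avg = condition_average(make_matrix(vals, samples))
        assert avg[("exp1", LIGHT)].iloc[0] == 5

    def test_geometric_mean_with_zero_is_zero(self):
        samples = make_sample_sheet(1, 2)
        vals = {s: [v] for s, v in zip(samples.index, [0, 8, 0, 8])}
        avg = condition_average(make_matrix(vals, samples))
        assert avg[("exp1", LIGHT)].iloc[0] == 0.0

    def test_single_replicate_passthrough_warns(self):
        samples = make_sample_sheet(1, 1)
        vals = {s: [v] for s, v in zip(samples.index, [10, 20])}
        with pytest.warns(UserWarning, match="single replicate"):
            avg = condition_average(make_matrix(vals, samples))
        assert avg[("exp1", LIGHT)].iloc[0] == 10

    def test_four_replicates_median_warns(self):
        samples = make_sample_sheet(1, 4)
        vals = {s: [v] for s, v in
                zip(samples.index, [1, 2, 3, 100, 1, 2, 3, 100])}
        with pytest.warns(UserWarning, match="4 replicates"):
            avg = condition_average(make_matrix(vals, samples))
        assert avg[("exp1", LIGHT)].iloc[0] == 2.5


class TestExperimentRatio:
    def _avg(self, light, dark, exp="exp1"):
        return pd.DataFrame(
            {(exp, LIGHT): [light], (exp, DARK): [dark]},
        ).rename_axis(columns=["experiment", "condition"])

    def test_simple_log2(self):
        ratios, valid = experiment_ratio(self._avg(50, 100))
        assert ratios.iloc[0, 0] == pytest.approx(-1.0)
        assert valid.iloc[0, 0]

    def test_dark_floor_first_experiment(self):
        ratios, valid = experiment_ratio(self._avg(50, 6))
        assert not valid.iloc[0, 0]
        assert np.isnan(ratios.iloc[0, 0])

    def test_dark_floor_other_experiments(self):
        avg = pd.DataFrame({
            ("exp1", LIGHT): [50], ("exp1", DARK): [9],
            ("exp2", LIGHT): [50], ("exp2", DARK): [9],
        }).rename_axis(columns=["experiment", "condition"])
        ratios, valid = experiment_ratio(avg)
        assert valid.loc[0, "exp1"]  # floor 7 for the first experiment
        assert not valid.loc[0, "exp2"]  # floor 10 for the rest

    def test_np_rescaling_on_log2_scale(self):
        params = ScreenParams(np_experiments=("exp1",))
        ratios, _ = experiment_ratio(self._avg(12.5, 100), params)  # raw -3
        assert ratios.iloc[0, 0] == pytest.approx(-1.8)

    def test_zero_light_uses_pseudocount(self):
        ratios, valid = experiment_ratio(self._avg(0, 128))
        assert ratios.iloc[0, 0] == pytest.approx(np.log2(0.5 / 128))
        assert valid.iloc[0, 0]


class TestGrowthScore:
    def _table(self, values):
        ratios = pd.DataFrame([values],
                              columns=[f"exp{i}" for i in range(len(values))])
        valid = ~ratios.isna()
        return ratios, valid

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-4, -3, -2.5, -2, -1, 0], -2.5),  # median of the five lowest
            ([-1, 0], -0.5),  # fewer than five: all of them
        ],
    )
    def test_median_of_strongest(self, values, expected):
        ratios, valid = self._table(values)
        out = growth_score(ratios, valid)
        assert out["score"].iloc[0] == pytest.approx(expected)

    def test_single_valid_experiment_undefined(self):
        ratios, valid = self._table([-3.0, np.nan, np.nan])
        out = growth_score(ratios, valid)
        assert np.isnan(out["score"].iloc[0])

    def test_invariant_to_experiment_order(self, rng):
        vals = rng.normal(size=(10, 6))
        ratios = pd.DataFrame(vals, columns=[f"exp{i}" for i in range(6)])
        valid = pd.DataFrame(True, index=ratios.index, columns=ratios.columns)
        a = growth_score(ratios, valid)["score"]
        perm = list(rng.permutation(ratios.columns))
        b = growth_score(ratios[perm], valid[perm])["score"]
        assert np.allclose(a, b)


class TestCallHits:
    def _setup(self, score, ratios_row):
        n_exp = len(ratios_row)
        ratios = pd.DataFrame([ratios_row], index=["b0"],
                              columns=[f"exp{i}" for i in range(n_exp)])
        valid = ~ratios.isna()
        scores = pd.DataFrame({"score": [score],
                               "n_valid": [valid.sum(axis=1).iloc[0]]},
                              index=["b0"])
        lib = BarcodeLibrary(pd.DataFrame({
            "barcode": ["b0" + "A" * 20], "mutant": ["m0"], "gene": ["g0"],
            "confidence": [1]}))
        lib.table.loc[0, "barcode"] = "b0".ljust(22, "A")
        scores.index = [lib.table["barcode"].iloc[0]]
        ratios.index = scores.index
        valid.index = scores.index
        return scores, ratios, valid, lib

    def test_hit_below_threshold_with_support(self):
        scores, ratios, valid, lib = self._setup(-2.0, [-2.1, -2.0, -1.9])
        _, genes = call_hits(scores, ratios, valid, lib)
        assert genes["hit"].iloc[0]

    def test_weak_score_not_a_hit(self):
        scores, ratios, valid, lib = self._setup(-1.0, [-1.0, -1.0, -1.0])
        _, genes = call_hits(scores, ratios, valid, lib)
        assert not genes["hit"].iloc[0]

    def test_strong_score_one_qualifying_experiment_not_a_hit(self):
        # under the ratio-based support rule, one sub-threshold experiment
        # is not enough however strong the aggregate score
        scores, ratios, valid, lib = self._setup(-2.0, [-3.5, -0.5])
        params = ScreenParams(support_rule="below_threshold")
        _, genes = call_hits(scores, ratios, valid, lib, params)
        assert not genes["hit"].iloc[0]

    def test_gene_score_is_strongest_mutant(self):
        lib = BarcodeLibrary(pd.DataFrame({
            "barcode": ["A" * 22, "C" * 22],
            "mutant": ["m0", "m1"], "gene": ["g0", "g0"],
            "confidence": [1, 1]}))
        idx = lib.table["barcode"]
        ratios = pd.DataFrame({"exp0": [-2.0, -0.5], "exp1": [-2.0, -0.5]},
                              index=idx)
        valid = pd.DataFrame(True, index=idx, columns=ratios.columns)
        scores = pd.DataFrame({"score": [-2.0, -0.5], "n_valid": [2, 2]},
                              index=idx)
        _, genes = call_hits(scores, ratios, valid, lib)
        assert genes["score"].iloc[0] == -2.0
        assert genes["n_mutants"].iloc[0] == 2


class TestMonotonicityAndInvariance:
    def test_lowering_light_counts_never_raises_score(self, small_screen):
        _, library, cm, _ = small_screen
        nm = normalize_per_million(cm)
        base = score_screen(nm, library)["scores"]["score"]
        poked = nm.copy()
        light_cols = poked.sample_ids(condition=LIGHT)
        poked.counts[light_cols] *= 0.5
        lowered = score_screen(poked, library)["scores"]["score"]
        both = ~(base.isna() | lowered.isna())
        assert (lowered[both] <= base[both] + 1e-9).all()

    def test_row_order_invariance(self, small_screen):
        _, library, cm, _ = small_screen
        nm = normalize_per_million(cm)
        base = score_screen(nm, library)["scores"]["score"]
        shuffled = CountMatrix(nm.counts.iloc[::-1], nm.samples)
        flipped = score_screen(shuffled, library)["scores"]["score"]
        pd.testing.assert_series_equal(base.sort_index(), flipped.sort_index())


class TestSwapDetection:
    def test_planted_swap_recovered_exactly(self, small_screen):
        _, _, cm, _ = small_screen
        nm = normalize_per_million(cm)
        swapped = apply_swaps(nm, [("exp1_light_r2", "exp3_dark_r1")])
        report = detect_swaps(swapped)
        assert len(report.pairs) == 1
        assert set(report.pairs.iloc[0][["sample_a", "sample_b"]]) == {
            "exp1_light_r2", "exp3_dark_r1"}

    def test_clean_screen_unflagged(self, small_screen):
        _, _, cm, _ = small_screen
        report = detect_swaps(normalize_per_million(cm))
        assert report.pairs.empty

    def test_apply_swaps_roundtrip(self, small_screen):
        _, _, cm, _ = small_screen
        nm = normalize_per_million(cm)
        back = apply_swaps(apply_swaps(nm, [("exp1_light_r1", "exp2_dark_r2")]),
                           [("exp1_light_r1", "exp2_dark_r2")])
        pd.testing.assert_frame_equal(nm.counts, back.counts)

    def test_constant_columns_skipped_with_warning(self):
        samples = make_sample_sheet(1, 2)
        counts = pd.DataFrame(
            {samples.index[0]: [5, 5, 5], samples.index[1]: [1, 2, 3],
             samples.index[2]: [1, 2, 3], samples.index[3]: [1, 2, 4]})
        report = detect_swaps(CountMatrix(counts, samples))
        assert any("constant" in w for w in report.warnings)

    def test_single_replicate_yields_empty_report(self):
        samples = make_sample_sheet(1, 1)
        counts = pd.DataFrame({samples.index[0]: [1, 2], samples.index[1]: [2, 1]})
        report = detect_swaps(CountMatrix(counts, samples))
        assert report.pairs.empty
        assert any("fewer than 2" in w for w in report.warnings)
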