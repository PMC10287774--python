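"""Residual validation, group comparisons, and latitude analyses."""

import numpy as np
import pandas as pd
import pytest

from somoc.evaluate import (
    binned_latitude_trends,
    compare_ces,
    compare_sedimentary,
    latitude_regressions,
    summarize_validation,
    validate_equation_on_region,
)
from somoc.fit import RegionSummary
from somoc.registry import ConversionEquation
from somoc.synthetic import RegionSpec, generate_dataset
from tests.conftest import make_samples

HALF = ConversionEquation("half", "region", "X", "linear", {"m": 0.5, "b": 0.0})


class TestValidateEquation:
    def test_zero_residuals(self):
        som = np.array([10.0, 20, 30, 40])
        rep = validate_equation_on_region(HALF, make_samples(som, 0.5 * som))
        assert rep.central_tendency == 0.0
        assert not rep.different_from_zero

    def test_large_shift_detected(self):
        rng = np.random.default_rng(8)
        som = rng.uniform(10, 80, 50)
        oc = 0.5 * som + rng.normal(5.0, 1.0, 50)  # residuals ~ N(5, 1)
        rep = validate_equation_on_region(HALF, make_samples(som, oc))
        assert rep.different_from_zero and rep.p_value < 1e-6
        assert rep.test_used == "one_sample_t"
        assert rep.central_tendency == pytest.approx(5.0, abs=0.6)

    def test_symmetric_alternating_residuals_take_wilcoxon_path(self):
        som = np.full(12, 20.0)
        som[::2] = 40.0
        resid = np.tile([1.0, -1.0], 6)
        rep = validate_equation_on_region(HALF, make_samples(som, 0.5 * som + resid))
        assert rep.test_used == "wilcoxon_signed_rank"  # two-point residuals fail Shapiro
        assert rep.p_value > 0.5
        assert not rep.different_from_zero
        assert rep.central_tendency == 0.0  # median on the nonparametric path

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            validate_equation_on_region(HALF, make_samples([10, 20], [5, 10]))

    def test_missing_oc_rejected(self):
        df = make_samples([10, 20, 30], [5, np.nan, 15])
        with pytest.raises(ValueError):
            validate_equation_on_region(HALF, df)

    def test_type_i_error_calibrated(self):
        """Under true-null residuals the gated test rejects at ~alpha."""
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 400
        som = np.linspace(10, 80, 20)
        base = make_samples(som, som)  # oc overwritten per replicate
        for _ in range(n_rep):
            base = base.copy()
            base["oc"] = 0.5 * som + rng.normal(0, 1.0, som.size)
            rep = validate_equation_on_region(HALF, base)
            rejections += rep.different_from_zero
        assert 0.02 <= rejections / n_rep <= 0.08


class TestSummarize:
    def test_abs_sum_and_mean(self):
        reps = [
            validate_equation_on_region(HALF, make_samples(
                np.array([10.0, 20, 30, 40]), 0.5 * np.array([10.0, 20, 30, 40]) + c,
                region=r))
            for r, c in [("A", 1.0), ("B", -1.0), ("C", 2.0)]
        ]
        summary = summarize_validation(reps, "test")
        assert summary.abs_sum == pytest.approx(4.0)
        assert summary.abs_mean == pytest.approx(4.0 / 3.0)
        assert summary.abs_mean * summary.n_regions == pytest.approx(summary.abs_sum)

    def test_all_zero_tendencies(self):
        som = np.array([10.0, 20, 30])
        reps = [
            validate_equation_on_region(HALF, make_samples(som, 0.5 * som, region=r))
            for r in "AB"
        ]
        summary = summarize_validation(reps)
        assert summary.abs_sum == 0.0 and summary.abs_mean == 0.0

    def test_duplicate_regions_rejected(self):
        som = np.array([10.0, 20, 30])
        rep = validate_equation_on_region(HALF, make_samples(som, 0.5 * som, region="A"))
        with pytest.raises(ValueError, match="duplicate"):
            summarize_validation([rep, rep])


class TestGroupComparisons:
    @staticmethod
    def _two_group_frame(rng, mean_a=0.46, sd_a=0.07, n_a=300, mean_b=0.32,
                         sd_b=0.12, n_b=150):
        som = np.full(n_a + n_b, 50.0)
        ratio = np.concatenate([
            np.clip(rng.normal(mean_a, sd_a, n_a), 0.01, 0.99),
            np.clip(rng.normal(mean_b, sd_b, n_b), 0.01, 0.99),
        ])
        df = make_samples(som, ratio * som)
        df["sedimentary"] = ["carbonate"] * n_a + ["terrigenous"] * n_b
        df["ces"] = ["CE"] * n_a + ["TD"] * n_b
        return df

    def test_identical_groups_t_zero(self):
        som = np.full(8, 40.0)
        ratio = np.tile([0.35, 0.40, 0.45, 0.50], 2)  # same values in each group
        df = make_samples(som, ratio * som)
        df["sedimentary"] = ["carbonate"] * 4 + ["terrigenous"] * 4
        res = compare_sedimentary(df)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 6

    def test_separated_groups_significant(self):
        df = self._two_group_frame(np.random.default_rng(12))
        res = compare_sedimentary(df)
        assert res.p_value < 0.001
        assert res.group_means["carbonate"] > res.group_means["terrigenous"]

    def test_missing_group_rejected(self):
        som = np.full(4, 40.0)
        df = make_samples(som, 0.4 * som)
        df["sedimentary"] = "carbonate"
        with pytest.raises(ValueError, match="both"):
            compare_sedimentary(df)

    def test_f_equals_t_squared_for_two_groups(self):
        df = self._two_group_frame(np.random.default_rng(77))
        t = compare_sedimentary(df)
        a = compare_ces(df)  # exactly two CES groups in this frame
        assert a.f_statistic == pytest.approx(t.t_statistic**2, rel=1e-8)
        assert a.p_value == pytest.approx(t.p_value, rel=1e-6)

    def test_extreme_separation_all_tukey_significant(self):
        rng = np.random.default_rng(4)
        som = np.full(60, 50.0)
        ratio = np.concatenate([
            rng.normal(0.2, 0.01, 30), rng.normal(0.7, 0.01, 30)
        ])
        df = make_samples(som, ratio * som)
        df["ces"] = ["TD"] * 30 + ["CE"] * 30
        res = compare_ces(df)
        assert res.tukey["reject"].all()
        assert res.letters["CE"] != res.letters["TD"]

    def test_null_groups_share_letters(self):
        rng = np.random.default_rng(99)
        som = np.full(120, 50.0)
        ratio = rng.normal(0.45, 0.05, 120)
        df = make_samples(som, np.clip(ratio, 0.01, 0.99) * som)
        df["ces"] = np.repeat(["TD", "TE", "CE", "COC"], 30)
        res = compare_ces(df)
        # same-distribution groups: no pair should separate at alpha=0.05
        assert len(set(res.letters.values())) == 1

    def test_single_group_rejected(self):
        som = np.full(4, 40.0)
        df = make_samples(som, 0.4 * som)
        df["ces"] = "CE"
        with pytest.raises(ValueError):
            compare_ces(df)


class TestLatitude:
    @staticmethod
    def _summaries(lats, slopes, soms):
        return [
            RegionSummary(region=f"R{i}", mean_som=ms, n=20, slope=s, latitude=lat)
            for i, (lat, s, ms) in enumerate(zip(lats, slopes, soms))
        ]

    def test_exact_lines_recovered(self):
        lats = np.array([25.0, 26, 27, 28, 29])
        summ = self._summaries(lats, 0.9 - 0.02 * lats, 100 - 2.5 * lats)
        fit_slope, fit_som = latitude_regressions(summ)
        assert fit_slope.coefficients["m"] == pytest.approx(-0.02, abs=1e-10)
        assert fit_som.coefficients["m"] == pytest.approx(-2.5, abs=1e-9)
        assert fit_slope.r_squared == pytest.approx(1.0)

    def test_subset_restriction(self):
        lats = np.array([25.0, 26, 27, 28, 29])
        summ = self._summaries(lats, 0.9 - 0.02 * lats, 100 - 2.5 * lats)
        sub = latitude_regressions(summ, subset=["R0", "R1", "R2"])
        assert sub[0].n == 3

    def test_shuffled_latitudes_destroy_association(self):
        rng = np.random.default_rng(0)
        lats = np.linspace(24, 30, 11)
        slopes = 0.9 - 0.02 * lats + rng.normal(0, 0.001, 11)
        shuffled = rng.permutation(lats)
        summ = self._summaries(shuffled, slopes, np.full(11, 40.0))
        fit_slope, _ = latitude_regressions(summ)
        assert fit_slope.r_squared < 0.3

    def test_constant_latitude_rejected(self):
        summ = self._summaries([25.0] * 4, [0.4] * 4, [40.0] * 4)
        with pytest.raises(ValueError):
            latitude_regressions(summ)

    def test_missing_latitude_rejected(self):
        summ = [RegionSummary(region="A", mean_som=40, n=5, slope=0.4, latitude=None)] * 3
        with pytest.raises(ValueError, match="latitude"):
            latitude_regressions(summ)


def _flat_slope_specs(base_slope=0.45, n_regions=8, n_samples=120):
    return [
        RegionSpec(
            region=f"R{i}", ces="CE", sedimentary="carbonate", latitude=float(lat),
            n_samples=n_samples, som_mean=40.0, som_sd=15.0, som_range=(2.0, 90.0),
            true_slope=base_slope, true_intercept=0.0, noise_sd=2.0,
        )
        for i, lat in enumerate(np.linspace(24.5, 30.0, n_regions))
    ]


class TestBinnedTrends:
    def test_latitude_independent_generator_near_zero(self):
        df = generate_dataset(_flat_slope_specs(), 11)
        res = binned_latitude_trends(df)
        spread = res.table["slope_per_degree"].std() / np.sqrt(len(res.table))
        assert abs(res.mean_slope_all) <= 3 * spread + 0.005

    def test_built_in_effect_recovered(self):
        df = generate_dataset(
            _flat_slope_specs(), 11, ratio_latitude_effect=-0.04, ref_latitude=27.0
        )
        res = binned_latitude_trends(df)
        assert res.mean_slope_significant == pytest.approx(-0.04, abs=0.01)

    def test_single_populated_bin(self):
        rng = np.random.default_rng(1)
        som = rng.uniform(32, 38, 30)
        df = make_samples(som, 0.45 * som + rng.normal(0, 1, 30))
        df["region"] = np.repeat(["A", "B", "C"], 10)
        df["latitude"] = np.repeat([25.0, 27.0, 29.0], 10)
        res = binned_latitude_trends(df)
        assert len(res.table) == 1
        assert res.table["som_bin_low"].iloc[0] == 30.0
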