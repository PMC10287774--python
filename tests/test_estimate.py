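"""Hierarchical selection, OC prediction, stocks, and stock comparisons."""

import numpy as np
import pandas as pd
import pytest

from somoc.estimate import (
    HierarchicalConverter,
    compare_stock_estimates,
    compute_stock,
    estimate_oc,
    predict_dataset,
    select_equation,
)
from somoc.fit import RegionSummary, fit_slope_vs_mean_som
from somoc.registry import ConversionEquation, EquationRegistry
from tests.conftest import make_samples

TIER_ORDER = ["regional", "ces", "sedimentary", "general", "slope_from_mean_som"]


class TestSelection:
    def test_region_context(self, registry):
        eq, tier = select_equation(registry, {"region": "Tampa Bay"})
        assert tier == "regional" and eq.coefficients["m"] == 0.427

    def test_ces_context(self, registry):
        eq, tier = select_equation(registry, {"ces": "TD"})
        assert tier == "ces" and eq.coefficients["m"] == 0.287

    def test_empty_context_falls_to_general_linear(self, registry):
        eq, tier = select_equation(registry, {})
        assert tier == "general" and eq.id == "gen_linear"
        assert eq.coefficients == {"m": 0.511, "b": -2.497}

    def test_carbonate_lagoon_borrows_open_coast(self, registry):
        eq, tier = select_equation(registry, {"ces": "CL"})
        assert tier == "ces" and eq.id == "ces_coc"

    def test_unknown_region_falls_through(self, registry):
        eq, tier = select_equation(registry, {"region": "Atlantis", "ces": "CE"})
        assert tier == "ces"

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_equation(EquationRegistry(), {})

    def test_unknown_context_key_rejected(self, registry):
        with pytest.raises(ValueError, match="unknown context"):
            select_equation(registry, {"continent": "America"})

    def test_tier_monotonicity(self, registry):
        """Adding context keys never yields a lower-priority tier."""
        base_contexts = [
            {},
            {"sedimentary": "carbonate"},
            {"ces": "CE"},
            {"region": "Tampa Bay"},
        ]
        extras = [{}, {"sedimentary": "terrigenous"}, {"ces": "TOC"},
                  {"region": "Marapanim"}]
        for base in base_contexts:
            _, tier0 = select_equation(registry, base)
            for extra in extras:
                merged = {**extra, **base}
                _, tier1 = select_equation(registry, merged)
                assert TIER_ORDER.index(tier1) <= TIER_ORDER.index(tier0)

    def test_slope_rule_when_no_general_equation(self, registry):
        ms = np.array([5.0, 20, 60])
        curve = fit_slope_vs_mean_som([
            RegionSummary(region=f"R{i}", mean_som=m, n=10, slope=0.1 * m**0.4)
            for i, m in enumerate(ms)
        ])
        bare = EquationRegistry(registry.lookup("region"))
        eq, tier = select_equation(bare, {"regional_mean_som": 30.0}, slope_curve=curve)
        assert tier == "slope_from_mean_som"
        assert eq.coefficients["m"] == pytest.approx(0.1 * 30**0.4, rel=1e-4)
        assert "b" not in eq.coefficients  # the rule assumes a zero intercept


class TestEstimateOc:
    def test_negative_prediction_clamped(self, registry):
        pred = estimate_oc(registry.lookup_one("ces", "CE"), 0.0, tier="ces")
        assert pred.oc_raw == pytest.approx(-1.7)
        assert pred.oc == 0.0 and pred.clamped

    def test_laguna_gandoca_low_som_clamped(self, registry):
        eq = registry.lookup(scope_key="Laguna Gandoca")[0]
        pred = estimate_oc(eq, 5.0, tier="regional")
        assert pred.oc_raw == pytest.approx(0.687 * 5 - 15.5)
        assert pred.oc == 0.0 and pred.clamped

    def test_zero_se_equation(self):
        eq = ConversionEquation(
            "e", "region", "X", "linear", {"m": 0.5, "b": 0.0},
            coefficient_se={"m": 0.0, "b": 0.0},
        )
        pred = estimate_oc(eq, 40.0)
        assert pred.oc == 20.0 and pred.oc_se == 0.0 and not pred.clamped

    def test_se_propagation(self, registry):
        eq = registry.lookup_one("ces", "CE")  # m +/- 0.005, b +/- 0.3
        pred = estimate_oc(eq, 50.0, tier="ces")
        assert pred.oc_se == pytest.approx(np.hypot(50 * 0.005, 0.3))

    def test_out_of_range_som_rejected(self, registry):
        with pytest.raises(ValueError):
            estimate_oc(registry.get("gen_linear"), 120.0)

    def test_extrapolation_flagged(self, registry):
        pred = estimate_oc(registry.get("lit_mangrove_power"), 95.0)
        assert pred.extrapolated


class TestPredictDataset:
    def test_measured_takes_precedence(self, registry):
        df = make_samples([20.0, 30.0], [8.0, np.nan], region="Tampa Bay")
        preds = predict_dataset(df, registry)
        assert list(preds["tier"]) == ["measured", "regional"]
        assert preds["oc"].iloc[0] == 8.0

    def test_row_context_from_columns(self, registry):
        df = make_samples([20.0], [np.nan], region="Nowhere", ces="TE")
        preds = predict_dataset(df, registry)
        assert preds["tier"].iloc[0] == "ces"

    def test_explicit_context_overrides(self, registry):
        df = make_samples([20.0], [np.nan])
        preds = predict_dataset(df, registry, context={"region": "Marapanim"},
                                use_measured=False)
        assert preds["equation_id"].iloc[0] == "reg_marapanim"


class TestHierarchicalConverter:
    def test_fit_predict(self, registry):
        conv = HierarchicalConverter(region="Southwest Everglades").fit()
        assert conv.tier_ == "regional"
        np.testing.assert_allclose(conv.predict([60.0]), [28.7])
        np.testing.assert_allclose(conv.predict([0.0]), [0.0])  # clamped

    def test_unclamped_mode(self):
        conv = HierarchicalConverter(ces="CE", clamp=False).fit()
        np.testing.assert_allclose(conv.predict([0.0]), [-1.7])

    def test_predict_detail_tiers(self):
        conv = HierarchicalConverter(sedimentary="carbonate").fit()
        det = conv.predict_detail([10.0, 50.0])
        assert all(p.tier == "sedimentary" for p in det)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            HierarchicalConverter().predict([10.0])


class TestStocks:
    @staticmethod
    def _intervals(tops, bottoms, oc, bd):
        return pd.DataFrame({
            "depth_top": tops, "depth_bottom": bottoms,
            "oc": oc, "bulk_density": bd,
        })

    def test_unit_conversion(self):
        est = compute_stock(self._intervals([0], [100], [10.0], [0.5]), core_id="c")
        assert est.stock == pytest.approx(500.0)  # 5 g cm^-2 -> 500 Mg ha^-1
        assert est.gap_fraction == 0.0

    def test_zero_oc_zero_stock(self):
        est = compute_stock(self._intervals([0, 50], [50, 100], [0.0, 0.0], [0.8, 0.8]))
        assert est.stock == 0.0

    def test_additivity_over_partitions(self):
        whole = compute_stock(self._intervals([0], [100], [10.0], [0.5]))
        halves = compute_stock(
            self._intervals([0, 50], [50, 100], [10.0, 10.0], [0.5, 0.5])
        )
        assert halves.stock == pytest.approx(whole.stock)

    def test_homogeneous_in_bulk_density(self):
        base = self._intervals([0, 50], [50, 100], [12.0, 8.0], [0.4, 0.6])
        doubled = base.assign(bulk_density=base["bulk_density"] * 2)
        assert compute_stock(doubled).stock == pytest.approx(2 * compute_stock(base).stock)

    def test_straddling_interval_prorated(self):
        full = compute_stock(self._intervals([0], [100], [10.0], [0.5]))
        straddle = compute_stock(self._intervals([0, 80], [80, 120], [10.0, 10.0],
                                                 [0.5, 0.5]))
        assert straddle.stock == pytest.approx(full.stock)

    def test_gap_fraction(self):
        est = compute_stock(self._intervals([0, 60], [40, 80], [10.0, 10.0], [0.5, 0.5]))
        assert est.gap_fraction == pytest.approx(0.4)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            compute_stock(self._intervals([0, 30], [50, 80], [10, 10], [0.5, 0.5]))

    def test_missing_bulk_density_rejected(self):
        with pytest.raises(ValueError, match="ulk density"):
            compute_stock(self._intervals([0], [100], [10.0], [np.nan]))


class TestCompareStocks:
    def test_identical_pairs_p_one(self):
        res = compare_stock_estimates([(s, s) for s in [10.0, 20, 30, 40, 50]])
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_systematic_scaling_detected(self):
        a = np.linspace(10, 300, 30)
        res = compare_stock_estimates(np.column_stack([a, 1.5 * a]))
        assert res.p_value < 0.01
        assert res.median_b > res.median_a

    def test_below_minimum_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 5"):
            compare_stock_estimates([(1.0, 2.0)])

    def test_unpaired_shape_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            compare_stock_estimates(np.ones((6, 3)))
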