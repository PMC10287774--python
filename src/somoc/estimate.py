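"""Hierarchical OC estimation, stock computation and stock comparison.

Selecting a conversion equation follows a fixed accuracy hierarchy: measure
OC directly when possible; otherwise use a region-specific equation, then a
coastal-environmental-setting (CES) equation, then a sedimentary-setting
equation, then a general mangrove equation; as a last resort, predict a
zero-intercept slope from regional mean SOM via the cross-regional power
curve.  Carbonate-lagoon contexts borrow the carbonate open coast equation,
since no carbonate-lagoon calibration exists in the built-in set.

Negative model predictions (possible at low SOM under the strongly negative
intercepts of several regional equations) are clamped to zero; the raw value
is retained alongside.

Stocks integrate OC over depth: for each interval,
(OC/100) x bulk density (g cm^-3) x thickness (cm) gives g OC cm^-2, and
1 g cm^-2 = 100 Mg ha^-1.  Intervals straddling the depth limit are pro-rated
by the in-limit length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from somoc.fit import FitResult, predict_slope
from somoc.registry import (
    ConversionEquation,
    EquationRegistry,
    Form,
    ScopeLevel,
    evaluate_equation,
    is_extrapolated,
    load_builtin_registry,
)

__all__ = [
    "TIERS",
    "SamplePrediction",
    "StockEstimate",
    "StockComparison",
    "HierarchicalConverter",
    "select_equation",
    "estimate_oc",
    "predict_dataset",
    "compute_stock",
    "compare_stock_estimates",
]

#: Selection tiers in order of decreasing accuracy.
TIERS = (
    "measured",
    "regional",
    "ces",
    "sedimentary",
    "general",
    "slope_from_mean_som",
)

#: Substitutions for CES classes without a calibrated equation.
_CES_SUBSTITUTIONS = {"CL": "COC"}  # carbonate lagoon -> carbonate open coast


@dataclass(frozen=True)
class SamplePrediction:
    """Predicted OC for one sample.

    ``oc_raw`` is the unclamped model value; ``oc`` is max(oc_raw, 0).
    ``oc_se`` propagates linear coefficient SEs as
    sqrt(som^2 * SE_m^2 + SE_b^2) — slope-intercept covariance is not
    recoverable from published tables and is ignored; NaN for non-linear
    forms or when no SEs exist.
    """

    sample_ref: object
    equation_id: str
    tier: str
    oc_raw: float
    oc: float
    oc_se: float
    extrapolated: bool
    clamped: bool


@dataclass(frozen=True)
class StockEstimate:
    """Depth-integrated OC stock for one core."""

    core_id: str
    depth_limit: float
    stock: float  # Mg ha^-1
    n_intervals: int
    gap_fraction: float  # fraction of the 0..depth_limit profile without data


def select_equation(
    registry: EquationRegistry,
    context: dict,
    slope_curve: Optional[FitResult] = None,
    general_form: str = "linear",
) -> Tuple[ConversionEquation, str]:
    """Select the highest-accuracy applicable equation for a context.

    ``context`` may hold ``region``, ``ces``, ``sedimentary`` and
    ``regional_mean_som`` keys.  Deterministic for a fixed registry and
    context.  Falls back to the general equation when no narrower scope
    applies; the slope-from-mean-SOM rule is used only when no general
    equation exists in the registry (it assumes a zero intercept, which
    fitted regional intercepts rarely support).
    """
    if len(registry) == 0:
        raise ValueError("empty equation registry")
    unknown = set(context) - {"region", "ces", "sedimentary", "regional_mean_som"}
    if unknown:
        raise ValueError(f"unknown context key(s): {sorted(unknown)}")

    region = context.get("region")
    if region is not None:
        hits = registry.lookup(ScopeLevel.REGION, region)
        if len(hits) == 1:
            return hits[0], "regional"

    ces = context.get("ces")
    if ces is not None:
        code = _CES_SUBSTITUTIONS.get(ces, ces)
        hits = registry.lookup(ScopeLevel.CES, code)
        if len(hits) == 1:
            return hits[0], "ces"

    sedimentary = context.get("sedimentary")
    if sedimentary is not None:
        hits = registry.lookup(ScopeLevel.SEDIMENTARY, sedimentary)
        if len(hits) == 1:
            return hits[0], "sedimentary"

    general = [
        eq for eq in registry.lookup(ScopeLevel.GENERAL_MANGROVE)
        if eq.form is Form(general_form)
    ]
    if general:
        return general[0], "general"

    mean_som = context.get("regional_mean_som")
    if mean_som is not None and slope_curve is not None:
        slope = predict_slope(slope_curve, mean_som)
        eq = ConversionEquation(
            id="slope_from_mean_som",
            scope_level=ScopeLevel.GENERAL_MANGROVE,
            scope_key="",
            form=Form.LINEAR,
            coefficients={"m": slope},
            provenance="slope_vs_mean_som_curve",
        )
        return eq, "slope_from_mean_som"
    raise ValueError("no applicable equation for the given context")


def estimate_oc(
    eq: ConversionEquation,
    som: float,
    tier: str = "general",
    sample_ref: object = None,
    clamp: bool = True,
) -> SamplePrediction:
    """Predict OC (%) from SOM (%) with one equation, with SE and flags."""
    if not 0.0 <= som <= 100.0:
        raise ValueError("som must lie in [0, 100]")
    raw = evaluate_equation(eq, som)
    se = float("nan")
    if eq.form is Form.LINEAR and eq.coefficient_se is not None:
        se_m = eq.coefficient_se.get("m")
        if se_m is not None:
            se_b = eq.coefficient_se.get("b", 0.0)
            se = float(np.sqrt(som**2 * se_m**2 + se_b**2))
    clamped = clamp and raw < 0.0
    return SamplePrediction(
        sample_ref=sample_ref,
        equation_id=eq.id,
        tier=tier,
        oc_raw=float(raw),
        oc=0.0 if clamped else float(raw),
        oc_se=se,
        extrapolated=is_extrapolated(eq, som),
        clamped=bool(clamped),
    )


def predict_dataset(
    samples: pd.DataFrame,
    registry: Optional[EquationRegistry] = None,
    context: Optional[dict] = None,
    use_measured: bool = True,
    clamp: bool = True,
    slope_curve: Optional[FitResult] = None,
    general_form: str = "linear",
) -> pd.DataFrame:
    """Per-sample OC predictions for a sample table.

    Context keys absent from ``context`` are read per row from the table's
    ``region`` / ``ces`` / ``sedimentary`` columns where present.  Measured
    OC takes precedence (tier ``measured``) unless ``use_measured=False``.
    """
    registry = registry if registry is not None else load_builtin_registry()
    context = context or {}
    rows = []
    for idx, row in samples.iterrows():
        if use_measured and "oc" in samples.columns and pd.notna(row["oc"]):
            rows.append({
                "sample_ref": idx, "equation_id": "", "tier": "measured",
                "oc_raw": float(row["oc"]), "oc": float(row["oc"]),
                "oc_se": float("nan"), "extrapolated": False, "clamped": False,
            })
            continue
        ctx = dict(context)
        for key in ("region", "ces", "sedimentary"):
            if key not in ctx and key in samples.columns and pd.notna(row.get(key)):
                ctx[key] = row[key]
        eq, tier = select_equation(
            registry, ctx, slope_curve=slope_curve, general_form=general_form
        )
        pred = estimate_oc(eq, float(row["som"]), tier=tier, sample_ref=idx, clamp=clamp)
        rows.append(pred.__dict__)
    return pd.DataFrame(rows).set_index("sample_ref")


class HierarchicalConverter(BaseEstimator):
    """Scikit-learn style wrapper around hierarchical equation selection.

    ``fit`` resolves the equation for the configured context against the
    registry (the built-in registry when none is given); ``predict`` maps
    SOM (%) to OC (%), clamped at zero by default.

    Attributes (after ``fit``): ``equation_``, ``tier_``.
    """

    def __init__(
        self,
        registry: Optional[EquationRegistry] = None,
        region: Optional[str] = None,
        ces: Optional[str] = None,
        sedimentary: Optional[str] = None,
        regional_mean_som: Optional[float] = None,
        slope_curve: Optional[FitResult] = None,
        general_form: str = "linear",
        clamp: bool = True,
    ):
        self.registry = registry
        self.region = region
        self.ces = ces
        self.sedimentary = sedimentary
        self.regional_mean_som = regional_mean_som
        self.slope_curve = slope_curve
        self.general_form = general_form
        self.clamp = clamp

    def fit(self, X=None, y=None):
        registry = self.registry if self.registry is not None else load_builtin_registry()
        context = {
            k: v
            for k, v in {
                "region": self.region,
                "ces": self.ces,
                "sedimentary": self.sedimentary,
                "regional_mean_som": self.regional_mean_som,
            }.items()
            if v is not None
        }
        self.equation_, self.tier_ = select_equation(
            registry, context,
            slope_curve=self.slope_curve, general_form=self.general_form,
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "equation_"):
            raise ValueError("HierarchicalConverter is not fitted")
        som = np.asarray(X, dtype=float).ravel()
        out = np.array([evaluate_equation(self.equation_, s) for s in som])
        if self.clamp:
            out = np.maximum(out, 0.0)
        return out

    def predict_detail(self, X) -> list:
        """Per-sample :class:`SamplePrediction` objects."""
        if not hasattr(self, "equation_"):
            raise ValueError("HierarchicalConverter is not fitted")
        som = np.asarray(X, dtype=float).ravel()
        return [
            estimate_oc(self.equation_, s, tier=self.tier_, sample_ref=i, clamp=self.clamp)
            for i, s in enumerate(som)
        ]


# ---------------------------------------------------------------------------
# Stocks

#: Unit conversion: 1 g OC cm^-2 equals 100 Mg OC ha^-1.
G_PER_CM2_TO_MG_PER_HA = 100.0


def compute_stock(
    intervals: pd.DataFrame,
    depth_limit: float = 100.0,
    core_id: Optional[str] = None,
) -> StockEstimate:
    """Depth-integrated OC stock (Mg ha^-1) for one core.

    ``intervals`` needs columns ``depth_top``, ``depth_bottom``, ``oc`` (%)
    and ``bulk_density`` (g cm^-3); intervals must not overlap.  Intervals
    straddling ``depth_limit`` contribute pro-rata by their in-limit length.
    ``gap_fraction`` is the fraction of 0..depth_limit not covered by data.
    """
    required = {"depth_top", "depth_bottom", "oc", "bulk_density"}
    missing = required - set(intervals.columns)
    if missing:
        raise ValueError(f"stock computation lacks column(s): {sorted(missing)}")
    if depth_limit <= 0:
        raise ValueError("depth_limit must be positive")
    df = intervals.sort_values("depth_top")
    tops = df["depth_top"].to_numpy(dtype=float)
    bottoms = df["depth_bottom"].to_numpy(dtype=float)
    if np.any(tops >= bottoms):
        raise ValueError("each interval needs depth_top < depth_bottom")
    if np.any(bottoms[:-1] > tops[1:]):
        raise ValueError("depth intervals overlap")
    if df["bulk_density"].isna().any():
        raise ValueError("bulk density required for every interval")
    if df["oc"].isna().any():
        raise ValueError("oc required for every interval")

    stock = 0.0
    covered = 0.0
    n_used = 0
    for top, bottom, oc, bd in zip(
        tops, bottoms, df["oc"].to_numpy(float), df["bulk_density"].to_numpy(float)
    ):
        lo = max(top, 0.0)
        hi = min(bottom, depth_limit)
        if hi <= lo:
            continue
        thickness = hi - lo
        stock += (oc / 100.0) * bd * thickness * G_PER_CM2_TO_MG_PER_HA
        covered += thickness
        n_used += 1
    if core_id is None:
        core_id = str(df["core_id"].iloc[0]) if "core_id" in df.columns else ""
    return StockEstimate(
        core_id=core_id,
        depth_limit=float(depth_limit),
        stock=float(stock),
        n_intervals=n_used,
        gap_fraction=float(max(0.0, 1.0 - covered / depth_limit)),
    )


@dataclass(frozen=True)
class StockComparison:
    """Paired Wilcoxon signed-rank comparison of two stock estimate sets."""

    statistic: float
    p_value: float
    n_pairs: int
    median_a: float
    median_b: float
    iqr_a: Tuple[float, float]
    iqr_b: Tuple[float, float]


def compare_stock_estimates(paired: Sequence[Tuple[float, float]]) -> StockComparison:
    """Two-sided paired Wilcoxon signed-rank test on stock estimate pairs."""
    arr = np.asarray(paired, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("paired input must be (stock_a, stock_b) pairs")
    if arr.shape[0] < 5:
        raise ValueError("paired comparison requires n >= 5 pairs")
    a, b = arr[:, 0], arr[:, 1]
    diff = a - b
    if np.all(diff == 0.0):
        statistic, p = 0.0, 1.0  # identical estimates: no evidence of a shift
    else:
        res = stats.wilcoxon(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return StockComparison(
        statistic=statistic,
        p_value=p,
        n_pairs=int(arr.shape[0]),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        iqr_a=(float(q1a), float(q3a)),
        iqr_b=(float(q1b), float(q3b)),
    )
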