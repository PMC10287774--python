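"""Validation of conversion equations and group comparisons of OC:SOM.

An equation is validated within a region by testing whether the residuals
(observed minus modeled OC) are centered on zero.  The Shapiro-Wilk test
gates the choice of test: normal residuals go to a one-sample t-test, and
non-normal residuals to the two-sided one-sample Wilcoxon signed-rank test.
No transformation is attempted before the gate, and no multiple-testing
correction is applied across regions.

Group structure in the per-sample OC:SOM ratio is compared with an
independent two-sample t-test (two sedimentary settings) or a one-way ANOVA
with Tukey HSD post-hoc letters (six coastal environmental settings).
Cross-regional latitude analyses round out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from somoc.fit import ConversionCurve, FitResult, RegionSummary
from somoc.registry import ConversionEquation, evaluate_equation

__all__ = [
    "ResidualReport",
    "ValidationSummary",
    "GroupComparison",
    "CESComparison",
    "validate_equation_on_region",
    "summarize_validation",
    "compare_sedimentary",
    "compare_ces",
    "latitude_regressions",
    "binned_latitude_trends",
    "BinnedTrendResult",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ResidualReport:
    """Zero-centering test of one equation's residuals within one region.

    ``central_tendency`` is the residual mean on the t-test path and the
    median on the Wilcoxon path (the robust counterpart of the location the
    test addresses).
    """

    region: str
    equation_id: str
    n: int
    central_tendency: float
    normality_p: float
    test_used: str  # "one_sample_t" | "wilcoxon_signed_rank"
    p_value: float
    different_from_zero: bool


@dataclass(frozen=True)
class ValidationSummary:
    """Cross-region roll-up of residual central tendencies for one family."""

    equation_family: str
    abs_sum: float
    abs_mean: float
    n_regions: int
    n_not_different_from_zero: int


def validate_equation_on_region(
    eq: ConversionEquation,
    samples: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    normality_alpha: float = ALPHA_DEFAULT,
) -> ResidualReport:
    """Test whether an equation's residuals in one region center on zero."""
    if samples["oc"].isna().any():
        raise ValueError("validation requires measured oc for every sample")
    regions = samples["region"].dropna().unique() if "region" in samples.columns else []
    if len(regions) > 1:
        raise ValueError("validation runs one region at a time")
    region = str(regions[0]) if len(regions) else ""
    som = samples["som"].to_numpy(dtype=float)
    oc = samples["oc"].to_numpy(dtype=float)
    if som.size < 3:
        raise ValueError("validation requires n >= 3")
    modeled = np.array([evaluate_equation(eq, s) for s in som])
    resid = oc - modeled

    if np.ptp(resid) == 0.0:
        # Degenerate: identical residuals carry no sampling variability.
        value = float(resid[0])
        return ResidualReport(
            region=region, equation_id=eq.id, n=int(resid.size),
            central_tendency=value, normality_p=1.0, test_used="one_sample_t",
            p_value=1.0 if value == 0.0 else 0.0,
            different_from_zero=value != 0.0,
        )

    normality_p = float(stats.shapiro(resid).pvalue)
    if normality_p >= normality_alpha:
        test_used = "one_sample_t"
        central = float(np.mean(resid))
        p_value = float(stats.ttest_1samp(resid, 0.0).pvalue)
    else:
        test_used = "wilcoxon_signed_rank"
        central = float(np.median(resid))
        nonzero = resid[resid != 0.0]
        if nonzero.size == 0:
            p_value = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_value = float(
                    stats.wilcoxon(
                        nonzero, alternative="two-sided", correction=True,
                        method="auto",
                    ).pvalue
                )
    return ResidualReport(
        region=region, equation_id=eq.id, n=int(resid.size),
        central_tendency=central, normality_p=normality_p,
        test_used=test_used, p_value=p_value,
        different_from_zero=p_value < alpha,
    )


def summarize_validation(
    reports: Sequence[ResidualReport], equation_family: str = ""
) -> ValidationSummary:
    """Sum and mean of |central tendency| across one report per region.

    ``abs_sum`` (AbsSum) and ``abs_mean`` (AbsMean) rank equation families:
    lower values mean the family tracks regional OC more faithfully.
    """
    regions = [r.region for r in reports]
    if len(set(regions)) != len(regions):
        raise ValueError("one report per region; duplicate regions found")
    if not reports:
        raise ValueError("no reports to summarize")
    abs_sum = float(sum(abs(r.central_tendency) for r in reports))
    n_regions = len(reports)
    return ValidationSummary(
        equation_family=equation_family,
        abs_sum=abs_sum,
        abs_mean=abs_sum / n_regions,
        n_regions=n_regions,
        n_not_different_from_zero=sum(1 for r in reports if not r.different_from_zero),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Independent two-sample t-test of OC:SOM between sedimentary settings."""

    t_statistic: float
    df: float
    p_value: float
    group_means: dict
    group_ses: dict
    group_ns: dict


def _ratios_by_group(samples: pd.DataFrame, column: str) -> dict:
    df = samples.dropna(subset=[column, "oc", "som"])
    df = df[df["som"] > 0]
    return {
        str(name): (grp["oc"] / grp["som"]).to_numpy(dtype=float)
        for name, grp in df.groupby(column, sort=True)
    }


def compare_sedimentary(samples: pd.DataFrame) -> GroupComparison:
    """Pooled-variance t-test of mean OC:SOM: carbonate vs terrigenous."""
    groups = _ratios_by_group(samples, "sedimentary")
    if set(groups) != {"carbonate", "terrigenous"}:
        raise ValueError("both sedimentary settings must be represented")
    a, b = groups["carbonate"], groups["terrigenous"]
    if min(a.size, b.size) < 2:
        raise ValueError("each sedimentary group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(res.statistic),
        df=float(a.size + b.size - 2),
        p_value=float(res.pvalue),
        group_means={k: float(v.mean()) for k, v in groups.items()},
        group_ses={k: float(v.std(ddof=1) / np.sqrt(v.size)) for k, v in groups.items()},
        group_ns={k: int(v.size) for k, v in groups.items()},
    )


@dataclass(frozen=True)
class CESComparison:
    """One-way ANOVA of OC:SOM across CES groups with Tukey HSD letters."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame = field(repr=False)
    letters: dict = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)


def _compact_letter_display(groups: Sequence[str], distinct: set) -> dict:
    """Assign letters so groups sharing a letter are not significantly different.

    ``groups`` must be ordered (by descending mean); ``distinct`` holds
    frozensets of group pairs whose means differ significantly.
    """
    letter_sets: list = []  # each item: set of groups sharing one letter
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in distinct for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # Absorb redundant sets (subset of another).
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_ces(samples: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> CESComparison:
    """One-way ANOVA of OC:SOM across coastal environmental settings.

    Post-hoc pairwise comparisons use Tukey's HSD at ``alpha``; the compact
    letter display marks groups whose means are statistically separable.
    """
    groups = _ratios_by_group(samples, "ces")
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two CES groups")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every CES group needs n >= 2")
    arrays = list(groups.values())
    res = stats.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)

    values = np.concatenate(arrays)
    labels = np.concatenate([[name] * arr.size for name, arr in groups.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    distinct = {
        frozenset((str(r["group1"]), str(r["group2"])))
        for _, r in tukey_df.iterrows()
        if bool(r["reject"])
    }
    means = {k_: float(v.mean()) for k_, v in groups.items()}
    ordered = sorted(groups, key=lambda g: -means[g])
    letters = _compact_letter_display(ordered, distinct)
    return CESComparison(
        f_statistic=float(res.statistic),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(res.pvalue),
        tukey=tukey_df,
        letters=letters,
        group_means=means,
    )


def latitude_regressions(
    summaries: Sequence[RegionSummary],
    subset: Optional[Sequence[str]] = None,
) -> Tuple[FitResult, FitResult]:
    """Linear regressions of regional slope and mean SOM on latitude.

    ``subset`` restricts to named regions (e.g. the Florida regions, where a
    north-south carbonate gradient makes latitude a sedimentary proxy).
    Returns (slope ~ latitude, mean SOM ~ latitude).
    """
    if subset is not None:
        wanted = set(subset)
        summaries = [s for s in summaries if s.region in wanted]
    if len(summaries) < 3:
        raise ValueError("latitude regression requires >= 3 regions")
    if any(s.latitude is None for s in summaries):
        raise ValueError("every region needs a latitude")
    lat = np.array([s.latitude for s in summaries], dtype=float)
    if np.ptp(lat) == 0.0:
        raise ValueError("latitude has zero variance across regions")
    slope = np.array([s.slope for s in summaries], dtype=float)
    som = np.array([s.mean_som for s in summaries], dtype=float)
    fit_slope = ConversionCurve(form="linear").fit(lat, slope).result_
    fit_som = ConversionCurve(form="linear").fit(lat, som).result_
    return fit_slope, fit_som


@dataclass(frozen=True)
class BinnedTrendResult:
    """Per-SOM-bin latitude trends in regional mean OC:SOM.

    ``table`` has one row per usable bin: bin bounds, number of regions, the
    fitted per-degree slope of regional mean OC:SOM on latitude, and its
    p-value.  ``mean_slope_significant`` averages the slope over bins whose
    trend is significant at the chosen alpha (NaN when none are);
    ``mean_slope_all`` averages over every usable bin.  ``skipped_bins``
    lists bins with fewer than 3 regions.
    """

    table: pd.DataFrame = field(repr=False)
    mean_slope_significant: float = float("nan")
    mean_slope_all: float = float("nan")
    skipped_bins: tuple = ()


def binned_latitude_trends(
    samples: pd.DataFrame,
    bin_width: float = 10.0,
    alpha: float = ALPHA_DEFAULT,
) -> BinnedTrendResult:
    """Latitude trends of mean OC:SOM within SOM increments.

    Binning by SOM removes the confounding of latitude with regional SOM
    content: within each SOM bin, regional mean OC:SOM is regressed on
    latitude.  A negative per-degree slope indicates OC-poorer organic matter
    toward higher latitude at matched SOM.
    """
    df = samples.dropna(subset=["oc", "som", "latitude", "region"])
    df = df[df["som"] > 0].copy()
    if df.empty:
        raise ValueError("no samples with oc, som, latitude and region")
    df["ratio"] = df["oc"] / df["som"]
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    rows = []
    skipped = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = df[(df["som"] >= lo) & (df["som"] < hi)]
        if sub.empty:
            continue
        per_region = sub.groupby("region").agg(
            ratio=("ratio", "mean"), latitude=("latitude", "mean")
        )
        if len(per_region) < 3 or per_region["latitude"].nunique() < 2:
            skipped.append((float(lo), float(hi)))
            continue
        fit = ConversionCurve(form="linear").fit(
            per_region["latitude"].to_numpy(), per_region["ratio"].to_numpy()
        ).result_
        m = fit.coefficients["m"]
        se = fit.coefficient_se["m"]
        dfree = fit.n - 2
        t_stat = m / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(t_stat), dfree)) if dfree > 0 else float("nan")
        rows.append({
            "som_bin_low": float(lo),
            "som_bin_high": float(hi),
            "n_regions": int(fit.n),
            "slope_per_degree": float(m),
            "slope_se": float(se),
            "p_value": p,
            "significant": p < alpha,
        })
    table = pd.DataFrame(
        rows,
        columns=[
            "som_bin_low", "som_bin_high", "n_regions",
            "slope_per_degree", "slope_se", "p_value", "significant",
        ],
    )
    sig = table[table["significant"]]
    return BinnedTrendResult(
        table=table,
        mean_slope_significant=float(sig["slope_per_degree"].mean()) if not sig.empty else float("nan"),
        mean_slope_all=float(table["slope_per_degree"].mean()) if not table.empty else float("nan"),
        skipped_bins=tuple(skipped),
    )
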