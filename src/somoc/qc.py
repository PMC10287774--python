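"""Two-stage outlier screening applied before deriving conversion equations.

Stage 1 removes physically impossible OC:SOM ratios: organic carbon cannot
exceed organic matter (ratio >= 1 indicates incomplete inorganic-carbon
removal) and cannot be non-positive (ratio <= 0 indicates a sample-preparation
error).  Stage 2 applies the modified Thompson Tau test to the OC:SOM ratios
within each region, iteratively removing the single most deviant point while
it exceeds a Student-t-based threshold times the sample standard deviation.

Samples live in a pandas DataFrame with one row per core depth interval; see
:data:`SAMPLE_COLUMNS` for the schema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SAMPLE_COLUMNS",
    "SoilSample",
    "validate_samples",
    "oc_som_ratio",
    "filter_ratio_bounds",
    "thompson_tau_filter",
    "thompson_tau_mask",
    "screen_dataset",
]

#: Canonical sample-table schema.  ``som`` and the depth bounds are required;
#: the rest are optional and may be absent or NaN.
SAMPLE_COLUMNS = {
    "region": "region label (required for the Tau stage)",
    "site": "site label within a region",
    "core_id": "soil core identifier",
    "depth_top": "interval top, cm below surface",
    "depth_bottom": "interval bottom, cm below surface",
    "som": "soil organic matter, % of dry mass",
    "oc": "measured organic carbon, % of dry mass (optional)",
    "bulk_density": "dry bulk density, g cm^-3 (optional)",
    "caco3": "CaCO3 content, % (optional)",
    "ces": "coastal environmental setting code (optional)",
    "sedimentary": "terrigenous | carbonate (optional)",
    "latitude": "decimal degrees, south negative (optional)",
}


@dataclass(frozen=True)
class SoilSample:
    """One depth interval of one soil core (row-object convenience type)."""

    region: str
    site: str
    core_id: str
    depth_top: float
    depth_bottom: float
    som: float
    oc: Optional[float] = None
    bulk_density: Optional[float] = None
    caco3: Optional[float] = None
    ces: Optional[str] = None
    sedimentary: Optional[str] = None
    latitude: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.som <= 100.0:
            raise ValueError("som must lie in [0, 100]")
        if not self.depth_top < self.depth_bottom:
            raise ValueError("depth_top must be above depth_bottom")


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Check a sample table against the schema; returns the frame unchanged."""
    if "som" not in df.columns:
        raise ValueError("sample table must have a 'som' column")
    som = df["som"].dropna()
    if ((som < 0) | (som > 100)).any():
        raise ValueError("som values must lie in [0, 100]")
    if {"depth_top", "depth_bottom"} <= set(df.columns):
        both = df[["depth_top", "depth_bottom"]].dropna()
        if (both["depth_top"] >= both["depth_bottom"]).any():
            raise ValueError("depth_top must be above depth_bottom")
    return df


def oc_som_ratio(df: pd.DataFrame) -> pd.Series:
    """Per-sample OC:SOM ratio; NaN where OC is missing, inf at SOM = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return df["oc"] / df["som"]


def filter_ratio_bounds(samples: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Remove samples whose OC:SOM ratio is >= 1 or <= 0.

    Rows where OC is missing pass through unscreened (no ratio to judge).
    A sample with SOM = 0 but measured OC has an undefined ratio and is
    removed: OC without SOM indicates an analysis error.

    Returns
    -------
    kept, removed : DataFrame
        ``removed`` carries a ``reason`` column with codes ``ratio_high``,
        ``ratio_nonpositive`` or ``undefined_ratio``.
    """
    if "oc" not in samples.columns:
        raise ValueError("ratio screening requires an 'oc' column")
    has_oc = samples["oc"].notna() & samples["som"].notna()
    som = samples["som"]
    oc = samples["oc"]
    undefined = has_oc & (som == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = oc / som
    high = has_oc & ~undefined & (ratio >= 1.0)
    nonpos = has_oc & ~undefined & (ratio <= 0.0)
    removed_mask = undefined | high | nonpos
    removed = samples[removed_mask].copy()
    reason = pd.Series("", index=removed.index, dtype=object)
    reason[undefined[removed_mask]] = "undefined_ratio"
    reason[high[removed_mask]] = "ratio_high"
    reason[nonpos[removed_mask]] = "ratio_nonpositive"
    removed["reason"] = reason
    return samples[~removed_mask].copy(), removed


def thompson_tau_mask(values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Boolean keep-mask for the modified Thompson Tau test.

    Iteratively: with n retained points, compute mean and sample SD and the
    threshold ``tau = t * (n - 1) / (sqrt(n) * sqrt(n - 2 + t**2))`` where
    ``t`` is the two-sided Student-t critical value at ``alpha`` with n - 2
    degrees of freedom.  The single point with the largest absolute deviation
    from the mean (first occurrence on ties) is removed if its deviation
    exceeds ``tau * SD``; repeat until no removal or fewer than 3 points
    remain.
    """
    x = np.asarray(values, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    keep = np.ones(x.size, dtype=bool)
    if x.size < 3:
        warnings.warn("Thompson Tau test requires n >= 3; no screening applied")
        return keep
    while keep.sum() >= 3:
        idx = np.flatnonzero(keep)
        sub = x[idx]
        n = sub.size
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
        tau = t_crit * (n - 1) / (np.sqrt(n) * np.sqrt(n - 2 + t_crit**2))
        worst = int(np.argmax(dev))
        if dev[worst] > tau * sd:
            keep[idx[worst]] = False
        else:
            break
    return keep


def thompson_tau_filter(
    values: Sequence[float], alpha: float = 0.05
) -> Tuple[list, list]:
    """Split ``values`` into (kept, removed) by the modified Thompson Tau test."""
    x = list(values)
    keep = thompson_tau_mask(x, alpha=alpha)
    kept = [v for v, k in zip(x, keep) if k]
    removed = [v for v, k in zip(x, keep) if not k]
    return kept, removed


def screen_dataset(
    samples: pd.DataFrame, alpha: float = 0.05
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full two-stage screening: ratio bounds, then per-region Tau filtering.

    The Tau stage operates on the OC:SOM ratio within each region.  Samples
    lacking a region label pass the bounds filter but are exempt from the Tau
    stage; the exemption is noted in the log with stage ``tau`` and reason
    ``region_missing_exempt`` (those rows remain in ``kept``).

    Returns
    -------
    kept : DataFrame
    removal_log : DataFrame
        Columns ``sample_id`` (input index), ``stage`` (``bounds`` | ``tau``),
        ``region``, ``reason``, ``value`` (the offending ratio).
    """
    log_rows = []
    if samples.empty:
        empty_log = pd.DataFrame(
            columns=["sample_id", "stage", "region", "reason", "value"]
        )
        return samples.copy(), empty_log

    kept, removed = filter_ratio_bounds(samples)
    ratios_removed = oc_som_ratio(removed) if not removed.empty else pd.Series(dtype=float)
    for idx, row in removed.iterrows():
        log_rows.append({
            "sample_id": idx,
            "stage": "bounds",
            "region": row.get("region"),
            "reason": row["reason"],
            "value": ratios_removed.loc[idx],
        })

    has_region = "region" in kept.columns
    screenable = kept["oc"].notna() if "oc" in kept.columns else pd.Series(False, index=kept.index)
    if has_region:
        no_region = screenable & kept["region"].isna()
        for idx in kept.index[no_region]:
            log_rows.append({
                "sample_id": idx,
                "stage": "tau",
                "region": None,
                "reason": "region_missing_exempt",
                "value": np.nan,
            })
        drop = []
        for region, grp in kept[screenable & ~no_region].groupby("region", sort=False):
            ratio = (grp["oc"] / grp["som"]).to_numpy()
            if ratio.size < 3:
                continue
            keep_mask = thompson_tau_mask(ratio, alpha=alpha)
            for pos in np.flatnonzero(~keep_mask):
                idx = grp.index[pos]
                drop.append(idx)
                log_rows.append({
                    "sample_id": idx,
                    "stage": "tau",
                    "region": region,
                    "reason": "tau_outlier",
                    "value": ratio[pos],
                })
        kept = kept.drop(index=drop)

    log = pd.DataFrame(
        log_rows, columns=["sample_id", "stage", "region", "reason", "value"]
    )
    return kept, log
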