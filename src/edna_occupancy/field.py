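"""Field-level statistics around the occupancy model.

Pre-model steps: fill missing water temperatures from the time-of-day
regression, screen colony/control pairs whose control ran ≥ 8 °C warmer
(eDNA degrades faster in warm water, which would bias the concentration
comparison), and tally the sampling-design counts. Post-model steps: the
naive occupancy/concentration summary table, the time–temperature Pearson
correlation, and the paired t-test of site-total concentrations.

Site "total concentration" is the sum of post-LOB sample concentrations
within the site — the site-level summaries (means including zero sites, and
a site range exceeding the largest single sample) only cohere under that
reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairComparison",
    "impute_temperature",
    "correlation_time_temp",
    "pair_table",
    "exclude_pairs",
    "naive_summary",
    "paired_concentration_test",
    "design_counts",
]

PAIR_TEMP_THRESHOLD_C = 8.0
MORNING_CUTOFF_MIN = 660  # 11:00; "before 11AM" is strictly earlier
SHARED_TEMP_RANGE_C = (20.3, 27.8)  # closed interval covered by both strata


@dataclass(frozen=True)
class PairComparison:
    """Concentration totals and the temperature screen for one island pair."""

    pair_id: str
    colony_total: float
    control_total: float
    temp_median_diff: float  # median(control) − median(colony), °C
    excluded: bool


def impute_temperature(samples: pd.DataFrame) -> pd.DataFrame:
    """Fill missing water temperatures from an OLS fit on collection time.

    Fits temperature ~ time over the measured samples (at least 10 required)
    and replaces missing values with fitted ones, setting ``temp_imputed``.
    Measured values are never touched.
    """
    out = samples.copy()
    temp = out["water_temp_c"].to_numpy(dtype=float)
    time = out["time_min"].to_numpy(dtype=float)
    missing = np.isnan(temp)
    if "temp_imputed" not in out.columns:
        out["temp_imputed"] = False
    if not missing.any():
        return out
    n_meas = int((~missing).sum())
    if n_meas == 0:
        raise ValueError("all temperatures missing; nothing to fit")
    if n_meas < 10:
        raise ValueError(f"only {n_meas} measured temperatures; need >= 10")
    slope, intercept = np.polyfit(time[~missing], temp[~missing], 1)
    out.loc[missing, "water_temp_c"] = intercept + slope * time[missing]
    out.loc[missing, "temp_imputed"] = True
    return out


def correlation_time_temp(
    samples: pd.DataFrame, exclude_imputed: bool = True
) -> tuple[float, float, int, float]:
    """Pearson correlation of collection time and water temperature.

    Returns ``(r, t, df, p)`` with t = r√(n−2)/√(1−r²), df = n−2 and a
    two-sided p from the t distribution (t = ±inf and p = 0 when |r| = 1).
    """
    df_ = samples
    if exclude_imputed and "temp_imputed" in df_.columns:
        df_ = df_[~df_["temp_imputed"].astype(bool)]
    x = df_["time_min"].to_numpy(dtype=float)
    y = df_["water_temp_c"].to_numpy(dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    dof = n - 2
    if abs(r) >= 1.0:
        return float(np.sign(r)), float(np.sign(r) * np.inf), dof, 0.0
    t = r * np.sqrt(dof) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(t), dof, float(p)


def pair_table(
    samples: pd.DataFrame, threshold_c: float = PAIR_TEMP_THRESHOLD_C
) -> list[PairComparison]:
    """Per-pair site totals and the median-temperature screen.

    ``samples`` needs ``pair_id``, ``island_type``, ``water_temp_c`` and
    post-LOB ``concentration`` columns. A pair is excluded when the median
    control temperature is at least ``threshold_c`` above the colony median.
    """
    out = []
    for pid, grp in samples.groupby("pair_id", sort=True):
        sides = {t: g for t, g in grp.groupby("island_type")}
        if set(sides) != {"colony", "control"}:
            raise ValueError(f"pair {pid!r} is missing one side")
        med = {
            t: float(np.median(g["water_temp_c"].dropna())) for t, g in sides.items()
        }
        diff = med["control"] - med["colony"]
        out.append(
            PairComparison(
                pair_id=pid,
                colony_total=float(sides["colony"]["concentration"].sum()),
                control_total=float(sides["control"]["concentration"].sum()),
                temp_median_diff=diff,
                excluded=diff >= threshold_c,
            )
        )
    return out


def exclude_pairs(
    pairs: list[PairComparison],
) -> tuple[list[PairComparison], list[PairComparison]]:
    """Partition pairs into (retained, excluded) by the temperature screen."""
    retained = [p for p in pairs if not p.excluded]
    excluded = [p for p in pairs if p.excluded]
    return retained, excluded


def naive_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Count-level summary per island type, before any model.

    ``samples`` needs ``site_id``, ``island_type`` and post-LOB
    ``concentration``. Per type: positive/total samples with percent
    (rounded half-to-even to 1 decimal), positive/total sites, the mean
    site-total concentration (zero sites included), and the min/max positive
    sample concentration (NaN when the stratum has no positives).
    """
    rows = []
    for typ in ("colony", "control"):
        grp = samples[samples["island_type"] == typ]
        if grp.empty:
            raise ValueError(f"no samples of island type {typ!r}")
        conc = grp["concentration"].to_numpy(dtype=float)
        pos = conc > 0
        site_totals = grp.groupby("site_id")["concentration"].sum()
        pos_conc = conc[pos]
        rows.append(
            {
                "island_type": typ,
                "positive_samples": int(pos.sum()),
                "total_samples": len(grp),
                "pct_positive": round(100.0 * pos.sum() / len(grp), 1),
                "positive_sites": int((site_totals > 0).sum()),
                "total_sites": len(site_totals),
                "mean_site_total": float(site_totals.mean()),
                "min_positive": float(pos_conc.min()) if pos.any() else np.nan,
                "max_positive": float(pos_conc.max()) if pos.any() else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("island_type")


def paired_concentration_test(
    retained: list[PairComparison],
) -> tuple[float, float, float, int, float]:
    """Classical paired t-test of colony vs control site totals.

    Differences are colony − control (so a positive mean means more eDNA at
    colonies). Returns ``(mean_diff, sd_diff, t, df, p)`` with
    df = n_pairs − 1 and a two-sided p; identical totals give t = 0, p = 1.
    """
    if len(retained) < 2:
        raise ValueError("need at least 2 retained pairs")
    d = np.array([p.colony_total - p.control_total for p in retained])
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
    else:
        t = mean / (sd / np.sqrt(n))
    dof = n - 1
    p = 1.0 if (sd == 0.0 and mean == 0.0) else 2.0 * float(stats.t.sf(abs(t), dof))
    return mean, sd, float(t), dof, p


def design_counts(
    samples: pd.DataFrame,
    cutoff_min: int = MORNING_CUTOFF_MIN,
    temp_range: tuple[float, float] = SHARED_TEMP_RANGE_C,
) -> dict:
    """Sampling-design tallies: morning sampling and the shared temperature window.

    Per island type, the count and percent (1 decimal) of samples collected
    strictly before ``cutoff_min``; overall, the count and percent of
    samples whose temperature lies in the closed ``temp_range``.
    """
    out: dict = {}
    for typ, grp in samples.groupby("island_type"):
        before = int((grp["time_min"] < cutoff_min).sum())
        out[f"{typ}_before_cutoff"] = before
        out[f"{typ}_total"] = len(grp)
        out[f"{typ}_pct_before"] = round(100.0 * before / len(grp), 1)
    lo, hi = temp_range
    in_range = int(samples["water_temp_c"].between(lo, hi, inclusive="both").sum())
    out["in_temp_range"] = in_range
    out["total_samples"] = len(samples)
    out["pct_in_temp_range"] = round(100.0 * in_range / len(samples), 1)
    return out
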