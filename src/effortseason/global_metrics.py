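"""Global gear-stratified effort series and their seasonal statistics.

``E_g`` is the globally summed daily-mean effort of gear g in a month
(fishing-vessel-days per day); the total ``E`` is the sum over gears.
Seasonality of the global series is described by the relative variation
``E_g / Ē_g`` around the full-window mean and its standard deviation,
and the boreal-winter effort deficit is converted into an implied
number of non-fishing (holiday) days per month.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .ingest import months_period_index

logger = logging.getLogger(__name__)

HOLIDAY_MONTHS = (12, 1, 2)
BASELINE_MONTHS = tuple(range(3, 12))  # March .. November


def global_series(effort: xr.DataArray) -> pd.DataFrame:
    """Globally integrated monthly series per gear.

    Returns a DataFrame indexed by month (PeriodIndex), one column per
    gear plus ``total``, in fishing-vessel-days per day.
    """
    summed = effort.sum(dim=("lat", "lon"))
    df = pd.DataFrame(
        summed.transpose("month", "gear").values,
        index=months_period_index(effort),
        columns=[str(g) for g in effort["gear"].values],
    )
    df["total"] = df.sum(axis=1)
    df.index.name = "month"
    return df


def relative_variation(series: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Relative series ``E_g / Ē_g`` and its sample standard deviation.

    ``Ē_g`` is the mean over the full window.  Gears with zero mean are
    excluded with a warning (the ratio is undefined).  The mean of each
    returned relative series is 1 by construction.
    """
    if len(series) < 2:
        raise ValueError("need at least two months for a relative series")
    means = series.mean(axis=0)
    zero = means[means == 0].index.tolist()
    if zero:
        logger.warning("gears with zero mean effort excluded: %s", zero)
    cols = [c for c in series.columns if c not in zero]
    rel = series[cols] / means[cols]
    sd = rel.std(axis=0, ddof=1)
    return rel, sd


def gear_shares(series: pd.DataFrame) -> pd.Series:
    """Percent of window-summed effort per gear; sums to 100."""
    cols = [c for c in series.columns if c != "total"]
    totals = series[cols].sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("zero total effort; shares undefined")
    return 100.0 * totals / grand


def implied_holiday_days(total_series: pd.Series,
                         holiday_months=HOLIDAY_MONTHS,
                         baseline_months=BASELINE_MONTHS) -> pd.Series:
    """Implied non-fishing days for the boreal-winter months.

    ``total_series`` is a monthly total-effort series (daily-mean units,
    PeriodIndex) — normally computed with the moratorium region (the
    Chinese EEZ in the source analysis) removed.  The baseline is the
    mean over all March–November months pooled across years.  For each
    target month m, ``implied_days = (1 - Ē_m / baseline) * d_m``
    where ``Ē_m`` pools month m across years and ``d_m`` is the mean
    calendar length of that month over the window.  Values are signed:
    a month busier than baseline yields negative days.
    """
    idx = total_series.index
    if not isinstance(idx, pd.PeriodIndex):
        idx = pd.PeriodIndex(idx, freq="M")
        total_series = pd.Series(total_series.values, index=idx)
    month_no = idx.month
    base = total_series[np.isin(month_no, baseline_months)]
    if base.empty:
        raise ValueError("series contains no baseline (March–November) months")
    baseline = base.mean()
    if baseline <= 0:
        raise ValueError("baseline effort is zero; implied days undefined")
    out = {}
    for m in holiday_months:
        sel = total_series[month_no == m]
        if sel.empty:
            out[m] = np.nan
            continue
        days = np.mean([p.days_in_month for p in sel.index])
        out[m] = float((1.0 - sel.mean() / baseline) * days)
    return pd.Series(out, name="implied_holiday_days")


def summary(series: pd.DataFrame,
            masked_total: pd.Series | None = None) -> dict:
    """JSON-ready summary: per-gear sd of the relative series, shares,
    and the holiday estimate (on ``masked_total`` when provided)."""
    rel, sd = relative_variation(series)
    shares = gear_shares(series)
    holiday = implied_holiday_days(
        masked_total if masked_total is not None else series["total"]
    )
    return {
        "sd_relative": {g: float(v) for g, v in sd.items()},
        "shares_pct": {g: float(v) for g, v in shares.items()},
        "implied_holiday_days": {int(m): float(v) for m, v in holiday.items()},
    }
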