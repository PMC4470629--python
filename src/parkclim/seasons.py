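"""Visitation-season statistics: windows, spline daily curves, season length.

Seasons follow the standard protected-area convention: the peak season is
the three contiguous calendar months (circularly) with the highest total
visitation, the shoulder seasons the two months either side of the peak,
and the low season the three contiguous months with the lowest total.
The overall visitation season runs from the day the cumulative annual
curve reaches 10% of the annual total to the day 10% remains (the central
80% of visits); monthly totals are disaggregated to daily rates with a
periodic cubic spline before accumulating.  A 365-day year is used
throughout (month lengths 31,28,31,...); leap days are immaterial at the
precision of long-term means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
YEAR_DAYS = 365
_BOUNDS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])  # day-of-year month edges
_MIDPOINTS = _BOUNDS[:-1] + MONTH_LENGTHS / 2.0


@dataclass(frozen=True)
class Window:
    """A contiguous circular run of calendar months."""

    start: int  # 1..12
    months: tuple

    def __contains__(self, m):
        return m in self.months


@dataclass(frozen=True)
class SeasonProfile:
    park_id: str
    peak: Window
    shoulder: tuple  # 4 months
    low: Window
    season_start: float  # continuous day-of-year
    season_end: float
    season_length_days: float
    degenerate: bool


def _window_months(start: int, size: int) -> tuple:
    return tuple((start - 1 + i) % 12 + 1 for i in range(size))


def find_window(values, size: int = 3, mode: str = "max") -> Window:
    """The circular `size`-month window with the largest/smallest sum.

    Ties break toward the earliest start month.  All-equal input is
    degenerate (flagged at the profile level) but still returns the
    earliest window.
    """
    v = np.asarray(values, float)
    if len(v) != 12 or (v < 0).any():
        raise ValueError("need 12 non-negative monthly values")
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    ext = np.concatenate([v, v[: size - 1]])
    sums = np.array([ext[s : s + size].sum() for s in range(12)])
    best = int(np.argmax(sums) if mode == "max" else np.argmin(sums))  # first index wins ties
    return Window(start=best + 1, months=_window_months(best + 1, size))


def shoulder_months(peak: Window) -> tuple:
    """The two months before plus the two after the peak window, mod 12."""
    s0 = peak.start
    size = len(peak.months)
    before = [(s0 - 1 - d - 1) % 12 + 1 for d in (1, 0)]
    after = [(s0 - 1 + size + d) % 12 + 1 for d in (0, 1)]
    return tuple(before + after)


def daily_curve(monthly_totals, month_lengths=MONTH_LENGTHS) -> np.ndarray:
    """Disaggregate 12 monthly totals to 365 daily visitation rates.

    A periodic cubic spline is drawn through the average daily rate
    (total / days in month) at each month's midpoint, evaluated at day
    midpoints; negative excursions are clamped to zero and the curve is
    rescaled so the daily values sum to the annual total exactly.
    """
    tot = np.asarray(monthly_totals, float)
    lengths = np.asarray(month_lengths)
    if len(tot) != 12 or (tot < 0).any():
        raise ValueError("need 12 non-negative monthly totals")
    if lengths.sum() != YEAR_DAYS:
        raise ValueError(f"month lengths must sum to {YEAR_DAYS}")
    annual = tot.sum()
    if annual == 0:
        raise ValueError("all-zero visitation: daily curve undefined")
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    mids = bounds[:-1] + lengths / 2.0
    rates = tot / lengths
    x = np.concatenate([mids, [mids[0] + YEAR_DAYS]])
    y = np.concatenate([rates, [rates[0]]])
    spline = CubicSpline(x, y, bc_type="periodic")
    days = np.arange(1, YEAR_DAYS + 1) - 0.5
    t = mids[0] + (days - mids[0]) % YEAR_DAYS
    daily = np.maximum(spline(t), 0.0)
    return daily * (annual / daily.sum())


def season_length(daily) -> tuple[float, float, float]:
    """(start, end, length) of the central-80% visitation season, in days.

    The cumulative curve is piecewise linear (constant rate within each
    day); start is the interpolated crossing of 10% of the annual total,
    end the crossing of 90%.
    """
    r = np.asarray(daily, float)
    if len(r) != YEAR_DAYS or (r < 0).any():
        raise ValueError(f"need {YEAR_DAYS} non-negative daily rates")
    total = r.sum()
    if total <= 0:
        raise ValueError("season undefined for zero total")
    cum = np.concatenate([[0.0], np.cumsum(r)])

    def crossing(q: float) -> float:
        i = int(np.searchsorted(cum, q))  # first day-end with cum >= q
        if i == 0:
            return 0.0
        return (i - 1) + (q - cum[i - 1]) / r[i - 1]

    start = crossing(0.10 * total)
    end = crossing(0.90 * total)
    return start, end, end - start


def season_profile(park_id: str, monthly_totals) -> SeasonProfile:
    """Windows plus spline-based season timing for one monthly series."""
    tot = np.asarray(monthly_totals, float)
    peak = find_window(tot, 3, "max")
    low = find_window(tot, 3, "min")
    start, end, length = season_length(daily_curve(tot))
    return SeasonProfile(
        park_id=park_id,
        peak=peak,
        shoulder=shoulder_months(peak),
        low=low,
        season_start=start,
        season_end=end,
        season_length_days=length,
        degenerate=bool(np.ptp(tot) == 0),
    )


def circular_month_distance(a: int, b: int) -> int:
    d = abs(a - b) % 12
    return min(d, 12 - d)


def timing_shift(hist: SeasonProfile, future: SeasonProfile):
    """(peak shift, low shift, within-one-month flag) between two profiles.

    Shifts are circular distances (0..6) between window start months; the
    stability flag is None when either profile is degenerate.
    """
    peak_shift = circular_month_distance(hist.peak.start, future.peak.start)
    low_shift = circular_month_distance(hist.low.start, future.low.start)
    if hist.degenerate or future.degenerate:
        return peak_shift, low_shift, None
    return peak_shift, low_shift, bool(peak_shift <= 1 and low_shift <= 1)


# ---------------------------------------------------------------------------
# System-level aggregation


def profiles_from_projections(projections) -> dict:
    """{(park, scenario, growth): SeasonProfile} from capped monthly values."""
    out = {}
    for pp in projections:
        vals = [mp.capped_value for mp in pp.months]
        out[(pp.park_id, pp.scenario, pp.growth_ceiling)] = season_profile(pp.park_id, vals)
    return out


def summarize_system(
    fits: dict,
    clims: dict,
    projections,
    hist_profiles: dict,
    future_profiles: dict | None = None,
    baseline: str = "fitted",
) -> pd.DataFrame:
    """Per scenario × growth-ceiling summary of projected change.

    Percent changes are system totals (summed over the projected parks)
    relative to a baseline: ``"fitted"`` (default) projects each park at
    its historical temperatures under the same ceiling, so a zero-warming
    scenario yields exactly 0% change; ``"observed"`` uses the historical
    climatological means directly, the convention used when quoting change
    against the measured record.  Seasonal changes use each park's
    *historical* peak/shoulder/low windows.  Season-length change is
    always future minus historical-observed, in days.
    """
    from parkclim.projection import project_park
    from parkclim.scenarios import ScenarioTemps

    if baseline not in ("fitted", "observed"):
        raise ValueError("baseline must be 'fitted' or 'observed'")
    if future_profiles is None:
        future_profiles = profiles_from_projections(projections)

    rows = []
    keys = sorted({(pp.scenario, pp.growth_ceiling) for pp in projections})
    for scen_name, g in keys:
        subset = [pp for pp in projections
                  if pp.scenario == scen_name and pp.growth_ceiling == g]
        tot_future = tot_base = 0.0
        seas_future = {"peak": 0.0, "shoulder": 0.0, "low": 0.0}
        seas_base = {"peak": 0.0, "shoulder": 0.0, "low": 0.0}
        months_up = months_all = 0
        length_changes = []
        stable = []
        for pp in subset:
            park = pp.park_id
            clim = clims[park]
            if baseline == "fitted":
                base_scen = ScenarioTemps(park, "historical", clim.mean_temp, ("historical",))
                base_vals = np.array(
                    [mp.capped_value for mp in
                     project_park(fits[park], clim, base_scen, g).months]
                )
            else:
                base_vals = clim.mean_visits
            fut_vals = np.array([mp.capped_value for mp in pp.months])
            tot_future += fut_vals.sum()
            tot_base += base_vals.sum()
            months_up += int((fut_vals > base_vals).sum())
            months_all += 12
            hp = hist_profiles[park]
            for name, months in (("peak", hp.peak.months),
                                 ("shoulder", hp.shoulder),
                                 ("low", hp.low.months)):
                idx = [m - 1 for m in months]
                seas_future[name] += fut_vals[idx].sum()
                seas_base[name] += base_vals[idx].sum()
            fp = future_profiles[(park, scen_name, g)]
            length_changes.append(fp.season_length_days - hp.season_length_days)
            _, _, ok = timing_shift(hp, fp)
            if ok is not None:
                stable.append(ok)
        pct = lambda f, b: 100.0 * (f - b) / b if b > 0 else np.nan
        rows.append(
            {"scenario": scen_name, "growth": g, "n_parks": len(subset),
             "pct_change_annual": pct(tot_future, tot_base),
             "pct_change_peak": pct(seas_future["peak"], seas_base["peak"]),
             "pct_change_shoulder": pct(seas_future["shoulder"], seas_base["shoulder"]),
             "pct_change_low": pct(seas_future["low"], seas_base["low"]),
             "frac_months_increasing": months_up / months_all if months_all else np.nan,
             "mean_season_length_change_days": float(np.mean(length_changes))
             if length_changes else np.nan,
             "frac_timing_within_one_month": float(np.mean(stable)) if stable else np.nan}
        )
    return pd.DataFrame(rows)


def season_table(profiles: dict, series_labels: dict | None = None) -> pd.DataFrame:
    """Season CSV rows from {key: SeasonProfile}; key may be park or tuple."""
    rows = []
    for key, p in sorted(profiles.items(), key=lambda kv: str(kv[0])):
        if isinstance(key, tuple):
            series = f"{key[1]}_{key[2]}"
        else:
            series = "hist"
        rows.append(
            {"park_id": p.park_id, "series": series, "peak_start": p.peak.start,
             "low_start": p.low.start, "season_start_doy": p.season_start,
             "season_end_doy": p.season_end,
             "season_length_days": p.season_length_days,
             "degenerate": p.degenerate}
        )
    return pd.DataFrame(rows)
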