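"""Tabular input/output, park-inclusion filtering and long-term climatologies.

All tables are long-format pandas DataFrames with one row per
park × year × month observation.  Schemas (header row mandatory, months
1-based, temperatures in °C):

* visits:       ``park_id,year,month,recreation_visits``
* temperature:  ``park_id,year,month,tmean_c``
* future:       ``park_id,model,rcp,month,tmean_c``
* baseline:     ``park_id,year,month,tmean_c,source`` (``source`` in
  ``{cru, worldclim}``)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MONTHS = np.arange(1, 13)

VISITS_SCHEMA = ["park_id", "year", "month", "recreation_visits"]
TEMPERATURE_SCHEMA = ["park_id", "year", "month", "tmean_c"]
FUTURE_SCHEMA = ["park_id", "model", "rcp", "month", "tmean_c"]

_VALUE_COLUMN = {"visits": "recreation_visits", "temperature": "tmean_c"}


class TableFormatError(ValueError):
    """Raised when an input table violates its schema or invariants."""


@dataclass(frozen=True)
class ParkClimatology:
    """Long-term monthly means of visits and temperature for one park.

    Arrays are indexed by calendar month (position 0 = January).
    ``se_visits`` is the standard error of the monthly mean
    (sample SD / sqrt(n_years)); it is 0 where only one year is available.
    """

    park_id: str
    mean_visits: np.ndarray
    se_visits: np.ndarray
    n_years_visits: np.ndarray
    mean_temp: np.ndarray
    n_years_temp: np.ndarray

    @property
    def annual_total(self) -> float:
        return float(self.mean_visits.sum())

    def __post_init__(self):
        for name in ("mean_visits", "se_visits", "mean_temp"):
            arr = getattr(self, name)
            if len(arr) != 12:
                raise ValueError(f"{name} must have 12 entries, got {len(arr)}")
        if (self.mean_visits < 0).any():
            raise ValueError("mean_visits must be non-negative")
        if (self.n_years_visits < 1).any() or (self.n_years_temp < 1).any():
            raise ValueError("every month needs at least one year of records")


@dataclass(frozen=True)
class InclusionReport:
    park_id: str
    n_complete_years: int
    mean_annual_visits: float
    retained: bool
    reason: str = ""


def load_monthly_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a long-format monthly visits or temperature CSV.

    Parameters
    ----------
    path
        CSV file with the documented schema for `kind`.
    kind
        ``"visits"`` or ``"temperature"``.

    Returns
    -------
    DataFrame with the schema columns, validated: months in 1..12, visit
    values non-negative, (park_id, year, month) unique.  Non-integer visit
    counts are tolerated (agencies rescale some series) but logged.
    """
    if kind not in _VALUE_COLUMN:
        raise ValueError(f"kind must be 'visits' or 'temperature', got {kind!r}")
    value_col = _VALUE_COLUMN[kind]
    schema = VISITS_SCHEMA if kind == "visits" else TEMPERATURE_SCHEMA

    df = pd.read_csv(path, dtype={"park_id": str})
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing} (header must be {schema})")
    df = df[schema].copy()
    df["year"] = df["year"].astype(int)
    df["month"] = df["month"].astype(int)
    df[value_col] = df[value_col].astype(float)

    _validate_records(df, value_col, kind, str(path))
    logger.info("loaded %d %s rows from %s", len(df), kind, path)
    return df


def _validate_records(df: pd.DataFrame, value_col: str, kind: str, origin: str) -> None:
    bad_month = df.index[(df["month"] < 1) | (df["month"] > 12)]
    if len(bad_month):
        i = bad_month[0]
        raise TableFormatError(
            f"{origin}: row {i} ({df.loc[i, 'park_id']}, {df.loc[i, 'year']}) "
            f"has month={df.loc[i, 'month']} outside 1..12"
        )
    if df[value_col].isna().any():
        i = df.index[df[value_col].isna()][0]
        raise TableFormatError(f"{origin}: row {i} has missing {value_col}")
    if kind == "visits":
        neg = df.index[df[value_col] < 0]
        if len(neg):
            i = neg[0]
            raise TableFormatError(
                f"{origin}: row {i} ({df.loc[i, 'park_id']}, {df.loc[i, 'year']}-"
                f"{df.loc[i, 'month']:02d}) has negative visits {df.loc[i, value_col]}"
            )
        nonint = df[value_col] % 1 != 0
        if nonint.any():
            logger.warning(
                "%s: %d non-integer visit values (rescaled series?)", origin, int(nonint.sum())
            )
    dup = df.duplicated(subset=["park_id", "year", "month"], keep=False)
    if dup.any():
        i = df.index[dup][0]
        raise TableFormatError(
            f"{origin}: duplicated key (park_id={df.loc[i, 'park_id']}, "
            f"year={df.loc[i, 'year']}, month={df.loc[i, 'month']})"
        )


def write_monthly_table(df: pd.DataFrame, path) -> None:
    """Write a long-format table; full float precision so read(write(x)) == x."""
    df.to_csv(path, index=False, float_format="%.17g")


def complete_year_totals(visits: pd.DataFrame) -> pd.DataFrame:
    """Annual totals for complete calendar years (all 12 months present).

    Returns a frame ``park_id, year, annual_visits`` restricted to
    park-years with exactly 12 monthly records.
    """
    g = visits.groupby(["park_id", "year"])["recreation_visits"]
    agg = g.agg(n="size", annual_visits="sum").reset_index()
    return agg.loc[agg["n"] == 12, ["park_id", "year", "annual_visits"]].reset_index(drop=True)


def filter_parks(
    visits: pd.DataFrame,
    min_years: int = 10,
    min_mean_annual: float = 8000.0,
) -> tuple[list[str], list[InclusionReport]]:
    """Apply the park-inclusion rule: enough complete years, enough visitors.

    A park is retained iff it has at least `min_years` complete calendar
    years (all 12 months recorded) and the mean annual total over those
    complete years is at least `min_mean_annual`.  "Years of data" is read
    as complete calendar years so partial years cannot deflate the mean.
    """
    if visits.empty:
        raise ValueError("visits table is empty")
    totals = complete_year_totals(visits)
    reports: list[InclusionReport] = []
    retained: list[str] = []
    for park in sorted(visits["park_id"].unique()):
        t = totals.loc[totals["park_id"] == park, "annual_visits"]
        n_years = len(t)
        mean_annual = float(t.mean()) if n_years else 0.0
        if n_years < min_years:
            reports.append(InclusionReport(park, n_years, mean_annual, False, "years"))
        elif mean_annual < min_mean_annual:
            reports.append(InclusionReport(park, n_years, mean_annual, False, "visits"))
        else:
            reports.append(InclusionReport(park, n_years, mean_annual, True, ""))
            retained.append(park)
    logger.info("retained %d of %d parks", len(retained), len(reports))
    return retained, reports


def inclusion_table(reports: list[InclusionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "park_id": r.park_id,
                "n_complete_years": r.n_complete_years,
                "mean_annual_visits": r.mean_annual_visits,
                "retained": r.retained,
                "reason": r.reason,
            }
            for r in reports
        ]
    )


def build_climatology(
    visits: pd.DataFrame, temps: pd.DataFrame, park_id: str
) -> ParkClimatology:
    """Long-term monthly mean visits and temperature for one park.

    Each month's mean is taken over all years with a record for that month;
    the per-month year count is kept for audit.  A calendar month with no
    record at all is a hard error — the park cannot be modelled.
    """
    v = visits.loc[visits["park_id"] == park_id]
    t = temps.loc[temps["park_id"] == park_id]

    mean_v = np.empty(12)
    se_v = np.empty(12)
    n_v = np.empty(12, dtype=int)
    mean_t = np.empty(12)
    n_t = np.empty(12, dtype=int)
    for m in MONTHS:
        vm = v.loc[v["month"] == m, "recreation_visits"].to_numpy()
        tm = t.loc[t["month"] == m, "tmean_c"].to_numpy()
        if len(vm) == 0:
            raise ValueError(f"park {park_id}: no visit records for month {m}")
        if len(tm) == 0:
            raise ValueError(f"park {park_id}: no temperature records for month {m}")
        mean_v[m - 1] = vm.mean()
        se_v[m - 1] = vm.std(ddof=1) / np.sqrt(len(vm)) if len(vm) > 1 else 0.0
        n_v[m - 1] = len(vm)
        mean_t[m - 1] = tm.mean()
        n_t[m - 1] = len(tm)
        if len(vm) == 1:
            logger.warning("park %s month %d: single year, SE reported as 0", park_id, m)
    return ParkClimatology(park_id, mean_v, se_v, n_v, mean_t, n_t)


def build_climatologies(
    visits: pd.DataFrame, temps: pd.DataFrame, park_ids
) -> dict[str, ParkClimatology]:
    return {p: build_climatology(visits, temps, p) for p in park_ids}


def climatology_table(clims: dict[str, ParkClimatology]) -> pd.DataFrame:
    rows = []
    for p, c in clims.items():
        for m in MONTHS:
            rows.append(
                {
                    "park_id": p,
                    "month": int(m),
                    "mean_visits": c.mean_visits[m - 1],
                    "se_visits": c.se_visits[m - 1],
                    "n_years_visits": int(c.n_years_visits[m - 1]),
                    "mean_temp": c.mean_temp[m - 1],
                    "n_years_temp": int(c.n_years_temp[m - 1]),
                }
            )
    return pd.DataFrame(rows)
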