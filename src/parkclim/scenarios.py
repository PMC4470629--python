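"""Future temperature scenarios: delta bias-correction and ensemble selection.

The delta (change-factor) method removes climate-model bias by carrying
only the model-simulated change: subtract the model-era baseline from each
member's future monthly means, then add those deltas onto the observed
(station/reanalysis-era) baseline.  Low and high scenarios are formed by
ranking members on their annual mean temperature at the park and
ensemble-averaging the five lowest (low scenario, typically from the
moderate-forcing pathway) or five highest (high scenario, from the
high-forcing pathway).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from parkclim.core_io import MONTHS


@dataclass(frozen=True)
class ScenarioTemps:
    """Per-park future monthly temperature for a named scenario."""

    park_id: str
    scenario: str
    temps: np.ndarray  # 12 monthly means, °C
    members: tuple  # sorted member model ids

    def __post_init__(self):
        if len(self.temps) != 12 or not np.all(np.isfinite(self.temps)):
            raise ValueError("scenario needs 12 finite monthly temperatures")

    @property
    def annual_mean(self) -> float:
        return float(np.mean(self.temps))


def _month_table(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """Pivot to months-as-columns, erroring on missing months."""
    wide = df.pivot_table(index=by, columns="month", values=value, aggfunc="first")
    missing = [m for m in MONTHS if m not in wide.columns]
    if missing or wide.isna().any().any():
        bad = missing or sorted(wide.columns[wide.isna().any()])
        raise ValueError(f"missing months {bad} for some {by}")
    return wide[list(MONTHS)]


def compute_deltas(future: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """δ(park, model, m) = future(park, model, m) − baseline(park, m).

    `future` has columns park_id, model, rcp, month, tmean_c; `baseline`
    has park_id, month, tmean_c (both from the same gridded product, so
    the subtraction cancels its bias).  Returns the same long format with a
    `delta_c` column.
    """
    fut = _month_table(future, "tmean_c", ["park_id", "model", "rcp"])
    base = _month_table(baseline, "tmean_c", ["park_id"])
    rows = []
    for (park, model, rcp), temps in fut.iterrows():
        if park not in base.index:
            raise ValueError(f"no baseline for park {park}")
        d = temps.to_numpy() - base.loc[park].to_numpy()
        for m in MONTHS:
            rows.append({"park_id": park, "model": model, "rcp": rcp,
                         "month": int(m), "delta_c": d[m - 1]})
    return pd.DataFrame(rows)


def apply_deltas(observed_baseline: pd.DataFrame, deltas: pd.DataFrame) -> pd.DataFrame:
    """future(park, model, m) = observed baseline(park, m) + δ(park, model, m)."""
    base = _month_table(observed_baseline, "tmean_c", ["park_id"])
    dl = _month_table(deltas, "delta_c", ["park_id", "model", "rcp"])
    rows = []
    for (park, model, rcp), d in dl.iterrows():
        if park not in base.index:
            raise ValueError(f"no observed baseline for park {park}")
        t = base.loc[park].to_numpy() + d.to_numpy()
        for m in MONTHS:
            rows.append({"park_id": park, "model": model, "rcp": rcp,
                         "month": int(m), "tmean_c": t[m - 1]})
    return pd.DataFrame(rows)


def select_and_average_ensemble(
    future: pd.DataFrame,
    park_id: str,
    mode: str,
    n_select: int = 5,
    scenario: str | None = None,
    rcp: str | None = None,
) -> ScenarioTemps:
    """Rank one park's members by annual mean temperature; average the
    `n_select` lowest (mode="lowest") or highest (mode="highest").

    Ties in annual mean break lexicographically on model id, so the member
    set is deterministic and order-independent.
    """
    if mode not in ("lowest", "highest"):
        raise ValueError("mode must be 'lowest' or 'highest'")
    sub = future.loc[future["park_id"] == park_id]
    if rcp is not None:
        sub = sub.loc[sub["rcp"] == rcp]
    wide = _month_table(sub, "tmean_c", ["model"])
    if len(wide) < n_select:
        raise ValueError(
            f"park {park_id}: {len(wide)} members < n_select={n_select}"
        )
    annual = wide.mean(axis=1)
    ranked = sorted(annual.index, key=lambda m: (annual[m], m))
    members = ranked[:n_select] if mode == "lowest" else ranked[-n_select:]
    members = tuple(sorted(members))
    temps = wide.loc[list(members)].mean(axis=0).to_numpy()
    return ScenarioTemps(
        park_id=park_id,
        scenario=scenario or f"{mode}{n_select}",
        temps=temps,
        members=members,
    )


def build_scenarios(
    future: pd.DataFrame,
    park_ids,
    pairings: dict[str, tuple[str, str]] | None = None,
    n_select: int = 5,
) -> dict[tuple[str, str], ScenarioTemps]:
    """Named scenarios for every park.

    `pairings` maps scenario name -> (rcp label, mode); the default follows
    the low/high bookend convention: the five lowest members of the
    moderate pathway and the five highest of the high pathway.
    Returns {(park_id, scenario): ScenarioTemps}.
    """
    if pairings is None:
        pairings = {"rcp45_low": ("rcp45", "lowest"), "rcp85_high": ("rcp85", "highest")}
    out = {}
    for park in park_ids:
        for name, (rcp, mode) in pairings.items():
            out[(park, name)] = select_and_average_ensemble(
                future, park, mode, n_select=n_select, scenario=name, rcp=rcp
            )
    return out


def scenario_table(scens: dict[tuple[str, str], ScenarioTemps]) -> pd.DataFrame:
    rows = []
    for (park, name), s in sorted(scens.items()):
        for m in MONTHS:
            rows.append({"park_id": park, "scenario": name, "month": int(m),
                         "tmean_c": s.temps[m - 1], "members": ";".join(s.members)})
    return pd.DataFrame(rows)
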