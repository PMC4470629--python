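"""Project future monthly visitation for temperature-sensitive parks.

Predictions come from each park's selected historical polynomial evaluated
at the scenario temperatures, with the OLS standard error of the mean
prediction.  Projected months are clamped into [0, (1+g)·busiest
historical month] — negative polynomial extrapolations are floored at
zero, and growth above the ceiling g (5% or 25% by convention) over the
historical maximum monthly mean is capped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from parkclim.core_io import MONTHS, ParkClimatology
from parkclim.models import ParkFit
from parkclim.scenarios import ScenarioTemps


class NotTemperatureSensitiveError(ValueError):
    """Projection refused: the park fails the sensitivity rule (temperature
    in the best-fit model and adjusted R² ≥ 0.5)."""


@dataclass(frozen=True)
class MonthlyProjection:
    park_id: str
    scenario: str
    growth_ceiling: float
    month: int
    predicted: float  # uncapped polynomial prediction
    se: float  # OLS SE of the mean prediction (uncapped)
    capped_value: float  # clamp(predicted, 0, ceiling)
    capped: bool
    floored: bool


@dataclass(frozen=True)
class ParkProjection:
    park_id: str
    scenario: str
    growth_ceiling: float
    months: tuple  # 12 MonthlyProjection
    historical_annual: float
    projected_annual: float  # sum of capped values

    @property
    def pct_of_historical(self) -> float:
        return 100.0 * self.projected_annual / self.historical_annual


def predict_monthly(fit: ParkFit, scenario: ScenarioTemps) -> tuple[np.ndarray, np.ndarray]:
    """(prediction, SE) of mean monthly visits at the scenario temperatures."""
    if not fit.temp_sensitive:
        raise NotTemperatureSensitiveError(
            f"park {fit.park_id}: projection is limited to parks with temperature "
            "in the best-fit model and adjusted R^2 >= 0.5"
        )
    pred = fit.predict(scenario.temps)
    tc = np.asarray(scenario.temps, float) - fit.temp_center
    X = np.column_stack([tc**j for j in range(fit.selected_order + 1)])
    se = fit._result.get_prediction(X).se_mean
    return np.asarray(pred, float), np.asarray(se, float)


def apply_growth_ceiling(
    predicted: np.ndarray,
    se: np.ndarray,
    clim: ParkClimatology,
    g: float,
    park_id: str,
    scenario: str,
) -> list[MonthlyProjection]:
    """Clamp each month into [0, (1+g) · max historical monthly mean]."""
    if g <= -1:
        raise ValueError("growth ceiling must exceed -1")
    ceiling = (1.0 + g) * float(clim.mean_visits.max())
    out = []
    for m in MONTHS:
        p = float(predicted[m - 1])
        capped_value = min(max(p, 0.0), ceiling)
        out.append(
            MonthlyProjection(
                park_id=park_id,
                scenario=scenario,
                growth_ceiling=g,
                month=int(m),
                predicted=p,
                se=float(se[m - 1]),
                capped_value=capped_value,
                capped=p > ceiling,
                floored=p < 0.0,
            )
        )
    return out


def project_park(
    fit: ParkFit, clim: ParkClimatology, scenario: ScenarioTemps, g: float
) -> ParkProjection:
    """predict_monthly then apply_growth_ceiling, with annual bookkeeping."""
    pred, se = predict_monthly(fit, scenario)
    months = apply_growth_ceiling(pred, se, clim, g, fit.park_id, scenario.scenario)
    return ParkProjection(
        park_id=fit.park_id,
        scenario=scenario.scenario,
        growth_ceiling=g,
        months=tuple(months),
        historical_annual=clim.annual_total,
        projected_annual=float(sum(mp.capped_value for mp in months)),
    )


def project_system(
    fits: dict[str, ParkFit],
    clims: dict[str, ParkClimatology],
    scens: dict[tuple[str, str], ScenarioTemps],
    growth_ceilings=(0.05, 0.25),
) -> list[ParkProjection]:
    """All scenario × ceiling projections for the temperature-sensitive parks."""
    out = []
    for (park, name), scen in sorted(scens.items()):
        fit = fits[park]
        if not fit.temp_sensitive:
            continue
        for g in growth_ceilings:
            out.append(project_park(fit, clims[park], scen, g))
    return out


def projection_table(projections) -> pd.DataFrame:
    rows = []
    for pp in projections:
        for mp in pp.months:
            rows.append(
                {"park_id": mp.park_id, "scenario": mp.scenario,
                 "growth": mp.growth_ceiling, "month": mp.month,
                 "predicted": mp.predicted, "se": mp.se,
                 "capped_value": mp.capped_value, "capped": mp.capped,
                 "floored": mp.floored}
            )
    return pd.DataFrame(rows)
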