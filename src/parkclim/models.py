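"""System-wide GLM and per-park polynomial models of visitation vs temperature.

The system model is a binomial GLM (logit link) of the proportion of a
park's annual visits falling in each month, with a raw polynomial in
centered monthly mean temperature (order 0..3) plus a park categorical
term; candidate orders are compared by BIC computed from the binomial-form
log-likelihood evaluated at the observed proportions, and a quasibinomial
(Pearson) dispersion is reported for inference.  Per park, ordinary least
squares of long-term mean monthly visits on the same polynomial family is
selected by Gaussian-likelihood BIC at n = 12; a park is
temperature-sensitive when its best model includes temperature and reaches
adjusted R² ≥ 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import xlogy

from parkclim.core_io import MONTHS, ParkClimatology

logger = logging.getLogger(__name__)

ORDERS = (0, 1, 2, 3)


def monthly_proportions(clim: ParkClimatology) -> np.ndarray:
    """Proportion of the park's annual visits falling in each month."""
    total = clim.annual_total
    if total <= 0:
        raise ValueError(f"park {clim.park_id}: annual total is zero")
    p = clim.mean_visits / total
    assert abs(p.sum() - 1.0) < 1e-12
    return p


def system_design_dims(n_parks: int, order: int, n_months: int = 12) -> dict:
    """Row/parameter/df bookkeeping of the system GLM design, data-free.

    Parameters are one intercept per park (categorical) plus `order`
    temperature terms.
    """
    n_obs = n_parks * n_months
    n_params = n_parks + order
    return {"n_obs": n_obs, "n_params": n_params, "residual_df": n_obs - n_params}


@dataclass(frozen=True)
class SystemFit:
    """One fitted system-wide GLM candidate."""

    order: int
    temp_coefficients: np.ndarray  # β₁..β_k on centered temperature
    park_effects: dict  # park_id -> intercept on the logit scale
    loglik: float  # binomial-form log-likelihood at the proportions
    bic: float
    mcfadden_r2: float
    dispersion: float  # Pearson, quasibinomial-style
    n_obs: int
    n_parks: int
    temp_center: float
    delta_bic: float | None = None  # to runner-up, set by selection

    @property
    def n_params(self) -> int:
        return self.n_parks + self.order

    @property
    def residual_df(self) -> int:
        return self.n_obs - self.n_params


def _binomial_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    # Bernoulli-form log-likelihood evaluated at (possibly non-integer)
    # proportions; xlogy handles y == 0 and y == 1 exactly.
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(xlogy(y, mu) + xlogy(1 - y, 1 - mu)))


def _system_design(clims, order: int):
    parks = sorted(clims)
    y, temps, park_idx = [], [], []
    for i, p in enumerate(parks):
        y.append(monthly_proportions(clims[p]))
        temps.append(clims[p].mean_temp)
        park_idx.extend([i] * 12)
    y = np.concatenate(y)
    temps = np.concatenate(temps)
    center = temps.mean()
    tc = temps - center
    X = np.zeros((len(y), len(parks) + order))
    X[np.arange(len(y)), np.asarray(park_idx)] = 1.0
    for j in range(1, order + 1):
        X[:, len(parks) + j - 1] = tc**j
    return parks, y, X, center


def fit_system_glm(
    clims: dict, order: int, null_loglik: float | None = None, maxiter: int = 200
) -> SystemFit:
    """Fit the system GLM at one polynomial order.

    `clims` maps park_id -> ParkClimatology (≥ 2 parks).  The McFadden R²
    is computed against the order-0 (park-term-only) fit; pass its
    log-likelihood as `null_loglik` to avoid refitting it.
    """
    if order not in ORDERS:
        raise ValueError(f"order must be in {ORDERS}")
    if len(clims) < 2:
        raise ValueError("system fit needs at least 2 parks")
    parks, y, X, center = _system_design(clims, order)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=maxiter)
    if not res.converged:
        raise RuntimeError(
            f"system GLM (order {order}) did not converge in {maxiter} iterations; "
            f"deviance={res.deviance:.4g}"
        )
    mu = np.asarray(res.fittedvalues)
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        logger.warning("system GLM order %d: fitted proportions near 0/1 (separation?)", order)
    lnL = _binomial_loglik(y, mu)
    dims = system_design_dims(len(parks), order)
    bic = dims["n_params"] * np.log(dims["n_obs"]) - 2 * lnL
    pearson = float(np.sum((y - mu) ** 2 / (mu * (1 - mu))) / dims["residual_df"])

    if order == 0:
        null_lnL = lnL
    elif null_loglik is not None:
        null_lnL = null_loglik
    else:
        null_lnL = fit_system_glm(clims, 0).loglik
    if null_lnL == 0:
        raise ValueError("null log-likelihood is zero (degenerate data)")
    return SystemFit(
        order=order,
        temp_coefficients=np.asarray(res.params[len(parks):]),
        park_effects=dict(zip(parks, np.asarray(res.params[: len(parks)]))),
        loglik=lnL,
        bic=float(bic),
        mcfadden_r2=float(1.0 - lnL / null_lnL),
        dispersion=pearson,
        n_obs=dims["n_obs"],
        n_parks=len(parks),
        temp_center=float(center),
    )


def mcfadden_r2(fit, null_fit) -> float:
    """McFadden's pseudo-R²: 1 − lnL_fit / lnL_null."""
    if null_fit.loglik == 0:
        raise ValueError("null log-likelihood is zero (degenerate data)")
    return float(1.0 - fit.loglik / null_fit.loglik)


def fit_all_system_orders(clims: dict) -> dict[int, SystemFit]:
    null = fit_system_glm(clims, 0)
    fits = {0: null}
    for k in ORDERS[1:]:
        fits[k] = fit_system_glm(clims, k, null_loglik=null.loglik)
    return fits


def select_system_model(fits: dict[int, SystemFit]) -> SystemFit:
    """Minimum-BIC candidate; ties go to the lower order; ΔBIC recorded."""
    missing = [k for k in ORDERS if k not in fits]
    if missing:
        raise ValueError(f"missing candidate orders {missing}")
    best = min(ORDERS, key=lambda k: (fits[k].bic, k))
    others = [fits[k].bic for k in ORDERS if k != best]
    from dataclasses import replace

    return replace(fits[best], delta_bic=float(min(others) - fits[best].bic))


# ---------------------------------------------------------------------------
# Per-park models


@dataclass
class ParkFit:
    """Per-park polynomial regression of mean monthly visits on temperature."""

    park_id: str
    temp_center: float
    coefficients_by_order: dict  # order -> ascending coefs in centered temp
    rss_by_order: dict
    bic_by_order: dict
    selected_order: int
    adj_r2: float
    temp_sensitive: bool
    skipped_orders: tuple = ()
    _result: object = field(default=None, repr=False, compare=False)

    @property
    def coefficients(self) -> np.ndarray:
        return self.coefficients_by_order[self.selected_order]

    def design_row(self, temp: float) -> np.ndarray:
        tc = temp - self.temp_center
        return np.array([tc**j for j in range(self.selected_order + 1)])

    def predict(self, temps: np.ndarray) -> np.ndarray:
        tc = np.asarray(temps, float) - self.temp_center
        return np.polynomial.polynomial.polyval(tc, self.coefficients)


def gaussian_bic(rss: float, n: int, n_params: int) -> float:
    """BIC of a Gaussian regression up to an additive constant in n."""
    rss = max(float(rss), 1e-300)
    return n * np.log(rss / n) + n_params * np.log(n)


def fit_park_models(
    clim: ParkClimatology, max_order: int = 3, sensitivity_adj_r2: float = 0.5
) -> ParkFit:
    """OLS of the 12 long-term mean monthly visits on centered temperature.

    Candidate raw-polynomial orders 0..max_order are compared by
    Gaussian-likelihood BIC (n = 12); ties break toward the lower order.
    If all 12 temperatures are identical the polynomial columns are
    collinear and orders ≥ 1 are skipped with a warning.
    """
    y = clim.mean_visits
    t = clim.mean_temp
    center = float(t.mean())
    tc = t - center

    degenerate = np.ptp(t) == 0
    orders = [0] if degenerate else list(range(max_order + 1))
    if degenerate and max_order >= 1:
        logger.warning("park %s: constant temperature, orders >= 1 skipped", clim.park_id)

    coefs, rss, bic, results = {}, {}, {}, {}
    n = 12
    # RSS below numerical precision of the fit means "exact"; clamp so that
    # exact fits at several orders tie and parsimony resolves the order
    rss_floor = (1e-8 * max(1.0, float(np.abs(y).max()))) ** 2 * n
    for k in orders:
        X = np.column_stack([tc**j for j in range(k + 1)])
        res = sm.OLS(y, X).fit()
        coefs[k] = np.asarray(res.params)
        rss[k] = float(res.ssr)
        bic[k] = gaussian_bic(max(res.ssr, rss_floor), n, k + 1)
        results[k] = res
    selected = min(orders, key=lambda k: (bic[k], k))
    adj = float(results[selected].rsquared_adj)
    if not np.isfinite(adj):  # intercept-only model
        adj = 0.0
    return ParkFit(
        park_id=clim.park_id,
        temp_center=center,
        coefficients_by_order=coefs,
        rss_by_order=rss,
        bic_by_order=bic,
        selected_order=selected,
        adj_r2=adj,
        temp_sensitive=bool(selected >= 1 and adj >= sensitivity_adj_r2),
        skipped_orders=tuple(k for k in range(max_order + 1) if k not in orders),
        _result=results[selected],
    )


def classify_parks(fits) -> dict:
    """Summary counts over a collection of ParkFit."""
    fits = list(fits)
    if not fits:
        raise ValueError("no park fits to classify")
    orders = np.array([f.selected_order for f in fits])
    adj = np.array([f.adj_r2 for f in fits])
    return {
        "n_parks": len(fits),
        "counts_by_order": {k: int((orders == k).sum()) for k in ORDERS},
        "n_temperature_in_best": int((orders >= 1).sum()),
        "n_temperature_sensitive": sum(f.temp_sensitive for f in fits),
        "mean_adj_r2": float(adj.mean()),
        "median_adj_r2": float(np.median(adj)),
    }


def park_fit_table(fits) -> pd.DataFrame:
    """ParkFit table: one row per park, coefficients of the selected model."""
    rows = []
    for f in fits:
        b = {f"b{j}": np.nan for j in range(4)}
        for j, c in enumerate(f.coefficients):
            b[f"b{j}"] = c
        row = {"park_id": f.park_id, "selected_order": f.selected_order, **b,
               "adj_r2": f.adj_r2}
        for k in ORDERS:
            row[f"bic{k}"] = f.bic_by_order.get(k, np.nan)
        row["temp_sensitive"] = f.temp_sensitive
        rows.append(row)
    return pd.DataFrame(rows)
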