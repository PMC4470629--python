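"""Synthetic park systems with known ground truth.

Generates (a) per-park monthly temperature series with a sinusoidal
climate-normal cycle plus interannual noise, (b) overdispersed monthly
visit counts whose expected seasonal shape is a softmax-normalised
positive response to temperature, and (c) a pseudo-GCM ensemble of
additive warming offsets in the style of a downscaled CMIP5 table.
Every generator is deterministic under its seed, and every construction
records its ground truth so downstream fits have a parameter-recovery
test surface.

The latent visitation response is placed on the log scale: the monthly
weight is ``softmax(log q(T))`` where ``q`` is a positive polynomial of
known order in standardized temperature (``response_space="visits"``,
the default — the expected visit curve is then itself polynomial in
temperature, so polynomial-order recovery is well defined), or
``exp`` of a polynomial latent (``response_space="log"``, the natural
surface for the logit-link system GLM).  Expected visitation follows the
park's climate-normal cycle, not the realized yearly anomaly: visitors
plan trips months in advance on long-term averages.  Set
``couple_to_realized=True`` in :func:`simulate_visits` to tie weights to
the realized temperatures instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from parkclim.core_io import MONTHS

# Latent temperature response shared across parks in shared-response
# systems: 0.08·(T−10) + 0.0006·(T−10)³, expanded in ascending powers of
# absolute temperature (°C).  Monotone rising with an inflection at 10°C,
# so every polynomial order up to the cubic leaves a distinct signature on
# the visitation proportions — the shape is a recovery surface for
# system-level model selection, not a claim about any particular park
# system.
SHARED_CUBIC_RESPONSE = np.array([-1.4, 0.26, -0.018, 0.0006])


@dataclass(frozen=True)
class ParkGenerator:
    """Generating parameters for one synthetic park.

    ``beta`` are the response-polynomial coefficients (ascending, length
    order+1) in standardized temperature u = (T − t_mean)/amplitude unless
    ``basis="absolute"`` (coefficients in raw °C).  ``annual_scale`` is the
    expected total annual visits; ``dispersion`` is the variance inflation
    of monthly counts (variance = dispersion · mean).
    """

    park_id: str
    t_mean: float
    amplitude: float
    order: int
    beta: tuple
    annual_scale: float
    dispersion: float = 2.0
    n_years: int = 30
    sigma_t: float = 1.0
    peak_month: float = 7.0
    calendar_sd: float = 0.06
    start_year: int = 1984
    response_space: str = "visits"  # "visits" | "log"
    basis: str = "standardized"  # "standardized" | "absolute"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.order <= 3:
            raise ValueError("order must be in 0..3")
        if len(self.beta) != self.order + 1:
            raise ValueError("beta must have order+1 coefficients")
        if self.annual_scale <= 0:
            raise ValueError("annual_scale must be positive")
        if self.dispersion < 1:
            raise ValueError("dispersion must be >= 1")

    def expected_temps(self) -> np.ndarray:
        """Climate-normal monthly mean temperature (12 values, °C)."""
        return self.t_mean + self.amplitude * np.cos(
            2 * np.pi * (MONTHS - self.peak_month) / 12.0
        )

    def _standardize(self, temps: np.ndarray) -> np.ndarray:
        if self.basis == "absolute":
            return np.asarray(temps, dtype=float)
        if self.amplitude == 0:
            return np.zeros_like(np.asarray(temps, dtype=float))
        return (np.asarray(temps, dtype=float) - self.t_mean) / self.amplitude

    def calendar_pattern(self) -> np.ndarray:
        """Calendar (non-temperature) seasonal structure, as relative offsets.

        Real visitation carries holiday/school-vacation signal that monthly
        temperature cannot explain.  The pattern is constructed to be
        invisible to any temperature response: equal-and-opposite offsets
        within pairs of months whose climate-normal temperatures coincide
        (e.g. the months either side of the warm peak).  Zero when
        `calendar_sd` is 0 or no month pair shares a normal temperature.
        """
        h = np.zeros(12)
        if self.calendar_sd == 0:
            return h
        t = self.expected_temps()
        tol = 1e-6 * max(self.amplitude, 1.0)
        rng = _rng(self.seed, 2)
        used: set[int] = set()
        for i in range(12):
            if i in used:
                continue
            for j in range(i + 1, 12):
                if j not in used and abs(t[j] - t[i]) < tol:
                    d = rng.normal(0.0, self.calendar_sd)
                    h[i] += d
                    h[j] -= d
                    used.update((i, j))
                    break
            used.add(i)
        return np.clip(h, -0.5, 0.5)

    def monthly_weights(self, temps: np.ndarray | None = None) -> np.ndarray:
        """Softmax-normalised monthly visitation weights (sum to 1 exactly)."""
        t = self.expected_temps() if temps is None else np.asarray(temps, float)
        u = self._standardize(t)
        latent = np.polynomial.polynomial.polyval(u, np.asarray(self.beta, float))
        if self.response_space == "visits":
            q = np.asarray(latent, dtype=float)
            qmax = q.max()
            floor = 1e-9 * max(abs(qmax), 1.0)
            w = np.maximum(q, floor)
        else:
            # log space: softmax with max subtraction so exp never overflows
            w = np.exp(latent - latent.max())
        w = w * (1.0 + self.calendar_pattern())
        return w / w.sum()

    def expected_visits(self, temps: np.ndarray | None = None) -> np.ndarray:
        """True expected monthly visits μ (sums to annual_scale exactly)."""
        return self.annual_scale * self.monthly_weights(temps)

    def true_visit_polynomial(self) -> np.ndarray:
        """Temperature-response component of the expected-visits curve, as
        ascending coefficients in absolute °C.

        Only defined for ``response_space="visits"`` (where the response is
        a genuine polynomial of the generating order).  The calendar
        pattern, being orthogonal to any temperature response, is excluded;
        the scale uses the calendar-free normalisation.
        """
        if self.response_space != "visits":
            raise ValueError("polynomial truth only defined in visit space")
        P = np.polynomial.Polynomial
        q = P(np.asarray(self.beta, float))
        if self.basis == "standardized":
            if self.amplitude == 0:
                q = P([q(0.0)])
            else:
                q = q(P([-self.t_mean / self.amplitude, 1.0 / self.amplitude]))
        u = self._standardize(self.expected_temps())
        qvals = np.polynomial.polynomial.polyval(u, np.asarray(self.beta, float))
        scale = self.annual_scale / qvals.sum()
        coef = scale * q.coef
        out = np.zeros(self.order + 1)
        out[: len(coef)] = coef[: self.order + 1]
        return out


@dataclass(frozen=True)
class PseudoGCM:
    """One ensemble member: additive monthly warming offsets (°C)."""

    model_id: str
    offsets: tuple  # 12 per-month δ values
    rcp: str

    @property
    def annual_mean_offset(self) -> float:
        return float(np.mean(self.offsets))


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def simulate_temperature(gen: ParkGenerator) -> pd.DataFrame:
    """Monthly mean temperature records for all park-years.

    T(y, m) = climate normal(m) + Normal(0, sigma_t), iid across park-years.
    """
    if gen.n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = _rng(gen.seed, 0)
    normal = gen.expected_temps()
    years = np.arange(gen.start_year, gen.start_year + gen.n_years)
    rows = []
    for y in years:
        eps = rng.normal(0.0, gen.sigma_t, 12) if gen.sigma_t > 0 else np.zeros(12)
        for m in MONTHS:
            rows.append(
                {"park_id": gen.park_id, "year": int(y), "month": int(m),
                 "tmean_c": normal[m - 1] + eps[m - 1]}
            )
    return pd.DataFrame(rows)


def simulate_visits(
    gen: ParkGenerator, temps: pd.DataFrame, couple_to_realized: bool = False
) -> pd.DataFrame:
    """Overdispersed monthly visit counts for all park-years in `temps`.

    Expected counts are μ_m = annual_scale · weight_m with weights from the
    climate-normal cycle (or the realized temperatures when
    `couple_to_realized`).  Counts are negative-binomial with
    Var = dispersion · μ (Poisson when dispersion == 1).
    """
    t = temps.loc[temps["park_id"] == gen.park_id]
    if t.empty:
        raise ValueError(f"no temperatures for park {gen.park_id}")
    rng = _rng(gen.seed, 1)
    rows = []
    for year, grp in t.groupby("year"):
        grp = grp.sort_values("month")
        if not np.array_equal(grp["month"].to_numpy(), MONTHS):
            raise ValueError(f"park {gen.park_id} year {year}: incomplete months")
        mu = gen.expected_visits(
            grp["tmean_c"].to_numpy() if couple_to_realized else None
        )
        counts = _overdispersed_counts(rng, mu, gen.dispersion)
        for m, c in zip(MONTHS, counts):
            rows.append(
                {"park_id": gen.park_id, "year": int(year), "month": int(m),
                 "recreation_visits": float(c)}
            )
    return pd.DataFrame(rows)


def _overdispersed_counts(rng, mu: np.ndarray, phi: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-12)
    if phi == 1.0:
        return rng.poisson(mu)
    r = mu / (phi - 1.0)
    return rng.negative_binomial(r, r / (r + mu))


def simulate_park(gen: ParkGenerator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(visits, temps) tables for one park."""
    temps = simulate_temperature(gen)
    visits = simulate_visits(gen, temps)
    return visits, temps


def simulate_system(generators) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenated (visits, temps) tables for a list of parks."""
    v, t = [], []
    for g in generators:
        vi, ti = simulate_park(g)
        v.append(vi)
        t.append(ti)
    return pd.concat(v, ignore_index=True), pd.concat(t, ignore_index=True)


# ---------------------------------------------------------------------------
# Default study system

#: Mixing proportions for the generating polynomial order, chosen to echo the
#: distribution of best-fit orders observed across a large real park system.
DEFAULT_ORDER_PROBS = {0: 0.05, 1: 0.31, 2: 0.39, 3: 0.25}


def _sample_response(rng, order: int, u_grid: np.ndarray) -> tuple:
    """Positive order-`order` polynomial on the park's standardized temps.

    The leading coefficient is kept away from zero so the generating order
    is identifiable; the curve is shifted upward so it stays strictly
    positive over the months the park actually experiences.  Most sloped
    parks (≈85%) are oriented so visitation is higher in warm months, the
    dominant pattern in mid/high-latitude protected-area systems; the rest
    keep a cool-season peak (tropical/hot-desert parks).
    """
    if order == 0:
        return (1.0,)
    b = np.zeros(order + 1)
    b[0] = 1.0
    if order > 1:
        b[1:order] = rng.uniform(-0.5, 0.5, order - 1)
    b[order] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2)
    q = np.polynomial.polynomial.polyval(u_grid, b)
    warm_peak = rng.random() < 0.85
    if (np.corrcoef(q, u_grid)[0, 1] > 0) != warm_peak:
        b[1::2] *= -1.0  # mirror u -> -u: preserves order, flips orientation
        q = np.polynomial.polynomial.polyval(u_grid, b)
    span = q.max() - q.min()
    b[0] += 0.1 * span - q.min()
    return tuple(b)


def make_default_system(
    seed: int,
    n_parks: int = 50,
    n_years: int = 30,
    dispersion: float = 2.0,
    sigma_t: float = 1.0,
) -> list[ParkGenerator]:
    """The default 50-park study system.

    Mean annual temperatures span −5..28 °C, seasonal amplitudes 3..14 °C,
    annual totals log-uniform over 8·10³..2·10⁶ visits, generating orders
    mixed per :data:`DEFAULT_ORDER_PROBS`.
    """
    rng = _rng(seed, 100)
    orders = list(DEFAULT_ORDER_PROBS)
    probs = np.array([DEFAULT_ORDER_PROBS[k] for k in orders])
    gens = []
    for i in range(n_parks):
        t0 = rng.uniform(-5.0, 28.0)
        amp = rng.uniform(3.0, 14.0)
        k = int(rng.choice(orders, p=probs))
        scale = float(np.exp(rng.uniform(np.log(8e3), np.log(2e6))))
        u = np.cos(2 * np.pi * (MONTHS - 7.0) / 12.0)  # standardized normal cycle
        gens.append(
            ParkGenerator(
                park_id=f"P{i:03d}",
                t_mean=t0,
                amplitude=amp,
                order=k,
                beta=_sample_response(rng, k, u),
                annual_scale=scale,
                dispersion=dispersion,
                n_years=n_years,
                sigma_t=sigma_t,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return gens


def make_shared_response_system(
    seed: int,
    n_parks: int = 60,
    n_years: int = 20,
    coeffs: np.ndarray = SHARED_CUBIC_RESPONSE,
    dispersion: float = 2.0,
    sigma_t: float = 1.0,
) -> list[ParkGenerator]:
    """Parks sharing one latent log-scale response in absolute temperature.

    The system GLM's logit-linear structure is then correct up to the park
    intercept, so system-level polynomial-order recovery is well posed.
    """
    rng = _rng(seed, 200)
    coeffs = tuple(np.asarray(coeffs, float))
    gens = []
    for i in range(n_parks):
        gens.append(
            ParkGenerator(
                park_id=f"S{i:03d}",
                t_mean=rng.uniform(-5.0, 28.0),
                amplitude=rng.uniform(3.0, 14.0),
                order=len(coeffs) - 1,
                beta=coeffs,
                annual_scale=float(np.exp(rng.uniform(np.log(8e3), np.log(2e6)))),
                dispersion=dispersion,
                n_years=n_years,
                sigma_t=sigma_t,
                response_space="log",
                basis="absolute",
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return gens


# ---------------------------------------------------------------------------
# Pseudo-GCM ensemble

def simulate_gcm_ensemble(
    generators,
    rcp: str,
    n_models: int = 17,
    warming_mean: float = 1.3,
    warming_spread: float = 0.5,
    month_jitter: float = 0.3,
    baseline_bias_sd: float = 0.5,
    seed: int = 0,
) -> tuple[list[PseudoGCM], pd.DataFrame, pd.DataFrame, dict]:
    """Additive-warming ensemble plus baseline/future temperature tables.

    Each member's monthly offset is a model-level mean warming
    ~Normal(warming_mean, warming_spread) plus per-month jitter.  The
    gridded-product baseline for each park is its climate-normal cycle plus
    a fixed per-month product bias (which the delta method must cancel).

    Returns (members, baseline_table, future_table, truth) where truth
    records the exact offsets and the 5-lowest / 5-highest member sets by
    annual mean offset.
    """
    if n_models < 5:
        raise ValueError("ensemble needs at least 5 members")
    rng = _rng(seed, 300 + (0 if rcp.endswith("45") else 1))
    members = []
    for j in range(n_models):
        w = rng.normal(warming_mean, warming_spread)
        offs = w + rng.normal(0.0, month_jitter, 12)
        members.append(PseudoGCM(f"gcm{j:02d}", tuple(offs), rcp))

    order = np.argsort([m.annual_mean_offset for m in members], kind="stable")
    lowest5 = sorted(members[i].model_id for i in order[:5])
    highest5 = sorted(members[i].model_id for i in order[-5:])

    base_rows, fut_rows = [], []
    for g in generators:
        normal = g.expected_temps()
        bias = rng.normal(0.0, baseline_bias_sd, 12)
        for m in MONTHS:
            base_rows.append(
                {"park_id": g.park_id, "year": 1975, "month": int(m),
                 "tmean_c": normal[m - 1] + bias[m - 1], "source": "worldclim"}
            )
        for mem in members:
            for m in MONTHS:
                fut_rows.append(
                    {"park_id": g.park_id, "model": mem.model_id, "rcp": rcp,
                     "month": int(m),
                     "tmean_c": normal[m - 1] + bias[m - 1] + mem.offsets[m - 1]}
                )
    truth = {
        "rcp": rcp,
        "offsets": {m.model_id: list(m.offsets) for m in members},
        "annual_mean_offsets": {m.model_id: m.annual_mean_offset for m in members},
        "lowest5": lowest5,
        "highest5": highest5,
    }
    return members, pd.DataFrame(base_rows), pd.DataFrame(fut_rows), truth


def system_truth(generators) -> dict:
    """Ground-truth sidecar for a generated system (JSON-serialisable)."""
    return {
        g.park_id: {
            "order": g.order,
            "beta": list(map(float, g.beta)),
            "response_space": g.response_space,
            "basis": g.basis,
            "t_mean": g.t_mean,
            "amplitude": g.amplitude,
            "annual_scale": g.annual_scale,
            "dispersion": g.dispersion,
            "sigma_t": g.sigma_t,
            "expected_temps": list(map(float, g.expected_temps())),
            "expected_visits": list(map(float, g.expected_visits())),
        }
        for g in generators
    }


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
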