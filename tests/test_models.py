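import dataclasses

import numpy as np
import pytest

from helpers import make_clim

from parkclim import core_io, models, synthetic


class TestMonthlyProportions:
    def test_equal_months(self):
        clim = make_clim("A", np.full(12, 100.0), np.zeros(12))
        assert np.allclose(models.monthly_proportions(clim), 1 / 12)

    def test_single_nonzero_month(self):
        v = np.zeros(12)
        v[6] = 500.0
        p = models.monthly_proportions(make_clim("A", v, np.zeros(12)))
        assert p[6] == 1.0 and p.sum() == 1.0

    def test_hand_arithmetic(self):
        v = np.full(12, 1050 / 11)
        v[6] = 150.0
        v *= 1200.0 / v.sum()
        p = models.monthly_proportions(make_clim("A", v, np.zeros(12)))
        assert p[6] == pytest.approx(150.0 / 1200.0)

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            models.monthly_proportions(make_clim("A", np.zeros(12), np.zeros(12)))


class TestSystemDesign:
    @pytest.mark.parametrize(
        "n_parks, order, n_obs, residual_df",
        [(340, 3, 4080, 3737), (340, 0, 4080, 3740), (50, 3, 600, 547)],
    )
    def test_dimension_bookkeeping(self, n_parks, order, n_obs, residual_df):
        dims = models.system_design_dims(n_parks, order)
        assert dims["n_obs"] == n_obs
        assert dims["residual_df"] == residual_df
        assert dims["n_params"] == n_parks + order


@pytest.fixture(scope="module")
def small_system_clims(default_system):
    parks = sorted(default_system["clims"])[:10]
    return {p: default_system["clims"][p] for p in parks}


class TestSystemGLM:
    def test_order_zero_is_the_null(self, small_system_clims):
        f0 = models.fit_system_glm(small_system_clims, 0)
        assert f0.mcfadden_r2 == 0.0
        assert f0.residual_df == f0.n_obs - f0.n_parks

    def test_loglik_nondecreasing_in_order(self, small_system_clims):
        fits = models.fit_all_system_orders(small_system_clims)
        lls = [fits[k].loglik for k in models.ORDERS]
        assert np.all(np.diff(lls) >= -1e-8)
        assert all(0 <= fits[k].mcfadden_r2 <= 1 for k in models.ORDERS)
        assert all(np.isfinite(fits[k].bic) for k in models.ORDERS)

    def test_selection_argmin_and_ties(self, small_system_clims):
        fits = models.fit_all_system_orders(small_system_clims)
        def with_bics(bics):
            return {
                k: dataclasses.replace(fits[k], bic=b) for k, b in zip(models.ORDERS, bics)
            }
        best = models.select_system_model(with_bics([100.0, 90.0, 95.0, 97.0]))
        assert best.order == 1 and best.delta_bic == pytest.approx(5.0)
        tied = models.select_system_model(with_bics([100.0, 90.0, 90.0, 97.0]))
        assert tied.order == 1  # exact tie resolves to the lower order
        with pytest.raises(ValueError, match="missing candidate"):
            models.select_system_model({0: fits[0]})

    def test_selection_matches_exhaustive_enumeration(self, default_system):
        clims = default_system["clims"]
        sub = {p: clims[p] for p in sorted(clims)[:8]}
        fits = models.fit_all_system_orders(sub)
        best = models.select_system_model(fits)
        brute = min(models.ORDERS, key=lambda k: (fits[k].bic, k))
        assert best.order == brute

    def test_cubic_latent_recovered_across_replicates(self):
        # shared S-shaped cubic response: the cubic must win BIC selection
        hits = 0
        reps = 15
        for seed in range(reps):
            gens = synthetic.make_shared_response_system(seed=seed, n_parks=60, n_years=20)
            v, t = synthetic.simulate_system(gens)
            clims = core_io.build_climatologies(v, t, [g.park_id for g in gens])
            best = models.select_system_model(models.fit_all_system_orders(clims))
            hits += best.order == 3
        assert hits >= 0.9 * reps


class TestMcFadden:
    class F:
        def __init__(self, ll):
            self.loglik = ll

    def test_fit_equal_null_gives_zero(self):
        assert models.mcfadden_r2(self.F(-10.0), self.F(-10.0)) == 0.0

    def test_half_loglik_gives_half(self):
        assert models.mcfadden_r2(self.F(-5.0), self.F(-10.0)) == pytest.approx(0.5)

    def test_zero_null_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            models.mcfadden_r2(self.F(-5.0), self.F(0.0))

    def test_park_term_never_hurts(self, small_system_clims):
        # vs the same intercept-only null, the with-park fit can only gain
        import statsmodels.api as sm
        from parkclim.models import _binomial_loglik, _system_design
        parks, y, X, _ = _system_design(small_system_clims, 1)
        n_parks = len(parks)
        Xnopark = np.column_stack([np.ones(len(y)), X[:, n_parks:]])
        mu_np = sm.GLM(y, Xnopark, family=sm.families.Binomial()).fit().fittedvalues
        ll_nopark = _binomial_loglik(y, np.asarray(mu_np))
        ll_null = _binomial_loglik(y, np.full(len(y), y.mean()))
        ll_park = models.fit_system_glm(small_system_clims, 1).loglik
        null = self.F(ll_null)
        assert models.mcfadden_r2(self.F(ll_park), null) >= models.mcfadden_r2(
            self.F(ll_nopark), null
        )


class TestParkFits:
    def test_exact_linear_zero_noise(self, linear_park_clim):
        f = models.fit_park_models(linear_park_clim)
        assert f.selected_order == 1
        assert f.adj_r2 == pytest.approx(1.0)
        assert f.temp_sensitive
        assert f.coefficients[1] == pytest.approx(50.0)

    def test_constant_visits_select_null(self):
        t = 10 + 8 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12)
        f = models.fit_park_models(make_clim("C", np.full(12, 500.0), t))
        assert f.selected_order == 0 and not f.temp_sensitive

    def test_constant_temperature_skips_polynomials(self):
        f = models.fit_park_models(make_clim("D", np.arange(1.0, 13.0), np.full(12, 20.0)))
        assert f.selected_order == 0
        assert f.skipped_orders == (1, 2, 3)

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = rng.uniform(-10, 30, 12)
            v = np.abs(rng.normal(1e4, 3e3, 12))
            f = models.fit_park_models(make_clim("N", v, t))
            tc = t - t.mean()
            for k, coefs in f.coefficients_by_order.items():
                X = np.column_stack([tc**j for j in range(k + 1)])
                oracle = np.linalg.solve(X.T @ X, X.T @ v)
                assert np.allclose(coefs, oracle, rtol=1e-8)

    def test_selection_invariant_to_affine_temperature_rescaling(self, default_system):
        for park in sorted(default_system["clims"])[:10]:
            clim = default_system["clims"][park]
            rescaled = dataclasses.replace(clim, mean_temp=1.8 * clim.mean_temp + 32.0)
            assert (
                models.fit_park_models(clim).selected_order
                == models.fit_park_models(rescaled).selected_order
            )

    def test_rss_nonincreasing_in_order(self, default_system):
        for park in sorted(default_system["clims"])[:10]:
            f = models.fit_park_models(default_system["clims"][park])
            rss = [f.rss_by_order[k] for k in sorted(f.rss_by_order)]
            assert np.all(np.diff(rss) <= 1e-6 * max(rss[0], 1.0))

    def test_quadratic_park_parameter_recovery(self):
        # one true order-2 park, repeatedly re-simulated: BIC re-finds the
        # order and the coefficients stay within 2 SE of the pseudo-truth
        order_hits = 0
        cov_hits = cov_tot = 0
        reps = 100
        for rep in range(reps):
            g = synthetic.ParkGenerator(
                park_id="Q", t_mean=12.0, amplitude=9.0, order=2,
                beta=(1.2, 0.3, -0.8), annual_scale=3e5, dispersion=2.0,
                n_years=30, seed=2000 + rep,
            )
            v, t = synthetic.simulate_park(g)
            clim = core_io.build_climatology(v, t, "Q")
            f = models.fit_park_models(clim)
            if f.selected_order != 2:
                continue
            order_hits += 1
            tc = clim.mean_temp - clim.mean_temp.mean()
            X = np.column_stack([tc**j for j in range(3)])
            truth = np.linalg.lstsq(X, g.expected_visits(), rcond=None)[0]
            ok = np.abs(f.coefficients - truth) <= 2 * f._result.bse
            cov_hits += int(ok.sum())
            cov_tot += 3
        assert order_hits >= 0.8 * reps
        assert cov_hits / cov_tot >= 0.9


class TestClassifyParks:
    def test_counting(self):
        t = 10 + 8 * np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12)
        fits = [
            models.fit_park_models(make_clim("A", np.full(12, 500.0), t)),  # order 0
            models.fit_park_models(make_clim("B", 1000 + 50 * t, t)),  # order 1
            models.fit_park_models(make_clim("C", 2000 + 30 * t + 4 * (t - t.mean()) ** 2, t)),
        ]
        s = models.classify_parks(fits)
        assert s["n_parks"] == 3
        assert s["n_temperature_in_best"] == 2
        assert s["counts_by_order"][0] == 1

    def test_all_sensitive_fraction(self, default_park_fits):
        sens = [f for f in default_park_fits.values() if f.temp_sensitive]
        s = models.classify_parks(sens)
        assert s["n_temperature_sensitive"] == s["n_parks"]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            models.classify_parks([])
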