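import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from coralforage.glmm import (
    OibeModelSpec,
    backward_aic_select,
    compare_interaction,
    fit_oibe,
    jackknife_predictions,
    oibe_density,
    oibe_loglik,
    predict,
)
from coralforage.simulate import simulate_preference_pairs


def _row(y, cover=0.3, f1="a", f2="b", sp="sp1"):
    return {
        "coefficient": y, "hard_coral_cover": cover,
        "fish1_id": f1, "fish2_id": f2, "fish_species": sp,
        "site": "s1", "year": 2016,
    }


FIXED_SPEC = OibeModelSpec(mean_terms=("cover",), random_terms=())
PLAIN_SPEC = OibeModelSpec(mean_terms=("cover",), random_terms=(), inflation_terms=None)


class TestDensityAndLoglik:
    def test_single_one_contributes_log_nu(self):
        data = pd.DataFrame([_row(1.0)])
        spec = OibeModelSpec(mean_terms=(), random_terms=())
        ll = oibe_loglik({"beta": [0.0], "phi": 5.0, "nu": 0.3}, data, spec)
        assert ll == pytest.approx(np.log(0.3), abs=1e-12)

    def test_density_matches_scipy_beta_mixture(self):
        mu, phi, nu = 0.62, 9.0, 0.15
        y = np.linspace(0.01, 0.99, 37)
        ours = oibe_density(y, mu, phi, nu)
        ref = (1 - nu) * stats.beta.pdf(y, mu * phi, (1 - mu) * phi)
        assert np.allclose(ours, ref, rtol=1e-10)
        assert oibe_density(1.0, mu, phi, nu)[0] == nu

    def test_density_normalises_to_one(self):
        mu, phi, nu = 0.4, 6.0, 0.2
        cont, _ = integrate.quad(lambda y: oibe_density(y, mu, phi, nu)[0], 0, 1,
                                 limit=200)
        assert cont + nu == pytest.approx(1.0, abs=1e-6)

    def test_loglik_continuous_at_sigma_zero(self):
        df = simulate_preference_pairs(n_groups=4, fish_per_group=6, rng=0)
        spec = OibeModelSpec(mean_terms=("cover",))
        params = {"beta": [0.1, 1.0], "phi": 8.0, "nu": 0.1}
        ll0 = oibe_loglik({**params, "sigma_u": 0.0, "sigma_v": 0.0}, df, spec)
        ll_eps = oibe_loglik({**params, "sigma_u": 1e-4, "sigma_v": 1e-4}, df, spec)
        assert ll_eps == pytest.approx(ll0, abs=1e-3)


class TestFit:
    def test_nu_mle_is_proportion_of_ones(self):
        df = simulate_preference_pairs(n_groups=6, fish_per_group=10, nu=0.15, rng=3)
        fit = fit_oibe(df, OibeModelSpec(mean_terms=("cover",)),
                       compute_se=False, compute_r2=False)
        assert fit.nu == pytest.approx((df["coefficient"] == 1.0).mean())

    def test_duplicating_data_doubles_loglik_keeps_estimates(self):
        # exact likelihood additivity holds on the fixed-effects path; with
        # random effects the Laplace marginal is not additive in general
        df = simulate_preference_pairs(n_groups=5, fish_per_group=7, nu=0.1,
                                       sigma_u=0.0, sigma_v=0.0, rng=4)
        single = fit_oibe(df, FIXED_SPEC, compute_se=False, compute_r2=False)
        double = fit_oibe(pd.concat([df, df], ignore_index=True), FIXED_SPEC,
                          compute_se=False, compute_r2=False)
        assert double.beta["cover"] == pytest.approx(single.beta["cover"], rel=1e-3)
        assert double.loglik == pytest.approx(2 * single.loglik, rel=1e-5)

    def test_matches_independent_beta_regression_oracle(self):
        # sigma = 0, nu fixed 0: the model reduces to plain beta regression
        import statsmodels.api as sm
        from statsmodels.othermod.betareg import BetaModel

        df = simulate_preference_pairs(n_groups=8, fish_per_group=8, beta_cover=1.5,
                                       nu=0.0, sigma_u=0.0, sigma_v=0.0, phi=8.0, rng=7)
        fit = fit_oibe(df, PLAIN_SPEC, compute_se=False, compute_r2=False)
        X = sm.add_constant(df["hard_coral_cover"].to_numpy())
        oracle = BetaModel(df["coefficient"].to_numpy(), X).fit(disp=0)
        ours = np.array([fit.beta["(Intercept)"], fit.beta["cover"], np.log(fit.phi)])
        scale = np.maximum(np.abs(oracle.params), 1.0)
        assert np.all(np.abs(ours - oracle.params) / scale < 1e-4)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_aic_identity(self):
        df = simulate_preference_pairs(n_groups=4, fish_per_group=6, rng=5)
        fit = fit_oibe(df, OibeModelSpec(mean_terms=("cover",)),
                       compute_se=False, compute_r2=False)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)

    def test_rank_deficient_design_rejected(self):
        df = simulate_preference_pairs(n_groups=4, fish_per_group=5, rng=6)
        df["hard_coral_cover"] = 1.0  # collinear with the intercept
        with pytest.raises(ValueError):
            fit_oibe(df, OibeModelSpec(mean_terms=("cover",)))

    def test_monotone_link(self):
        df = simulate_preference_pairs(n_groups=8, fish_per_group=8, beta_cover=2.0, rng=9)
        fit = fit_oibe(df, OibeModelSpec(mean_terms=("cover",)),
                       compute_se=False, compute_r2=False)
        nd = pd.DataFrame({"hard_coral_cover": np.linspace(0, 1, 11),
                           "fish_species": "sp1", "site": "s1", "year": 2016})
        mu = predict(fit, nd)
        assert fit.beta["cover"] > 0
        assert np.all(np.diff(mu) > 0)

    def test_conditional_prediction_shifts_with_pair(self):
        df = simulate_preference_pairs(n_groups=6, fish_per_group=8, sigma_u=0.5,
                                       sigma_v=0.5, rng=11)
        fit = fit_oibe(df, OibeModelSpec(mean_terms=("cover",)),
                       compute_se=False, compute_r2=False)
        nd = pd.DataFrame({"hard_coral_cover": [0.3], "fish_species": "sp1",
                           "site": "s1", "year": 2016})
        pop = predict(fit, nd)
        f1 = max(fit.blup_u, key=lambda k: fit.blup_u[k])
        f2 = max(fit.blup_v, key=lambda k: fit.blup_v[k])
        cond = predict(fit, nd, pair=(f1, f2))
        assert cond[0] > pop[0]


class TestSelection:
    def test_two_point_rule_keeps_simple_model(self, monkeypatch):
        """A complex model short of the 2-AIC margin is not retained."""
        import coralforage.glmm as glmm_mod

        class Stub:
            def __init__(self, terms):
                self.spec = OibeModelSpec(mean_terms=terms)
                # dropping 'cover' worsens AIC by only 1.9 -> drop anyway
                self.aic = {("cover",): 100.0, (): 101.9}[terms]

        monkeypatch.setattr(
            glmm_mod, "fit_oibe",
            lambda data, spec, **kw: Stub(spec.mean_terms),
        )
        final, trace = glmm_mod.backward_aic_select(
            pd.DataFrame([_row(0.5)]), OibeModelSpec(mean_terms=("cover",))
        )
        assert final.spec.mean_terms == ()

    def test_two_point_rule_keeps_complex_model(self, monkeypatch):
        import coralforage.glmm as glmm_mod

        class Stub:
            def __init__(self, terms):
                self.spec = OibeModelSpec(mean_terms=terms)
                self.aic = {("cover",): 100.0, (): 102.1}[terms]

        monkeypatch.setattr(
            glmm_mod, "fit_oibe",
            lambda data, spec, **kw: Stub(spec.mean_terms),
        )
        final, _ = glmm_mod.backward_aic_select(
            pd.DataFrame([_row(0.5)]), OibeModelSpec(mean_terms=("cover",))
        )
        assert final.spec.mean_terms == ("cover",)

    def test_noise_terms_dropped_signal_terms_kept(self):
        kept_site_or_year = 0
        for seed in (2, 3, 4):
            df = simulate_preference_pairs(
                n_groups=18, fish_per_group=10, beta_cover=2.5, phi=10.0, nu=0.08,
                sigma_u=0.15, sigma_v=0.15,
                species_effects={"spA": 0.0, "spB": 0.6}, rng=seed,
            )
            final, trace = backward_aic_select(
                df, OibeModelSpec(mean_terms=("cover", "species", "site", "year"))
            )
            assert "cover" in final.spec.mean_terms
            assert "species" in final.spec.mean_terms
            kept_site_or_year += ("site" in final.spec.mean_terms
                                  or "year" in final.spec.mean_terms)
            assert trace  # every comparison recorded
        assert kept_site_or_year <= 1

    def test_interaction_not_preferred_under_common_slope(self):
        df = simulate_preference_pairs(
            n_groups=12, fish_per_group=9, beta_cover=2.0,
            species_effects={"spA": 0.0, "spB": 0.5}, rng=13,
        )
        preferred, delta = compare_interaction(
            df, OibeModelSpec(mean_terms=("cover", "species"))
        )
        assert "cover:species" not in preferred.mean_terms
        assert delta > -2.0

    def test_interaction_preferred_under_distinct_slopes(self):
        d1 = simulate_preference_pairs(n_groups=8, fish_per_group=9, beta_cover=0.0,
                                       species_effects={"spA": 0.0}, rng=14)
        d2 = simulate_preference_pairs(n_groups=8, fish_per_group=9, beta_cover=4.0,
                                       species_effects={"spB": 0.3}, rng=15)
        for col in ("fish1_id", "fish2_id"):
            d2[col] = "B" + d2[col]
        df = pd.concat([d1, d2], ignore_index=True)
        preferred, delta = compare_interaction(
            df, OibeModelSpec(mean_terms=("cover", "species"))
        )
        assert "cover:species" in preferred.mean_terms
        assert delta <= -2.0


@pytest.fixture(scope="module")
def df():
    return simulate_preference_pairs(n_groups=6, fish_per_group=8, beta_cover=2.0,
                                     nu=0.1, rng=21)


class TestJackknife:
    def test_single_replicate_band_collapses(self, df):
        bands = jackknife_predictions(df, OibeModelSpec(mean_terms=("cover",)),
                                      reps=1, seed=0, grid_size=5)
        for d in bands.values():
            assert np.allclose(d["lo"], d["hi"])

    def test_deterministic_given_seed(self, df):
        spec = OibeModelSpec(mean_terms=("cover",))
        b1 = jackknife_predictions(df, spec, reps=5, seed=7, grid_size=5)
        b2 = jackknife_predictions(df, spec, reps=5, seed=7, grid_size=5)
        for sp in b1:
            assert np.array_equal(b1[sp]["lo"], b2[sp]["lo"])
            assert np.array_equal(b1[sp]["hi"], b2[sp]["hi"])

    def test_band_brackets_full_data_prediction(self, df):
        bands = jackknife_predictions(df, OibeModelSpec(mean_terms=("cover",)),
                                      reps=15, seed=3, grid_size=8)
        for d in bands.values():
            inside = (d["fit"] >= d["lo"]) & (d["fit"] <= d["hi"])
            assert inside.mean() >= 0.9
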