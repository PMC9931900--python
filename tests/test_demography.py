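"""Two-stage vital-rate models: hazard identities, recovery, propagation."""

import numpy as np
import pandas as pd
import pytest

from popimpact import demography as dm
from popimpact.synthetic import SimConfig, simulate_encounter_histories, simulate_reproduction


class TestSurvivalCurve:
    def test_zero_hazard_full_survival(self):
        c = dm.survival_curve(np.zeros(12))
        assert np.allclose(c.s, 1.0)

    def test_constant_hazard_closed_form(self):
        c = dm.survival_curve(np.full(12, 0.1))
        assert c.s[-1] == pytest.approx(np.exp(-1.2))
        assert c.s[-1] == pytest.approx(0.3012, abs=1e-4)
        assert c.ch[-1] == pytest.approx(1.2)

    def test_survival_nonincreasing(self):
        rng = np.random.default_rng(0)
        c = dm.survival_curve(rng.exponential(0.2, size=50))
        assert np.all(np.diff(c.s) <= 0)
        assert np.all(np.diff(c.ch) >= 0)
        assert np.all((c.s > 0) & (c.s <= 1))

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValueError):
            dm.survival_curve(np.array([0.1, -0.2]))


class TestHazardLikelihood:
    def test_all_censored_reduces_to_survival_terms(self):
        """With zero events the likelihood is exactly prod exp(-UH)."""
        lp = np.log(np.array([[0.1, 0.3, 0.05]]))
        rows = dm._hazard_rows_loglik(lp, np.zeros(3))
        np.testing.assert_allclose(rows[0], -np.array([0.1, 0.3, 0.05]))

    def test_event_interval_probability(self):
        lp = np.log(np.array([[0.2]]))
        rows = dm._hazard_rows_loglik(lp, np.ones(1))
        assert rows[0, 0] == pytest.approx(np.log(1 - np.exp(-0.2)))


class TestValidation:
    def test_noncontiguous_intervals_rejected(self):
        df = pd.DataFrame(
            {"individual_id": ["a", "a"], "site_id": ["C0", "C0"], "year": [1, 1],
             "interval": [1, 3], "age_class": ["adult", "adult"],
             "status": ["alive", "dead"], "is_control_site": [True, True]}
        )
        with pytest.raises(ValueError, match="contiguous"):
            dm.validate_histories(df)

    def test_terminal_state_required(self):
        df = pd.DataFrame(
            {"individual_id": ["a", "a"], "site_id": ["C0", "C0"], "year": [1, 1],
             "interval": [1, 2], "age_class": ["adult", "adult"],
             "status": ["alive", "alive"], "is_control_site": [True, True]}
        )
        with pytest.raises(ValueError, match="dead/censored"):
            dm.validate_histories(df)


class TestTwoStageDesign:
    def _design(self):
        h = simulate_encounter_histories(SimConfig(seed=40, n_individuals=120))
        return dm._build_survival_design(h, include_impact=True)

    def test_impact_rows_exclude_control_site_effect(self):
        """Eq-structure check: the predicted log hazard at impact sites is
        built without the control-site varying effect (its mean is zero)."""
        des = self._design()
        g0, g1 = des.col_blocks["gamma"]
        o0, o1 = des.col_blocks["omega"]
        impact_rows = des.X_main[:, o0:o1].sum(axis=1) > 0
        assert impact_rows.any()
        assert np.all(des.X_main[impact_rows, g0:g1] == 0.0)
        assert np.all(des.X_main[~impact_rows, o0:o1] == 0.0)

    def test_impact_rows_share_calendar_year_effects(self):
        des = self._design()
        l0, l1 = des.col_blocks["lam"]
        assert np.all(des.X_main[:, l0:l1].sum(axis=1) == 1.0)

    def test_delta_columns_zero_on_control_rows(self):
        des = self._design()
        o0, o1 = des.col_blocks["omega"]
        control_rows = des.X_main[:, o0:o1].sum(axis=1) == 0
        assert np.all(des.X_delta[control_rows] == 0.0)


class TestControlSurvivalRecovery:
    def test_constant_hazard_baseline_recovered(self):
        cfg = SimConfig(seed=41, n_individuals=600, baseline_hazards=(0.1,) * 12,
                        true_beta_C=(), true_delta_G=(), true_psi_age=(0.0, 0.0),
                        sigma_site=0.0, sigma_year=0.0, censor_rate=0.0,
                        n_impact_sites=0, n_control_sites=4)
        h = simulate_encounter_histories(cfg)
        draws = dm.fit_control_survival(h, iters=6000, burn_in=3000, seed=1,
                                        baseline="constant")
        z = draws.flat("z")
        assert np.median(z) == pytest.approx(np.log(0.1), abs=0.12)

    def test_confounder_coefficients_recovered(self):
        cfg = SimConfig(seed=42, n_individuals=600, true_beta_C=(0.5, -0.5),
                        true_delta_G=(), n_impact_sites=0, n_control_sites=4)
        h = simulate_encounter_histories(cfg)
        draws = dm.fit_control_survival(h, iters=6000, burn_in=3000, seed=2,
                                        baseline="constant")
        bc = draws.flat("beta_c")
        for k, truth in enumerate((0.5, -0.5)):
            lo, hi = np.percentile(bc[:, k], [2.5, 97.5])
            assert lo <= truth <= hi

    def test_too_few_sites_rejected(self):
        h = simulate_encounter_histories(SimConfig(seed=43, n_individuals=30,
                                                   n_control_sites=1, n_impact_sites=1))
        with pytest.raises(ValueError, match="2 sites"):
            dm.fit_control_survival(h)


class TestTwoStagePropagation:
    def test_joint_delta_sd_exceeds_plugin_sd(self):
        """Freezing the control parameters at posterior medians removes the
        confounder uncertainty that the concurrent two-stage sampler
        propagates into delta.  The impact-site confounder is made
        collinear with the impact covariate — the regime the two-stage
        design exists for — so that confounder uncertainty actually loads
        onto delta rather than being absorbed by the site constant."""
        cfg = SimConfig(seed=44, n_individuals=500, n_impact_sites=4,
                        n_control_sites=6, true_delta_G=(-0.6,))
        h = simulate_encounter_histories(cfg)
        imp = ~h["is_control_site"]
        rng = np.random.default_rng(99)
        h.loc[imp, "x_c0"] = (2.0 * (h.loc[imp, "x_g0"] - 0.5)
                              + 0.3 * rng.standard_normal(imp.sum()))
        kw = dict(iters=10_000, burn_in=5000)
        joint = dm.fit_impact_survival(h, seed=3, **kw)
        fixed = {
            name: np.median(joint.flat(name).reshape(joint.n_retained(), -1), axis=0)
            for name in ("beta_c", "psi", "z", "gamma", "lam",
                         "log_sigma_gamma", "log_sigma_lambda")
        }
        plug = dm.fit_impact_survival(h, seed=4, fixed_control=fixed, **kw)
        assert joint.flat("delta").std() >= plug.flat("delta").std()

    def test_fixed_control_only_samples_impact_params(self):
        cfg = SimConfig(seed=45, n_individuals=120)
        h = simulate_encounter_histories(cfg)
        joint = dm.fit_impact_survival(h, seed=5, iters=800, burn_in=400)
        fixed = {
            name: np.median(joint.flat(name).reshape(joint.n_retained(), -1), axis=0)
            for name in ("beta_c", "psi", "z", "gamma", "lam",
                         "log_sigma_gamma", "log_sigma_lambda")
        }
        plug = dm.fit_impact_survival(h, seed=6, fixed_control=fixed,
                                      iters=800, burn_in=400)
        assert set(plug.params) == {"delta", "omega"}


class TestBinaryVitals:
    def test_hatchability_recovery(self):
        rng = np.random.default_rng(46)
        n = rng.integers(6, 11, size=400)
        y = rng.binomial(n, 0.9)
        rec = pd.DataFrame({"y": y, "n": n, "site_id": "C0", "is_control_site": True})
        draws = dm.fit_binary_vital(rec, family="binomial", iters=4000,
                                    burn_in=2000, seed=7)
        p = dm.predicted_probability(draws)
        assert np.median(p) == pytest.approx(0.9, abs=0.02)

    def test_all_failures_probability_near_zero(self):
        rec = pd.DataFrame({"y": np.zeros(60), "n": np.full(60, 5),
                            "site_id": "C0", "is_control_site": True})
        draws = dm.fit_binary_vital(rec, family="binomial", iters=4000,
                                    burn_in=2000, seed=8)
        assert np.median(dm.predicted_probability(draws)) < 0.02

    def test_y_exceeding_n_rejected(self):
        rec = pd.DataFrame({"y": [6], "n": [5], "site_id": "C0",
                            "is_control_site": True})
        with pytest.raises(ValueError, match="y <= n"):
            dm.fit_binary_vital(rec, family="binomial")

    def test_bernoulli_requires_binary(self):
        rec = pd.DataFrame({"y": [2.0], "site_id": "C0", "is_control_site": True})
        with pytest.raises(ValueError, match="0/1"):
            dm.fit_binary_vital(rec, family="bernoulli")

    def test_impact_terms_shift_logit_scale(self):
        """With delta and omega at zero the impact-site probability equals
        the baseline prediction logit^-1(P) (identity of the two-stage
        construction)."""
        draws_params = {
            "intercept": np.full((2, 5), 0.4),
            "beta_c": np.full((2, 5, 1), 1.0),
            "delta": np.zeros((2, 5, 1)),
            "omega": np.zeros((2, 5, 1)),
        }
        from popimpact.mcmc import PosteriorDraws

        d = PosteriorDraws(draws_params)
        p = dm.predicted_probability(d, x_c=[0.5], x_g=[1.0], site=0)
        assert np.allclose(p, 1 / (1 + np.exp(-0.9)))


class TestClutchSize:
    def test_poisson_means_recovered(self):
        rng = np.random.default_rng(47)
        rec = pd.DataFrame({
            "clutch_size": np.r_[rng.poisson(8.0, 500), rng.poisson(6.0, 300)],
            "age_class": "adult",
            "attempt": np.r_[np.ones(500, int), np.full(300, 2)],
        })
        draws = dm.fit_clutch_size(rec, iters=4000, burn_in=2000, seed=9)
        first = dm.expected_clutch(draws, "adult", 1)
        second = dm.expected_clutch(draws, "adult", 2)
        assert np.median(first) == pytest.approx(8.0, abs=0.4)
        assert np.median(second) == pytest.approx(6.0, abs=0.4)

    def test_identity_exp_psi(self):
        from popimpact.mcmc import PosteriorDraws

        d = PosteriorDraws({"clutch_psi": np.full((1, 4, 2), np.log(8.0)),
                            "clutch_t2": np.zeros((1, 4))})
        assert np.allclose(dm.expected_clutch(d, "adult", 1), 8.0)
        assert np.allclose(dm.expected_clutch(d, "yearling", 2), 8.0)

    def test_all_zero_counts_flagged(self):
        import warnings

        rec = pd.DataFrame({"clutch_size": np.zeros(30, int),
                            "age_class": "adult", "attempt": 1})
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            draws = dm.fit_clutch_size(rec, iters=2000, burn_in=1000, seed=10)
        assert any("zero" in str(x.message) for x in w)
        assert np.median(dm.expected_clutch(draws, "adult", 1)) < 0.2


class TestNestSurvival:
    def test_fit_and_survival_range(self):
        cfg = SimConfig(seed=48, n_hens=200)
        nests, _, _ = simulate_reproduction(cfg)
        draws = dm.fit_nest_survival(nests, nest_days=cfg.nest_days,
                                     iters=3000, burn_in=1500, seed=11)
        s1 = dm.nest_survival_draws(draws, attempt=1)
        truth = np.exp(-cfg.nest_days * cfg.nest_daily_hazard)
        assert np.all((s1 >= 0) & (s1 <= 1))
        assert np.median(s1) == pytest.approx(truth, abs=0.1)

    def test_exposure_bounds_checked(self):
        nests = pd.DataFrame({"nest_id": ["n1"], "hen_id": ["h1"], "attempt": [1],
                              "exposure_days": [50], "fate": ["failed"]})
        with pytest.raises(ValueError, match="exposure_days"):
            dm.fit_nest_survival(nests, nest_days=38)


class TestInformativePriorStage:
    def test_beta_prior_mean(self):
        d = dm.informative_prior_stage("np1", {"family": "beta", "a": 27, "b": 3},
                                       n_draws=40_000, seed=1)
        assert d.mean() == pytest.approx(0.9, abs=0.01)
        assert np.all((d >= 0) & (d <= 1))

    def test_point_mass(self):
        d = dm.informative_prior_stage("js", {"family": "point", "value": 0.5}, 100)
        assert np.all(d == 0.5)

    def test_probability_support_enforced(self):
        with pytest.raises(ValueError):
            dm.informative_prior_stage("js", {"family": "point", "value": 1.5}, 10)
        with pytest.raises(ValueError, match="normal"):
            dm.informative_prior_stage("js", {"family": "normal", "mu": 0.5, "sd": 1}, 10)

    def test_reproducible(self):
        a = dm.informative_prior_stage("x", {"family": "beta", "a": 2, "b": 2}, 50, seed=3)
        b = dm.informative_prior_stage("x", {"family": "beta", "a": 2, "b": 2}, 50, seed=3)
        np.testing.assert_array_equal(a, b)


class TestAnnualSurvivalDraws:
    def test_matches_survival_curve_composition(self):
        from popimpact.mcmc import PosteriorDraws

        z = np.full((1, 3, 12), np.log(0.1))
        d = PosteriorDraws({"z": z, "psi": np.full((1, 3), 0.5)})
        s_adult = dm.annual_survival_draws(d, age="adult")
        assert np.allclose(s_adult, np.exp(-1.2))
        s_yr = dm.annual_survival_draws(d, age="yearling")
        assert np.allclose(s_yr, np.exp(-1.2 * np.exp(0.5)))

    def test_extra_lp_identity(self):
        """Impact terms at zero leave the hazard prediction unchanged."""
        from popimpact.mcmc import PosteriorDraws

        z = np.full((1, 5, 12), np.log(0.05))
        d = PosteriorDraws({"z": z, "psi": np.zeros((1, 5))})
        np.testing.assert_allclose(
            dm.annual_survival_draws(d, extra_lp=0.0),
            dm.annual_survival_draws(d, extra_lp=np.zeros(5)),
        )
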