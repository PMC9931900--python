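"""BACI growth analysis: zones, state-space likelihood, ratios, selection."""

import numpy as np
import pytest

from conftest import make_lek_table
from popimpact import growth, mcmc
from popimpact.growth import CELLS, DEFAULT_THRESHOLDS_KM, ZoneAssignment
from popimpact.mcmc import LooResult, PosteriorDraws
from popimpact.synthetic import SimConfig, simulate_lek_counts


def _const_table(n_before=3, n_after=3):
    series = {"A": [20] * (n_before + n_after), "B": [40] * (n_before + n_after)}
    return make_lek_table(series, {"A": 2.0, "B": 30.0}, n_before)


class TestAssignZones:
    def test_threshold_splits_at_boundary(self):
        tab = make_lek_table(
            {"a": [5, 5, 5, 5], "b": [5, 5, 5, 5], "c": [5, 5, 5, 5]},
            {"a": 1.5, "b": 6.0, "c": 40.0}, 2,
        )
        (z,) = growth.assign_zones(tab, [5.0])
        assert [z.groups[k] for k in ("a", "b", "c")] == ["impact", "control", "control"]

    def test_default_threshold_list(self):
        assert DEFAULT_THRESHOLDS_KM == (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
        zones = growth.assign_zones(_const_table())
        assert [z.threshold_km for z in zones] == list(DEFAULT_THRESHOLDS_KM)

    def test_threshold_above_all_distances_all_impact(self):
        (z,) = growth.assign_zones(_const_table(), [100.0])
        assert z.n_impact == 2 and z.n_control == 0

    def test_invalid_tables_rejected(self):
        tab = _const_table()
        with pytest.raises(ValueError, match="positive"):
            growth.assign_zones(tab, [-1.0])
        bad = tab.copy()
        bad.loc[0, "distance_km"] = np.nan
        with pytest.raises(ValueError, match="distance"):
            growth.assign_zones(bad, [5.0])


class TestSSMLikelihood:
    def test_two_year_doubling_identity(self):
        """Counts 10 -> 20 with tiny variances: the marginal likelihood is
        maximised when the cell growth effect equals log 2 (state equation
        identity), probed on a grid."""
        tab = make_lek_table({"A": [10, 20, 40, 80]}, {"A": 1.0}, 4)
        zone = ZoneAssignment(5.0, {"A": "impact"})
        _, _, logy, obs, cell, after_tr = growth._prepare_arrays(tab, zone, "missing")
        n_eta = logy.shape[1] - 1

        def ll(beta_bi):
            theta = np.zeros((1, 4 + n_eta + 4))
            theta[0, 1] = beta_bi
            theta[0, -4:] = np.log([1e-3, 1e-3, 1e-3, 1e-3])
            return growth._ssm_loglik(theta, logy, obs, cell, after_tr)[0]

        grid = np.linspace(0.3, 1.1, 81)
        best = grid[np.argmax([ll(b) for b in grid])]
        assert best == pytest.approx(np.log(2.0), abs=0.02)

    def test_pointwise_sums_to_total(self):
        tab = simulate_lek_counts(SimConfig(seed=20, n_leks=15))
        (zone,) = growth.assign_zones(tab, [10.0])
        _, _, logy, obs, cell, after_tr = growth._prepare_arrays(tab, zone, "log1p")
        rng = np.random.default_rng(0)
        theta = np.r_[rng.normal(0, 0.1, 4 + logy.shape[1] - 1),
                      np.log([0.3, 0.1, 0.1, 0.1])][None]
        total = growth._ssm_loglik(theta, logy, obs, cell, after_tr)
        pw = growth._ssm_loglik(theta, logy, obs, cell, after_tr, pointwise=True)
        assert pw.shape == (1, logy.size)
        assert pw.sum() == pytest.approx(total[0], rel=1e-10)


class TestFitSSM:
    def test_noise_free_growth_concentrates_at_zero(self):
        """Constant counts: the identified cell-level growth rates (and
        hence lambda) concentrate at 0 (lambda = 1); the raw cell effect
        alone is confounded with a common year-effect shift, so the check
        is on the cell mean growth."""
        series = {f"L{i}": [10 * (i + 1)] * 8 for i in range(6)}
        dists = {f"L{i}": (3.0 if i < 3 else 30.0) for i in range(6)}
        tab = make_lek_table(series, dists, 4)
        (zone,) = growth.assign_zones(tab, [5.0])
        draws = growth.fit_ssm(tab, zone, iters=5000, burn_in=2500, seed=1,
                               pointwise=False, check_convergence=False)
        lam = growth.derive_lambda(draws)
        for cell in CELLS:
            assert np.median(lam[cell]) == pytest.approx(1.0, abs=0.05)

    def test_translation_invariance_of_growth(self):
        """Scaling all counts by a constant shifts levels (absorbed by the
        initial-state prior), leaving growth-rate posteriors unchanged up
        to Monte-Carlo error."""
        base = {"A": [10, 12, 15, 18], "B": [30, 31, 33, 36]}
        tab1 = make_lek_table(base, {"A": 2.0, "B": 30.0}, 2)
        tab2 = make_lek_table({k: [4 * c for c in v] for k, v in base.items()},
                              {"A": 2.0, "B": 30.0}, 2)
        (z1,) = growth.assign_zones(tab1, [5.0])
        (z2,) = growth.assign_zones(tab2, [5.0])
        kw = dict(iters=4000, burn_in=2000, seed=3, pointwise=False,
                  check_convergence=False)
        b1 = np.median(growth.fit_ssm(tab1, z1, **kw).flat("beta_tp"), axis=0)
        b2 = np.median(growth.fit_ssm(tab2, z2, **kw).flat("beta_tp"), axis=0)
        assert np.allclose(b1, b2, atol=0.06)


class TestDeriveLambda:
    def test_exp_identity(self):
        beta = np.zeros((1, 6, 4))
        beta[..., 1] = -0.2
        beta[..., 2] = 0.1
        lam = growth.derive_lambda(PosteriorDraws({"beta_tp": beta}))
        assert np.allclose(lam["before_control"], 1.0)
        assert np.allclose(lam["before_impact"], np.exp(-0.2))
        assert np.allclose(lam["after_control"], np.exp(0.1))

    def test_missing_beta_errors(self):
        with pytest.raises(ValueError):
            growth.derive_lambda(PosteriorDraws({"x": np.zeros((2, 3))}))


class TestBaciRatio:
    def _points(self, bc, bi, ac, ai, n=100):
        return {c: np.full(n, v) for c, v in zip(CELLS, (bc, bi, ac, ai))}

    def test_identical_cells_null(self):
        st = growth.baci_ratio(self._points(1.0, 1.0, 1.0, 1.0))
        assert np.allclose(st.r_baci, 1.0)
        assert np.allclose(st.ci_contribution, 0.0)
        assert np.allclose(st.ci_divergence, 0.0)
        assert st.evidence == "none"

    def test_worked_example(self):
        st = growth.baci_ratio(self._points(1.0, 1.1, 1.0, 0.9))
        assert st.r_baci[0] == pytest.approx(1.1 / 0.9)
        assert st.r_baci[0] == pytest.approx(1.2222, abs=1e-4)
        assert st.ci_contribution[0] == pytest.approx(0.2)
        assert st.ci_divergence[0] == pytest.approx(0.0, abs=1e-12)

    def test_evidence_grading_moderate(self):
        """92% of draws above 1.0 grades as moderate (between the 0.90 and
        0.95 thresholds)."""
        r = np.r_[np.full(92, 1.5), np.full(8, 0.5)]
        lam = {"before_control": np.ones(100), "before_impact": r,
               "after_control": np.ones(100), "after_impact": np.ones(100)}
        st = growth.baci_ratio(lam)
        assert st.mass_above_1 == pytest.approx(0.92)
        assert st.evidence == "moderate"

    @pytest.mark.parametrize("mass,grade", [(0.80, "none"), (0.86, "weak"),
                                            (0.91, "moderate"), (0.97, "substantial")])
    def test_evidence_thresholds(self, mass, grade):
        n = 1000
        k = int(round(mass * n))
        lam = {"before_control": np.ones(n),
               "before_impact": np.r_[np.full(k, 2.0), np.full(n - k, 0.5)],
               "after_control": np.ones(n), "after_impact": np.ones(n)}
        assert growth.baci_ratio(lam).evidence == grade

    def test_per_draw_ratio_identity(self):
        rng = np.random.default_rng(4)
        lam = {c: np.exp(rng.normal(0, 0.1, 500)) for c in CELLS}
        st = growth.baci_ratio(lam)
        np.testing.assert_allclose(st.r_baci * st.r_after, st.r_before, rtol=1e-12)

    def test_zero_denominator_errors(self):
        lam = self._points(1.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="zero lambda"):
            growth.baci_ratio(lam)

    def test_unpaired_lengths_error(self):
        lam = self._points(1.0, 1.0, 1.0, 1.0)
        lam["after_impact"] = np.ones(7)
        with pytest.raises(ValueError, match="paired"):
            growth.baci_ratio(lam)


class TestSelectZone:
    def _loo(self, looic):
        return LooResult(looic=looic, elpd=-looic / 2, se=1.0,
                         pointwise_elpd=np.zeros(2), pareto_k=np.zeros(2))

    def test_argmin_with_table(self):
        best, tab = growth.select_zone({2.0: self._loo(105.0), 10.0: self._loo(100.0)})
        assert best == 10.0
        assert list(tab["threshold_km"]) == [10.0, 2.0]

    def test_tie_goes_to_smallest_threshold(self):
        best, _ = growth.select_zone({10.0: self._loo(100.0), 2.0: self._loo(100.0)})
        assert best == 2.0

    def test_single_zone_trivially_selected(self):
        best, tab = growth.select_zone({5.0: self._loo(50.0)})
        assert best == 5.0 and len(tab) == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            growth.select_zone({})

    def test_fit_without_pointwise_cannot_enter_comparison(self):
        tab = _const_table()
        (zone,) = growth.assign_zones(tab, [5.0])
        draws = growth.fit_ssm(tab, zone, iters=600, burn_in=300, seed=0,
                               pointwise=False, check_convergence=False)
        with pytest.raises(ValueError, match="pointwise"):
            mcmc.psis_loo(draws)
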