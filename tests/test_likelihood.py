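import numpy as np
import pytest

import mdstiming as m
from mdstiming.cohort_data import Observation, ObsKind, SubjectRecord
from mdstiming.likelihood import _CompiledData
from mdstiming.model_core import TransplantEffects, apply_transplant_effects

from _oracles import discretized_cohort_loglik


def _obs(t, state, kind, post=False):
    return Observation(t, state, ObsKind(kind), post)


class TestIntervalLogLikelihood:
    def test_panel_self_transition_two_state(self, two_state):
        space, _, q = two_state
        eff = TransplantEffects.null(space)
        ll = m.interval_log_likelihood(0, _obs(1.0, 0, "panel"), 1.0, q, False, eff, space)
        assert ll == pytest.approx(-0.5, abs=1e-10)

    def test_exact_death_two_state(self, two_state):
        space, _, q = two_state
        eff = TransplantEffects.null(space)
        ll = m.interval_log_likelihood(0, _obs(1.0, 1, "death"), 1.0, q, False, eff, space)
        assert ll == pytest.approx(np.log(np.exp(-0.5) * 0.5), abs=1e-10)

    def test_panel_progression_chain(self):
        # A -> B at 1.0, B -> Death at 2.0: P[A,B](1) = e^-1 - e^-2
        from mdstiming.model_core import Scheme, StateSpace

        space = StateSpace(Scheme.IPSS, ("A", "B", "Death"), 1, 2, frozenset({0, 1}))
        q = np.array([[-1.0, 1.0, 0.0], [0.0, -2.0, 2.0], [0.0, 0.0, 0.0]])
        eff = TransplantEffects.null(space)
        ll = m.interval_log_likelihood(0, _obs(1.0, 1, "panel"), 1.0, q, False, eff, space)
        assert ll == pytest.approx(np.log(np.exp(-1) - np.exp(-2)), abs=1e-9)

    def test_transplant_covariate_switches_generator(self, two_state):
        space, _, q = two_state
        eff = TransplantEffects({0: np.log(2.0)})
        ll = m.interval_log_likelihood(0, _obs(1.0, 0, "panel"), 1.0, q, True, eff, space)
        assert ll == pytest.approx(-1.0, abs=1e-10)

    def test_nonpositive_dt_rejected(self, two_state):
        space, _, q = two_state
        with pytest.raises(ValueError):
            m.interval_log_likelihood(
                0, _obs(0.0, 0, "panel"), 0.0, q, False, TransplantEffects.null(space), space
            )


class TestCohortLogLikelihood:
    def test_empty_cohort_list_is_zero(self, three_state_chain):
        space, _, q = three_state_chain
        assert m.cohort_log_likelihood([], q, TransplantEffects.null(space), space) == 0.0

    def test_single_interval_matches_interval_ll(self, three_state_chain):
        space, _, q = three_state_chain
        eff = TransplantEffects.null(space)
        obs = [_obs(0.0, 0, "panel"), _obs(1.5, 1, "panel")]
        c = m.Cohort(space.scheme, [SubjectRecord("s1", 50, obs)])
        direct = m.interval_log_likelihood(0, obs[1], 1.5, q, False, eff, space)
        assert m.cohort_log_likelihood([c], q, eff, space) == pytest.approx(direct)

    def test_against_discretized_chain_oracle(self, three_state_chain):
        """Five panel subjects on the 3-state chain vs brute-force path sum."""
        space, _, q = three_state_chain
        eff = TransplantEffects.null(space)
        subjects = [
            SubjectRecord("s1", 50, [_obs(0.0, 0, "panel"), _obs(1.0, 1, "panel"),
                                     _obs(1.8, 2, "death")]),
            SubjectRecord("s2", 61, [_obs(0.0, 0, "panel"), _obs(0.5, 0, "panel"),
                                     _obs(1.5, 1, "panel"), _obs(2.5, 1, "censor")]),
            SubjectRecord("s3", 45, [_obs(0.0, 0, "panel"), _obs(0.7, 2, "death")]),
            SubjectRecord("s4", 58, [_obs(0.0, 1, "panel"), _obs(0.4, 1, "panel"),
                                     _obs(0.9, 2, "death")]),
            SubjectRecord("s5", 70, [_obs(0.0, 0, "panel"), _obs(2.0, 0, "censor")]),
        ]
        c = m.Cohort(space.scheme, subjects)
        got = m.cohort_log_likelihood([c], q, eff, space)
        want = discretized_cohort_loglik([c], q, eff, space, h=1e-3)
        assert got == pytest.approx(want, abs=1e-3)

    def test_invariance_under_reordering_and_splitting(self, three_state_chain):
        space, _, q = three_state_chain
        eff = TransplantEffects.null(space)
        s1 = SubjectRecord("a", 50, [_obs(0.0, 0, "panel"), _obs(2.0, 1, "panel"),
                                     _obs(3.0, 2, "death")])
        s2 = SubjectRecord("b", 55, [_obs(0.0, 0, "panel"), _obs(1.0, 0, "censor")])
        c12 = m.Cohort(space.scheme, [s1, s2])
        c21 = m.Cohort(space.scheme, [s2, s1])
        assert m.cohort_log_likelihood([c12], q, eff, space) == pytest.approx(
            m.cohort_log_likelihood([c21], q, eff, space)
        )
        # splitting an interval, marginalized over the interior state, is neutral
        base = SubjectRecord("c", 60, [_obs(0.0, 0, "panel"), _obs(2.0, 1, "panel")])
        unsplit = m.cohort_log_likelihood(
            [m.Cohort(space.scheme, [base])], q, eff, space
        )
        total = 0.0
        for mid in (0, 1):  # transient states observable at the interior time
            s_mid = SubjectRecord(
                "c", 60, [_obs(0.0, 0, "panel"), _obs(0.8, mid, "panel"),
                          _obs(2.0, 1, "panel")],
            )
            total += np.exp(
                m.cohort_log_likelihood([m.Cohort(space.scheme, [s_mid])], q, eff, space)
            )
        assert np.log(total) == pytest.approx(unsplit, abs=1e-9)

    def test_hsct_switch_interval_split(self, two_state):
        """An interval straddling hsct_time composes pre and post generators."""
        space, _, q = two_state
        eff = TransplantEffects({0: np.log(2.0)})
        obs = [_obs(0.0, 0, "panel", False), _obs(1.0, 0, "panel", True)]
        s = SubjectRecord("s1", 50, obs, hsct_time=0.25)
        c = m.Cohort(space.scheme, [s])
        got = m.cohort_log_likelihood([c], q, eff, space)
        # survive 0.25y at rate 0.5, then 0.75y at rate 1.0
        assert got == pytest.approx(-0.5 * 0.25 - 1.0 * 0.75, abs=1e-9)

    def test_compiled_likelihood_matches_reference(self, ipss_params, small_cohorts):
        space = ipss_params.space
        data = _CompiledData(small_cohorts, space)
        q1 = apply_transplant_effects(ipss_params.q, ipss_params.effects, space)
        fast = data.log_likelihood(ipss_params.q, q1)
        slow = m.cohort_log_likelihood(
            small_cohorts, ipss_params.q, ipss_params.effects, space
        )
        assert fast == pytest.approx(slow, rel=1e-9)


class TestFitModel:
    def test_exponential_mle_closed_form(self, two_state):
        """Exact-death data: q_hat = deaths / person-years."""
        space, structure, _ = two_state
        subjects = []
        # 10 deaths over 50 person-years total
        death_times = [2.0, 3.0, 7.0, 4.0, 6.0, 5.0, 8.0, 5.5, 4.5, 5.0]
        for i, t in enumerate(death_times):
            subjects.append(
                SubjectRecord(f"s{i}", 50, [_obs(0.0, 0, "panel"), _obs(t, 1, "death")])
            )
        c = m.Cohort(space.scheme, subjects)
        fit = m.fit_model(
            [c], space, structure,
            options={"ftol": 1e-15, "gtol": 1e-10, "fd": "3-point", "covariance": False},
        )
        assert fit.q_hat[0, 1] == pytest.approx(10.0 / sum(death_times), abs=1e-8)
        assert fit.converged

    def test_boundary_warning_for_unobserved_transition(self, three_state_chain):
        space, structure, q = three_state_chain
        # all subjects censored in A: no information on B at all
        subjects = [
            SubjectRecord(f"s{i}", 50, [_obs(0.0, 0, "panel"), _obs(0.5, 0, "panel"),
                                        _obs(1.0, 0, "censor")])
            for i in range(30)
        ]
        c = m.Cohort(space.scheme, subjects)
        fit = m.fit_model([c], space, structure, options={"covariance": False})
        assert any("boundary" in w for w in fit.warnings)

    def test_mle_beats_truth_on_same_data(self, ipss_params, small_cohorts, small_fit):
        truth_ll = m.cohort_log_likelihood(
            small_cohorts, ipss_params.q, ipss_params.effects, ipss_params.space
        )
        assert small_fit.log_likelihood >= truth_ll - 1e-4

    def test_fit_is_deterministic(self, ipss_params, small_cohorts, small_fit):
        refit = m.fit_model(
            small_cohorts, ipss_params.space, ipss_params.structure,
            options={"covariance": False},
        )
        np.testing.assert_array_equal(refit.theta_hat, small_fit.theta_hat)

    def test_save_load_roundtrip(self, tmp_path, small_fit):
        path = tmp_path / "fit.yaml"
        small_fit.save(path)
        back = m.FittedModel.load(path)
        np.testing.assert_allclose(back.q_hat, small_fit.q_hat, rtol=1e-12)
        assert back.effects_hat.log_hr == pytest.approx(small_fit.effects_hat.log_hr)
        assert back.log_likelihood == pytest.approx(small_fit.log_likelihood)


class TestHazardRatios:
    def test_wald_interval_shape(self, ipss_params):
        fit = m.FittedModel.from_parameters(
            ipss_params.space, ipss_params.structure, ipss_params.q, ipss_params.effects
        )
        n_rates = len(sorted(ipss_params.structure.allowed))
        k = len(fit.effects_hat.log_hr)
        fit.covariance = np.zeros((n_rates + k, n_rates + k))
        fit.covariance[n_rates, n_rates] = 0.1**2  # SE 0.1 on the first log-HR
        tbl = m.hazard_ratios(fit)
        first = tbl.iloc[0]
        assert first.hr == pytest.approx(3.0)  # fixture HR in the Low state
        assert first.ci_low == pytest.approx(3.0 * np.exp(-1.96 * 0.1), rel=1e-9)
        assert first.ci_high == pytest.approx(3.0 * np.exp(1.96 * 0.1), rel=1e-9)
        # zero-variance entries give degenerate CIs equal to the HR
        assert tbl.iloc[1].ci_low == pytest.approx(tbl.iloc[1].hr)

    def test_missing_covariance_gives_nan_ci(self, ipss_params):
        fit = m.FittedModel.from_parameters(
            ipss_params.space, ipss_params.structure, ipss_params.q, ipss_params.effects
        )
        tbl = m.hazard_ratios(fit)
        assert tbl.ci_low.isna().all()
        assert tbl.hr.iloc[0] == pytest.approx(3.0)


class TestSurvivalCurves:
    def test_two_state_exponential_survival(self, two_state):
        space, structure, q = two_state
        fit = m.FittedModel.from_parameters(space, structure, q, TransplantEffects.null(space))
        grid = np.array([0.0, 1.0, 2.0])
        s = m.model_survival_curve(fit, 0, grid)
        np.testing.assert_allclose(s, np.exp(-0.5 * grid), atol=1e-10)

    def test_starts_at_one_and_nonincreasing(self, truth_fitted):
        grid = np.linspace(0, 30, 200)
        s = m.model_survival_curve(truth_fitted, 0, grid)
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()

    def test_matches_km_of_simulated_deaths(self, ipss_params, truth_fitted):
        """Survival curve vs Kaplan-Meier of 50k exact simulated death times."""
        from mdstiming.synthetic import _sample_jump_path

        rng = np.random.default_rng(42)
        space = ipss_params.space
        deaths = np.array([
            _sample_jump_path(ipss_params.q, 0, space.death_index, rng)[0][-1]
            for _ in range(50_000)
        ])
        tl, km = m.km_estimator(deaths, np.ones_like(deaths, dtype=bool))
        model = m.model_survival_curve(truth_fitted, 0, tl)
        assert np.max(np.abs(km - model)) < 0.01


class TestKmEstimator:
    def test_hand_computed_example(self):
        tl, s = m.km_estimator([1.0, 2.0, 3.0], [True, False, True])
        surv = dict(zip(tl, s))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[3.0] == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        _, s = m.km_estimator([1.0, 2.0, 3.0], [False, False, False])
        np.testing.assert_allclose(s, 1.0)

    def test_exponential_sample_monte_carlo(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(2.0, size=20_000)  # rate 0.5
        tl, s = m.km_estimator(t, np.ones_like(t, dtype=bool))
        s_at_1 = s[np.searchsorted(tl, 1.0)]
        assert s_at_1 == pytest.approx(np.exp(-0.5), abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.km_estimator([], [])
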