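"""Decay-model evaluation, weighted-likelihood fitting and model comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clemq import (
    DecayParams,
    GranuleAgeObservation,
    compare_models,
    eval_decay_model,
    fit_decay_model,
    half_life,
    log_likelihood,
)
from clemq.decay_models import DecayModelFit, _laplace_log_evidence
from clemq.synthetic_data import generate_observations


def _obs(t, y, sem):
    return [
        GranuleAgeObservation(t=ti, y=yi, sem=si, n_replicates=3)
        for ti, yi, si in zip(t, y, sem)
    ]


class TestEvalDecayModel:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            (DecayParams(1, a=0.031, tau=6.0), 0.0, 0.031),
            (DecayParams(2, a=0.027, delta=2.72, tau=2.85), 2.0, 0.027),
            (DecayParams(2, a=0.027, delta=2.72, tau=2.85), 5.0, 0.027 * math.exp(-2.28 / 2.85)),
        ],
    )
    def test_known_values(self, params, t, expected):
        assert eval_decay_model(params, t) == pytest.approx(expected, rel=1e-12)

    def test_y_at_zero_is_plateau(self):
        for p in (
            DecayParams(1, a=0.03, tau=4.0),
            DecayParams(2, a=0.03, delta=1.0, tau=4.0),
            DecayParams(3, a=0.03, delta=1.0, tau=4.0, tau1=20.0),
        ):
            assert eval_decay_model(p, 0.0) == pytest.approx(p.a)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            eval_decay_model(DecayParams(1, a=0.03, tau=4.0), -1.0)

    def test_invalid_model_id_rejected(self):
        with pytest.raises(ValueError, match="model_id"):
            DecayParams(4, a=0.03, tau=4.0)

    def test_model2_with_zero_lag_equals_model1(self):
        t = np.linspace(0, 8, 100)
        y1 = eval_decay_model(DecayParams(1, a=0.03, tau=3.1), t)
        y2 = eval_decay_model(DecayParams(2, a=0.03, delta=0.0, tau=3.1), t)
        np.testing.assert_allclose(y1, y2, rtol=1e-12)

    def test_model3_slow_limit_equals_model2(self):
        t = np.linspace(0, 8, 100)
        y2 = eval_decay_model(DecayParams(2, a=0.03, delta=2.5, tau=3.1), t)
        y3 = eval_decay_model(DecayParams(3, a=0.03, delta=2.5, tau=3.1, tau1=1e9), t)
        np.testing.assert_allclose(y3, y2, rtol=1e-6)

    @given(
        a=st.floats(0.001, 0.2),
        delta=st.floats(0.0, 8.0),
        tau=st.floats(0.1, 40.0),
        tau1=st.floats(0.1, 40.0),
        model_id=st.sampled_from([1, 2, 3]),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nonincreasing_and_continuous(self, a, delta, tau, tau1, model_id):
        p = DecayParams(model_id, a=a, delta=delta, tau=tau, tau1=tau1 if model_id == 3 else None)
        t = np.linspace(0.0, 10.0, 400)
        y = eval_decay_model(p, t)
        assert np.all(np.diff(y) <= 1e-15)
        if model_id in (2, 3):
            eps = 1e-9
            below = eval_decay_model(p, max(delta - eps, 0.0))
            above = eval_decay_model(p, delta + eps)
            assert abs(below - above) < 1e-6 * a


class TestLogLikelihood:
    def test_zero_for_exact_data(self, model2_params, exact_obs):
        assert log_likelihood(exact_obs, model2_params) == pytest.approx(0.0, abs=1e-18)

    def test_single_standardized_residual(self):
        p = DecayParams(1, a=0.03, tau=4.0)
        obs = [GranuleAgeObservation(t=0.0, y=0.03 + 0.002, sem=0.002, n_replicates=3)]
        assert log_likelihood(obs, p) == pytest.approx(-0.5)

    def test_hand_computed_three_point_sum(self):
        # residuals in sem units: 1, -2, 0.5 -> -0.5*(1+4+0.25) = -2.625
        p = DecayParams(1, a=0.03, tau=4.0)
        t = np.array([0.0, 1.0, 2.0])
        f = eval_decay_model(p, t)
        sem = np.array([0.001, 0.002, 0.004])
        y = f + sem * np.array([1.0, -2.0, 0.5])
        assert log_likelihood(_obs(t, y, sem), p) == pytest.approx(-2.625)

    def test_zero_sem_rejected(self):
        p = DecayParams(1, a=0.03, tau=4.0)
        bad = [GranuleAgeObservation(t=1.0, y=0.02, sem=0.0, n_replicates=1)]
        with pytest.raises(ValueError, match="sem"):
            log_likelihood(bad, p)


class TestFitDecayModel:
    def test_exact_recovery_model1(self):
        truth = DecayParams(1, a=0.03, tau=4.0)
        t = np.array([0.27, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = eval_decay_model(truth, t)
        fit = fit_decay_model(_obs(t, y, np.full(6, 0.001)), 1, seed=0)
        assert fit.converged
        assert fit.params.a == pytest.approx(0.03, rel=1e-4)
        assert fit.params.tau == pytest.approx(4.0, rel=1e-4)

    def test_recovery_within_2se_model2(self, model2_params):
        obs = generate_observations(model2_params, seed=11)
        fit = fit_decay_model(obs, 2, seed=11)
        truth = np.array([0.027, 2.72, 2.85])
        assert np.all(np.abs(fit.params.free_values() - truth) <= 2 * fit.std_errors)

    def test_underdetermined_rejected(self):
        obs = _obs([1.0, 2.0], [0.02, 0.02], [0.001, 0.001])
        with pytest.raises(ValueError, match="observations"):
            fit_decay_model(obs, 3)

    def test_covariance_is_symmetric_psd_and_matches_std(self, model2_params):
        obs = generate_observations(model2_params, seed=3)
        fit = fit_decay_model(obs, 2, seed=3)
        cov = fit.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-15)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)
        np.testing.assert_allclose(fit.std_errors, np.sqrt(np.diag(cov)))

    def test_deterministic_given_seed(self, model2_params):
        obs = generate_observations(model2_params, seed=5)
        f1 = fit_decay_model(obs, 2, seed=9)
        f2 = fit_decay_model(obs, 2, seed=9)
        np.testing.assert_array_equal(f1.params.free_values(), f2.params.free_values())
        np.testing.assert_array_equal(f1.std_errors, f2.std_errors)


class TestCompareModels:
    @staticmethod
    def _fabricated_fits(logls):
        obs = tuple(_obs([0.27, 1, 2, 3, 4, 5], [0.027] * 6, [0.002] * 6))
        fits = []
        for mid, ll in zip((1, 2, 3), logls):
            params = DecayParams(mid, a=0.027, delta=2.72, tau=2.85, tau1=15.0 if mid == 3 else None)
            k = len(params.free_values())
            fits.append(
                DecayModelFit(
                    params=params,
                    std_errors=np.full(k, 0.1),
                    covariance=np.eye(k) * 0.01,
                    log_likelihood=ll,
                    n_obs=6,
                    converged=True,
                    observations=obs,
                )
            )
        return fits

    def test_likelihood_ratios_from_reported_fit_scores(self):
        comp = compare_models(self._fabricated_fits([-8.82, -7.20, -14.2]))
        assert comp.ratio(2, 1) == pytest.approx(math.exp(1.62), rel=1e-12)
        assert comp.ratio(2, 3) == pytest.approx(math.exp(7.0), rel=1e-12)
        assert 4.5 < comp.ratio(2, 1) < 5.5  # ~5-fold
        assert 1.0e3 * 0.9 < comp.ratio(2, 3) < 1.2e3  # ~1,000-fold
        assert comp.best_model() == 2

    def test_equal_likelihood_symmetry(self):
        fits = self._fabricated_fits([-5.0, -5.0, -20.0])[:2]
        comp = compare_models(fits)
        assert comp.ratio(1, 2) == pytest.approx(1.0)
        assert comp.posterior_probs[0] == pytest.approx(0.5)
        assert comp.posterior_probs[1] == pytest.approx(0.5)

    def test_probs_normalized_and_ratios_reciprocal(self):
        comp = compare_models(self._fabricated_fits([-8.82, -7.20, -14.2]))
        assert comp.posterior_probs.sum() == pytest.approx(1.0, abs=1e-9)
        r = comp.pairwise_ratios
        np.testing.assert_allclose(r, 1.0 / r.T, rtol=1e-12)

    def test_differing_observations_rejected(self, model2_params):
        obs_a = generate_observations(model2_params, seed=1)
        obs_b = generate_observations(model2_params, seed=2)
        fa = fit_decay_model(obs_a, 1, seed=1)
        fb = fit_decay_model(obs_b, 2, seed=1)
        with pytest.raises(ValueError, match="differing observation"):
            compare_models([fa, fb])

    def test_laplace_evidence_matches_gaussian_closed_form(self):
        # 1-parameter quadratic log-likelihood: logL = -0.5 (a - mu)^2 / s^2.
        # Closed form: Z = integral over the prior box / volume
        #            = s * sqrt(2 pi) / width for s << width.
        mu, s = 0.1, 0.004
        params = DecayParams(1, a=mu, tau=1.0)
        from clemq.decay_models import PARAM_BOUNDS

        width_a = PARAM_BOUNDS["a"][1] - PARAM_BOUNDS["a"][0]
        width_tau = PARAM_BOUNDS["tau"][1] - PARAM_BOUNDS["tau"][0]
        s_tau = 0.5
        cov = np.diag([s**2, s_tau**2])
        fit = DecayModelFit(
            params=params,
            std_errors=np.array([s, s_tau]),
            covariance=cov,
            log_likelihood=0.0,
            n_obs=6,
            converged=True,
        )
        expected = math.log(s * math.sqrt(2 * math.pi) / width_a) + math.log(
            s_tau * math.sqrt(2 * math.pi) / width_tau
        )
        assert _laplace_log_evidence(fit) == pytest.approx(expected, rel=0.01)

    def test_fewer_than_two_fits_rejected(self):
        with pytest.raises(ValueError, match="two fits"):
            compare_models(self._fabricated_fits([-1.0, -2.0, -3.0])[:1])


class TestHalfLife:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (DecayParams(2, a=0.027, delta=2.7, tau=2.8), 2.7 + math.log(2) * 2.8),
            (DecayParams(2, a=0.027, delta=0.0, tau=1.0), math.log(2)),
            (DecayParams(2, a=0.027, delta=2.72, tau=2.85), 2.72 + math.log(2) * 2.85),
            (DecayParams(1, a=0.031, tau=6.0), math.log(2) * 6.0),
        ],
    )
    def test_lag_plus_log2_tau(self, params, expected):
        assert half_life(params) == pytest.approx(expected, rel=1e-12)

    def test_reported_value_rounds_to_4_6_days(self):
        assert round(half_life(DecayParams(2, a=0.027, delta=2.7, tau=2.8)), 1) == 4.6

    def test_model3_piecewise_branches(self):
        # fast branch: slow phase only loses a little by delta
        p = DecayParams(3, a=0.03, delta=2.0, tau=3.0, tau1=20.0)
        t_half = half_life(p)
        assert eval_decay_model(p, t_half) == pytest.approx(0.015, rel=1e-9)
        # slow branch: tau1 ln2 < delta
        p2 = DecayParams(3, a=0.03, delta=5.0, tau=1.0, tau1=2.0)
        t_half2 = half_life(p2)
        assert t_half2 == pytest.approx(2.0 * math.log(2))
        assert eval_decay_model(p2, t_half2) == pytest.approx(0.015, rel=1e-9)


def test_grid_oracle_equivalence(model2_params):
    """Two-parameter optimum agrees with a dense brute-force grid (step 1e-3)."""
    truth = DecayParams(1, a=0.03, tau=4.0)
    t = np.array([0.27, 1.0, 2.0, 3.0, 4.0, 5.0])
    sems = np.full(6, 0.0015)
    rng = np.random.default_rng(7)
    y = np.clip(eval_decay_model(truth, t) + rng.normal(0, sems), 0, 1)
    obs = _obs(t, y, sems)
    fit = fit_decay_model(obs, 1, seed=7)
    a_hat, tau_hat = fit.params.free_values()

    step = 1e-3
    a_grid = np.arange(max(a_hat - 0.015, step), a_hat + 0.015, step)
    tau_grid = np.arange(max(tau_hat - 0.8, step), tau_hat + 0.8, step)
    A, T = np.meshgrid(a_grid, tau_grid, indexing="ij")
    pred = A[..., None] * np.exp(-t[None, None, :] / T[..., None])
    nll = 0.5 * np.sum(((y - pred) / sems) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    assert abs(a_hat - a_grid[i]) <= step + 1e-12
    assert abs(tau_hat - tau_grid[j]) <= step + 1e-12
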