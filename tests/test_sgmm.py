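"""Constrained sequential Gaussian mixture: densities, EM/MDL, updates, thresholds."""

import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from emgonset import (
    GmmConfig,
    GmmState,
    apply_constraints,
    component_density,
    em_fit,
    mdl_select,
    optimal_threshold,
    posterior_burst_prob,
    sequential_update,
)
from emgonset.sgmm import initialize_state


def random_constrained_state(rng, config=None):
    """Random state satisfying the burst/non-burst ordering constraints."""
    if config is None:
        config = GmmConfig()
    mu0 = rng.uniform(-30.0, 10.0)
    gap = rng.uniform(config.delta, 25.0)
    k0 = rng.uniform(0.5, 15.0)
    k1 = k0 * rng.uniform(1.0, 4.0)
    w1 = rng.uniform(config.epsilon, 0.6)
    return GmmState(w0=1 - w1, w1=w1, mu0=mu0, mu1=mu0 + gap, kappa0=k0, kappa1=k1)


class TestComponentDensity:
    def test_standard_normal_mode(self):
        assert component_density(0.0, 0.0, 1.0) == pytest.approx(
            1 / math.sqrt(2 * math.pi), abs=1e-12
        )

    def test_symmetry(self):
        assert component_density(2.5, 1.0, 3.0) == component_density(-0.5, 1.0, 3.0)

    def test_closed_form_value(self):
        want = math.exp(-0.5) / math.sqrt(8 * math.pi)
        assert component_density(2.0, 0.0, 4.0) == pytest.approx(want, abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            component_density(0.0, 0.0, 0.0)


class TestPosterior:
    def test_symmetric_midpoint(self):
        state = GmmState(0.5, 0.5, 0.0, 10.0, 4.0, 4.0)
        assert posterior_burst_prob(5.0, state) == pytest.approx(0.5, abs=1e-12)

    def test_dominance_limit(self):
        state = GmmState(0.5, 0.5, 0.0, 50.0, 1.0, 1.0)
        assert posterior_burst_prob(60.0, state) > 0.999

    def test_matches_direct_formula(self, rng):
        """Independent straight-line evaluation of the posterior ratio."""
        for _ in range(200):
            state = random_constrained_state(rng)
            x = rng.uniform(state.mu0 - 10, state.mu1 + 10)
            f0 = math.exp(-0.5 * (x - state.mu0) ** 2 / state.kappa0) / math.sqrt(
                2 * math.pi * state.kappa0
            )
            f1 = math.exp(-0.5 * (x - state.mu1) ** 2 / state.kappa1) / math.sqrt(
                2 * math.pi * state.kappa1
            )
            want = state.w1 * f1 / (state.w0 * f0 + state.w1 * f1)
            assert posterior_burst_prob(x, state) == pytest.approx(want, abs=1e-12)

    def test_extreme_observations_never_nan(self):
        state = GmmState(0.97, 0.03, 0.0, 3.5, 1.0, 1.0)
        for x in (-1e6, 1e6, -1e3, 1e3):
            p = posterior_burst_prob(x, state)
            assert 0.0 <= p <= 1.0


class TestEmFit:
    def test_single_gaussian_closed_form(self):
        fit, ll = em_fit(np.array([1.0, 2.0, 3.0]), n_components=1)
        assert fit.mu == pytest.approx(2.0)
        assert fit.kappa == pytest.approx(2.0 / 3.0)
        want_ll = sum(
            math.log(component_density(v, 2.0, 2.0 / 3.0)) for v in (1.0, 2.0, 3.0)
        )
        assert ll == pytest.approx(want_ll, abs=1e-9)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 700), rng.normal(10, 1, 300)])
        state, _ = em_fit(x, 2)
        assert state.mu0 == pytest.approx(0.0, abs=0.3)
        assert state.mu1 == pytest.approx(10.0, abs=0.3)
        assert state.w1 == pytest.approx(0.3, abs=0.05)

    def test_loglik_monotone(self, rng):
        x = np.concatenate([rng.normal(0, 2, 150), rng.normal(6, 1, 50)])
        _, _, history = em_fit(x, 2, return_history=True)
        assert all(b >= a - 1e-9 for a, b in zip(history, history[1:]))

    def test_agrees_with_sklearn_mixture(self):
        """Independent cross-check against a reference EM implementation."""
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(-5, 1.5, 400), rng.normal(5, 1.0, 200)])
        state, _ = em_fit(x, 2)
        gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        assert state.mu0 == pytest.approx(gm.means_.ravel()[order[0]], abs=0.1)
        assert state.mu1 == pytest.approx(gm.means_.ravel()[order[1]], abs=0.1)
        assert state.w1 == pytest.approx(gm.weights_[order[1]], abs=0.02)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            em_fit(np.array([1.0]))
        with pytest.raises(ValueError):
            em_fit(np.array([1.0, np.nan, 2.0]))
        with pytest.raises(ValueError):
            em_fit(np.zeros(10), n_components=3)


class TestMdlSelect:
    def test_noise_only_selects_one(self):
        hits = sum(
            mdl_select(np.random.default_rng(i).normal(0, 1, 80)) == 1
            for i in range(100)
        )
        assert hits >= 95

    def test_well_separated_selects_two(self):
        hits = 0
        for i in range(100):
            r = np.random.default_rng(1000 + i)
            x = np.concatenate([r.normal(0, 1, 40), r.normal(12, 1, 40)])
            hits += mdl_select(x) == 2
        assert hits >= 95


class TestConstraints:
    def test_mean_gap_enforced(self):
        state = GmmState(0.5, 0.5, 0.0, 1.0, 1.0, 1.0)
        out = apply_constraints(state, GmmConfig(delta=3.5))
        assert out.mu1 == 3.5

    def test_weight_floor_enforced(self):
        state = GmmState(0.999, 0.001, 0.0, 10.0, 1.0, 1.0)
        out = apply_constraints(state, GmmConfig(epsilon=0.03))
        assert out.w1 == 0.03 and out.w0 == 0.97

    def test_variance_ordering_enforced(self):
        state = GmmState(0.5, 0.5, 0.0, 10.0, 4.0, 1.0)
        assert apply_constraints(state).kappa1 == 4.0

    def test_idempotent_when_satisfied(self, rng):
        state = random_constrained_state(rng)
        assert apply_constraints(state) == apply_constraints(apply_constraints(state))


class TestSequentialUpdate:
    def test_alpha_one_is_identity(self, rng):
        cfg = GmmConfig(alpha=1.0)
        state = random_constrained_state(rng)
        out = sequential_update(state, state.mu1 + 1.0, cfg)
        assert out == apply_constraints(state, cfg)

    def test_posterior_fixed_point_keeps_weights(self):
        # with equal variances and x at the point where the posterior equals
        # the prior weights, the weight recursion is a fixed point
        state = GmmState(0.7, 0.3, 0.0, 10.0, 4.0, 4.0)
        # solve posterior(x) = w1: w1 f1 / (w0 f0 + w1 f1) = w1 <=> f1 = f0
        x = 5.0  # equal densities by symmetry
        out = sequential_update(state, x, GmmConfig(alpha=0.99))
        assert out.w1 == pytest.approx(state.w1, abs=1e-12)

    def test_matches_straight_line_recursions(self, rng):
        """Independent evaluation of the posterior and the three recursions."""
        cfg = GmmConfig()
        checked = 0
        while checked < 200:
            state = random_constrained_state(rng)
            x = rng.uniform(state.mu0 - 3, state.mu1 + 3)
            a = cfg.alpha
            f0 = component_density(x, state.mu0, state.kappa0)
            f1 = component_density(x, state.mu1, state.kappa1)
            p1 = state.w1 * f1 / (state.w0 * f0 + state.w1 * f1)
            p0 = 1 - p1
            w0n = a * state.w0 + (1 - a) * p0
            w1n = a * state.w1 + (1 - a) * p1
            mu0n = (a * state.w0 * state.mu0 + (1 - a) * p0 * x) / w0n
            mu1n = (a * state.w1 * state.mu1 + (1 - a) * p1 * x) / w1n
            k0n = (a * state.w0 * state.kappa0 + (1 - a) * p0 * (x - mu0n) ** 2) / w0n
            k1n = (a * state.w1 * state.kappa1 + (1 - a) * p1 * (x - mu1n) ** 2) / w1n
            # compare only where the constraints are inactive so the raw
            # recursions are observable
            if mu1n < mu0n + cfg.delta or k1n < k0n or w1n < cfg.epsilon:
                continue
            out = sequential_update(state, x, cfg)
            assert out.w0 == pytest.approx(w0n, abs=1e-12)
            assert out.w1 == pytest.approx(w1n, abs=1e-12)
            assert out.mu0 == pytest.approx(mu0n, abs=1e-12)
            assert out.mu1 == pytest.approx(mu1n, abs=1e-12)
            assert out.kappa0 == pytest.approx(k0n, abs=1e-12)
            assert out.kappa1 == pytest.approx(k1n, abs=1e-12)
            checked += 1

    def test_weights_sum_to_one(self, rng):
        state = random_constrained_state(rng)
        out = sequential_update(state, 5.0, GmmConfig())
        assert out.w0 + out.w1 == pytest.approx(1.0, abs=1e-12)

    def test_nonfinite_observation_skipped(self, rng):
        state = random_constrained_state(rng)
        with pytest.warns(UserWarning):
            out = sequential_update(state, float("nan"), GmmConfig())
        assert out == state

    def test_noise_only_convergence_and_constraints(self):
        """Long noise-only updating: mu0 tracks the noise and the virtual
        burst component keeps its enforced gap and weight floor."""
        cfg = GmmConfig()
        init = np.random.default_rng(5).normal(-20, math.sqrt(2.0), 80)
        state, k = initialize_state(init, cfg)
        assert k == 1
        r = np.random.default_rng(6)
        for _ in range(5000):
            state = sequential_update(state, r.normal(-20, math.sqrt(2.0)), cfg)
        assert state.mu0 == pytest.approx(-20.0, abs=0.5)
        assert state.mu1 - state.mu0 >= cfg.delta - 1e-12
        assert state.w1 >= cfg.epsilon - 1e-12

    def test_sequential_tracks_batch_on_stationary_stream(self):
        """After 2000 frames of a stationary bimodal stream the sequential
        means agree with batch EM on the same data within 0.5 dB."""
        rng = np.random.default_rng(9)
        labels = rng.random(2000) < 0.4
        x = np.where(labels, rng.normal(12.0, 2.0, 2000), rng.normal(0.0, 1.0, 2000))
        cfg = GmmConfig()
        state, _ = initialize_state(x[: cfg.m_init], cfg)
        for v in x[cfg.m_init :]:
            state = sequential_update(state, v, cfg)
        batch, _ = em_fit(x, 2)
        assert state.mu0 == pytest.approx(batch.mu0, abs=0.5)
        assert state.mu1 == pytest.approx(batch.mu1, abs=0.5)


class TestOptimalThreshold:
    def test_symmetric_midpoint(self):
        state = GmmState(0.5, 0.5, 0.0, 10.0, 2.0, 2.0)
        assert optimal_threshold(state) == pytest.approx(5.0, abs=1e-12)

    def test_equal_variance_closed_form(self):
        state = GmmState(0.7, 0.3, 0.0, 10.0, 1.0, 1.0)
        want = 5.0 + math.log(0.7 / 0.3) / 10.0
        assert optimal_threshold(state) == pytest.approx(want, abs=1e-9)
        assert optimal_threshold(state) == pytest.approx(5.0847, abs=1e-4)

    def test_threshold_is_density_crossing(self, rng):
        for _ in range(50):
            state = random_constrained_state(rng)
            theta = optimal_threshold(state)
            lhs = state.w1 * component_density(theta, state.mu1, state.kappa1)
            rhs = state.w0 * component_density(theta, state.mu0, state.kappa0)
            assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_matches_bayes_error_grid_minimizer(self, rng):
        """Brute-force 0.001 dB grid minimisation of the weighted error;
        positional agreement is only meaningful where the minimum is sharp
        (flat double-precision-zero valleys arise for huge separations)."""
        for _ in range(25):
            state = random_constrained_state(rng)
            theta = optimal_threshold(state)
            s0, s1 = math.sqrt(state.kappa0), math.sqrt(state.kappa1)
            grid = np.arange(state.mu0 - s0, state.mu1 + 3 * s1, 0.001)
            err = state.w1 * norm.cdf((grid - state.mu1) / s1) + state.w0 * (
                1 - norm.cdf((grid - state.mu0) / s0)
            )
            k = int(np.argmin(err))
            theta_err = state.w1 * norm.cdf((theta - state.mu1) / s1) + state.w0 * (
                1 - norm.cdf((theta - state.mu0) / s0)
            )
            assert theta_err <= err[k] * (1 + 1e-9) + 1e-12
            if err[k] > 1e-12:
                assert abs(theta - grid[k]) <= 0.002

    def test_unordered_means_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold(GmmState(0.5, 0.5, 5.0, 1.0, 1.0, 1.0))
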