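"""Membrane-potential update rules and trace recording."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ipvae import (
    DynamicsConfig,
    InferenceState,
    LatentConfig,
    SyntheticSpec,
    lateral_weights,
    online_step,
    rate_space_step,
    run_inference,
    static_prior_step,
    synth_patches,
)
from ipvae.generative import fisher_preconditioner, free_energy_gradient


def pinned(z_value):
    """Sampler hook that returns a fixed spike vector regardless of the state."""
    z = np.asarray(z_value, dtype=float)
    return lambda mean, family, rng: np.broadcast_to(z, np.shape(mean)).copy()


class TestLateralWeights:
    def test_orthonormal_columns_give_identity(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((8, 4)))
        assert np.allclose(lateral_weights(q), np.eye(4), atol=1e-12)

    def test_direct_arithmetic(self):
        assert np.allclose(lateral_weights(np.array([[1.0], [1.0]])), [[2.0]])

    def test_symmetric_positive_semidefinite(self):
        phi = np.random.default_rng(1).standard_normal((8, 4))
        W = lateral_weights(phi)
        assert np.allclose(W, W.T, atol=1e-12)
        assert np.linalg.eigvalsh(W).min() >= -1e-10
        assert np.allclose(np.diag(W), np.sum(phi**2, axis=0))


class TestStaticPriorStep:
    def test_fixed_point_with_null_input(self):
        cfg = LatentConfig(K=1, beta=1.0)
        dyn = DynamicsConfig(mode="static_prior", eta=1.0, T=1)
        u = np.array([-30.0])  # rate ~ 0, z = 0 a.s. (clamped to -8 internally)
        state = InferenceState(0, u.copy(), u.copy())
        new = static_prior_step(state, np.zeros(2), np.array([[1.0], [1.0]]), cfg, dyn,
                                np.random.default_rng(0), sampler=pinned([0.0]))
        assert np.allclose(new.u, np.clip(u, *cfg.u_clamp))
        assert np.allclose(new.u0, state.u0)

    def test_direct_arithmetic_with_pinned_spike(self):
        cfg = LatentConfig(K=1, beta=0.0)
        dyn = DynamicsConfig(mode="static_prior", eta=1.0, T=1)
        state = InferenceState(0, np.zeros(1), np.zeros(1))
        new = static_prior_step(state, np.array([1.0, 2.0]), np.array([[1.0], [1.0]]),
                                cfg, dyn, np.random.default_rng(0), sampler=pinned([3.0]))
        # u' = 0 + [Phi^T x - Phi^T Phi z] = 3 - 2*3 = -3
        assert np.allclose(new.u, [-3.0])

    def test_matches_natural_gradient_composition(self):
        rng = np.random.default_rng(3)
        cfg = LatentConfig(K=4, beta=0.8)
        dyn = DynamicsConfig(mode="static_prior", eta=0.3, T=1)
        phi = rng.standard_normal((6, 4))
        x = rng.standard_normal(6)
        u = rng.uniform(-1, 1, 4)
        u0 = rng.uniform(-1, 1, 4)
        z = rng.poisson(np.exp(u)).astype(float)
        state = InferenceState(0, u.copy(), u0.copy())
        new = static_prior_step(state, x, phi, cfg, dyn, np.random.default_rng(0),
                                sampler=pinned(z))
        nat_grad = -free_energy_gradient(x, phi, u, u0, z, cfg) / fisher_preconditioner(u, cfg)
        assert np.allclose(new.u, np.clip(u + dyn.eta * nat_grad, *cfg.u_clamp), atol=1e-10)


class TestOnlineStep:
    def test_null_drive_is_fixed_point(self):
        cfg = LatentConfig(K=1)
        dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
        state = InferenceState(0, np.array([0.5]), np.array([0.5]))
        new = online_step(state, np.zeros(2), np.array([[1.0], [1.0]]), cfg, dyn,
                          np.random.default_rng(0), sampler=pinned([0.0]))
        assert np.allclose(new.u, [0.5])

    def test_direct_arithmetic_and_rolling_prior(self):
        cfg = LatentConfig(K=1)
        dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
        state = InferenceState(0, np.zeros(1), np.full(1, -5.0))
        new = online_step(state, np.array([1.0, 2.0]), np.array([[1.0], [1.0]]),
                          cfg, dyn, np.random.default_rng(0), sampler=pinned([3.0]))
        assert np.allclose(new.u, [-3.0])
        assert np.allclose(new.u0, [0.0])  # old posterior became the prior

    def test_random_instance_matches_matrix_oracle(self):
        rng = np.random.default_rng(4)
        cfg = LatentConfig(K=8)
        dyn = DynamicsConfig(mode="online", eta=0.5, T=1)
        phi = rng.standard_normal((16, 8))
        x = rng.standard_normal(16)
        u = rng.uniform(-1, 1, 8)
        z = rng.poisson(np.exp(u)).astype(float)
        state = InferenceState(0, u.copy(), u.copy())
        new = online_step(state, x, phi, cfg, dyn, np.random.default_rng(0), sampler=pinned(z))
        oracle = np.clip(u + 0.5 * (phi.T @ x - phi.T @ phi @ z), *cfg.u_clamp)
        assert np.allclose(new.u, oracle, atol=1e-10)

    def test_self_suppression(self):
        # unit-norm columns, x = 0: a big spike on unit i strictly lowers u_i
        rng = np.random.default_rng(5)
        phi = rng.standard_normal((8, 3))
        phi /= np.linalg.norm(phi, axis=0, keepdims=True)
        cfg = LatentConfig(K=3)
        dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
        u = np.array([3.0, -1.0, -1.0])
        z = np.array([25.0, 0.0, 0.0])
        state = InferenceState(0, u.copy(), u.copy())
        new = online_step(state, np.zeros(8), phi, cfg, dyn,
                          np.random.default_rng(0), sampler=pinned(z))
        assert new.u[0] < u[0]


class TestRateSpaceEquivalence:
    def test_multiplicative_form_matches_exponentiated_update(self):
        rng = np.random.default_rng(6)
        cfg = LatentConfig(K=5, u_clamp=(-50.0, 50.0))  # wide clamp: compare raw algebra
        dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
        for _ in range(200):
            phi = rng.standard_normal((7, 5)) * 0.5
            x = rng.standard_normal(7)
            u = rng.uniform(-2, 2, 5)
            z = rng.poisson(np.exp(u)).astype(float)
            state = InferenceState(0, u.copy(), u.copy())
            new = online_step(state, x, phi, cfg, dyn, np.random.default_rng(0),
                              sampler=pinned(z))
            r_next = rate_space_step(np.exp(u), x, phi, z, dyn)
            assert np.allclose(r_next, np.exp(new.u), rtol=1e-10)

    def test_hand_algebra_toy_case(self):
        # u: 0 -> -3, so r: 1 -> e^{-3} = e^3 / e^6
        dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
        phi = np.array([[1.0], [1.0]])
        r_next = rate_space_step(np.array([1.0]), np.array([1.0, 2.0]), phi,
                                 np.array([3.0]), dyn)
        assert np.isclose(r_next[0], np.exp(-3.0), rtol=1e-12)

    def test_no_spikes_means_no_normalization(self):
        rng = np.random.default_rng(7)
        phi = rng.standard_normal((4, 3))
        x = rng.standard_normal(4)
        r = np.array([0.5, 1.0, 2.0])
        dyn = DynamicsConfig(mode="online", eta=1.0, T=1)
        r_next = rate_space_step(r, x, phi, np.zeros(3), dyn)
        assert np.allclose(r_next, r * np.exp(phi.T @ x), rtol=1e-12)

    def test_requires_unit_step(self):
        dyn = DynamicsConfig(mode="online", eta=0.5, T=1)
        with pytest.raises(ValueError, match="eta"):
            rate_space_step(np.ones(1), np.ones(2), np.ones((2, 1)), np.zeros(1), dyn)


class TestRunInference:
    def test_single_step_equals_one_step_op(self):
        rng_seed = 42
        cfg = LatentConfig(K=3)
        dyn = DynamicsConfig(mode="online", eta=0.5, T=1)
        phi = np.random.default_rng(0).standard_normal((5, 3))
        x = np.random.default_rng(1).standard_normal(5)
        u0 = np.full(3, np.log(0.5))
        trace = run_inference(x, phi, cfg, dyn, np.random.default_rng(rng_seed), u_init=u0)
        state = InferenceState(0, u0.copy(), u0.copy())
        new = online_step(state, x, phi, cfg, dyn, np.random.default_rng(rng_seed))
        assert np.allclose(trace.u[-1], new.u)
        assert np.allclose(trace.z[-1], new.z)

    def test_identical_seeds_identical_traces(self):
        cfg = LatentConfig(K=4)
        dyn = DynamicsConfig(mode="online", eta=0.2, T=50)
        phi = np.random.default_rng(2).standard_normal((6, 4))
        x = np.random.default_rng(3).standard_normal(6)
        t1 = run_inference(x, phi, cfg, dyn, np.random.default_rng(9))
        t2 = run_inference(x, phi, cfg, dyn, np.random.default_rng(9))
        assert np.array_equal(t1.u, t2.u) and np.array_equal(t1.z, t2.z)

    def test_update_norm_shrinks_on_synthetic_input(self):
        ds, phi_star, _ = synth_patches(SyntheticSpec(n_patches=4, seed=0))
        cfg = LatentConfig(K=16)
        dyn = DynamicsConfig(mode="online", eta=0.1, T=1000)
        trace = run_inference(ds.X[0], phi_star, cfg, dyn, np.random.default_rng(0))
        early = trace.update_norms[:100].mean()
        late = trace.update_norms[-100:].mean()
        assert late < early

    def test_divergence_guard_names_step(self):
        cfg = LatentConfig(K=1, u_clamp=(-np.inf, np.inf))
        dyn = DynamicsConfig(mode="online", eta=1.0, T=10)

        def bad_sampler(mean, family, rng):
            return np.full(np.shape(mean), np.nan)

        with pytest.raises(FloatingPointError, match="step 1"):
            run_inference(np.ones(2), np.ones((2, 1)), cfg, dyn,
                          np.random.default_rng(0), sampler=bad_sampler)

    def test_rolling_prior_kl_finite_every_step(self):
        from ipvae.generative import poisson_kl

        cfg = LatentConfig(K=4)
        dyn = DynamicsConfig(mode="online", eta=0.2, T=100)
        phi = np.random.default_rng(4).standard_normal((8, 4)) * 0.3
        x = np.random.default_rng(5).standard_normal(8)
        trace = run_inference(x, phi, cfg, dyn, np.random.default_rng(6))
        assert np.all(np.isfinite(trace.kl)) and np.all(trace.kl >= 0)

    def test_mean_field_fixed_point_solves_balance_equation(self):
        # With z replaced by its mean, fixed points satisfy Phi^T x = W exp(u*).
        rng = np.random.default_rng(10)
        phi = rng.standard_normal((4, 2))
        phi /= np.linalg.norm(phi, axis=0, keepdims=True)
        a_true = np.array([1.5, 0.8])
        x = phi @ a_true
        cfg = LatentConfig(K=2, u_clamp=(-20.0, 20.0))
        dyn = DynamicsConfig(mode="online", eta=0.05, T=4000)
        mean_field = lambda mean, family, _rng: mean
        trace = run_inference(x, phi, cfg, dyn, np.random.default_rng(0), sampler=mean_field)
        u_star = trace.u[-1]
        W = phi.T @ phi
        assert np.allclose(phi.T @ x, W @ np.exp(u_star), atol=1e-5)
        # independent root-finding oracle: since x is in the span, exp(u*) = a_true
        assert np.allclose(np.exp(u_star), a_true, atol=1e-4)

    def test_trace_roundtrip(self, tmp_path):
        cfg = LatentConfig(K=2)
        dyn = DynamicsConfig(mode="online", eta=0.5, T=5)
        phi = np.random.default_rng(0).standard_normal((3, 2))
        trace = run_inference(np.ones(3), phi, cfg, dyn, np.random.default_rng(1))
        trace.save(str(tmp_path / "trace"))
        loaded = np.load(tmp_path / "trace.npz")
        assert np.array_equal(loaded["u"], trace.u)
        assert (tmp_path / "trace.json").exists()


class TestDynamicsConfigValidation:
    @pytest.mark.parametrize("kwargs", [{"eta": 0.0}, {"T": 0}, {"mode": "warp"}])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DynamicsConfig(**kwargs)
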