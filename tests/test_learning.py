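"""Unit and property tests for the Infomax plasticity rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infomaxnet import LearningConfig, NetworkConfig, SynapticParameters
from infomaxnet.learning import (
    GlobalSignals,
    InfomaxTrainer,
    ReferenceLearner,
    TraceState,
    apply_update,
    eligibility_psi,
    global_signals,
    leaky_update,
    scale_coefficients,
    surprise_terms,
    train,
)
from infomaxnet.stimuli import EpisodicSequenceConfig, EpisodicSequenceStream

from conftest import make_params


class TestScaleCoefficients:
    def test_reference_values(self):
        c = scale_coefficients(1.0, 1.5, 3.0, 50, 0.05)
        assert c.kappa == pytest.approx(2.0 / (49 * 0.0025), rel=1e-12)
        assert c.kappa == pytest.approx(16.3265, rel=1e-4)
        assert c.zeta == pytest.approx(1.0 / 9.0, rel=1e-12)
        assert c.eta == pytest.approx(1.0 / (1.5 ** 2 * 0.05 ** 4), rel=1e-12)

    def test_scaling_laws(self):
        base = scale_coefficients(1.0, 1.0, 1.0, 50, 0.05)
        assert scale_coefficients(2.0, 1.0, 1.0, 50, 0.05).kappa == pytest.approx(base.kappa / 2)
        assert scale_coefficients(1.0, 1.0, 4.0, 50, 0.05).zeta == pytest.approx(base.zeta / 16)

    def test_tiny_network_rejected(self):
        with pytest.raises(ValueError):
            scale_coefficients(1.0, 1.0, 1.0, 1, 0.05)


class TestLeakyUpdate:
    def test_fixed_point(self):
        assert leaky_update(3.7, 3.7, 10.0) == pytest.approx(3.7)

    def test_first_step_from_cold_start(self):
        assert leaky_update(0.0, 5.0, 25.0) == pytest.approx(0.2)

    def test_geometric_convergence_closed_form(self):
        avg = 0.0
        for _ in range(100):
            avg = leaky_update(avg, 1.0, 10.0)
        assert avg == pytest.approx(1.0 - 0.9 ** 100, rel=1e-12)

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3), st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_convex_combination(self, avg, new, leak):
        out = float(leaky_update(avg, new, leak))
        lo, hi = min(avg, new), max(avg, new)
        assert lo - 1e-9 * (1 + abs(lo)) <= out <= hi + 1e-9 * (1 + abs(hi))


class TestEligibilityPsi:
    def test_saturated_prediction_vanishes(self):
        assert eligibility_psi(40.0, 1, 0.95) == pytest.approx(0.0, abs=1e-15)

    def test_fired_at_zero_input(self):
        assert eligibility_psi(0.0, 1, 0.95) == pytest.approx(0.5)

    def test_quiescent_at_zero_input(self):
        # -p_max/2 * 1/2 / (1 - p_max/2) with p_max = 0.95
        assert eligibility_psi(0.0, 0, 0.95) == pytest.approx(-0.2375 / 0.525)
        assert eligibility_psi(0.0, 0, 0.95) == pytest.approx(-0.45238, abs=1e-5)

    def test_sign_follows_outcome(self):
        for s in (-3.0, 0.0, 3.0):
            assert eligibility_psi(s, 1, 0.9) > 0
            assert eligibility_psi(s, 0, 0.9) < 0

    def test_score_identity_zero_mean(self):
        """E[psi | s] = 0 exactly: the score of the firing likelihood."""
        s_grid = np.linspace(-20, 20, 100)
        for p_max in np.linspace(0.05, 1.0, 10):
            sig = 1.0 / (1.0 + np.exp(-s_grid))
            p = p_max * sig
            e = p * eligibility_psi(s_grid, np.ones_like(s_grid), p_max) + (
                1 - p
            ) * eligibility_psi(s_grid, np.zeros_like(s_grid), p_max)
            np.testing.assert_allclose(e, 0.0, atol=1e-14)

    @given(st.floats(-30, 30), st.floats(0.05, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_psi_is_derivative_of_log_likelihood(self, s, p_max):
        """psi equals d/ds log p(x^{t+1} | s), checked by central differences."""
        eps = 1e-6

        def logp(s_, fired):
            p = p_max / (1.0 + math.exp(-s_))
            return math.log(p) if fired else math.log(1.0 - p)

        for fired in (0, 1):
            fd = (logp(s + eps, fired) - logp(s - eps, fired)) / (2 * eps)
            assert eligibility_psi(s, fired, p_max) == pytest.approx(fd, abs=1e-6)


class TestSurpriseTerms:
    def _traces(self, n, avg_p):
        t = TraceState.zeros(n, n)
        t.avg_fire_prob = np.full(n, avg_p)
        return t

    def test_perfectly_predicted_firing_is_zero(self):
        # p(x=1) = p_max sigma(s) equals the marginal estimate -> log 1
        net = NetworkConfig(n_neurons=1, p_max=0.95, p0=0.05)
        traces = self._traces(1, 0.95 / 2)
        lr, z = surprise_terms(np.array([1]), np.zeros(1), traces, 0.95, 1e-3)
        assert lr[0] == pytest.approx(0.0, abs=1e-12)

    def test_log19_for_saturated_firing(self):
        # x=1 with p -> p_max against marginal Z = p0: log(p_max/p0) = log 19
        traces = self._traces(1, 0.05)
        lr, _ = surprise_terms(np.array([1]), np.array([50.0]), traces, 0.95, 1e-3)
        assert lr[0] == pytest.approx(math.log(19.0), rel=1e-6)

    def test_denominator_floored_at_delta(self):
        traces = self._traces(1, 1e-6)
        lr, z = surprise_terms(np.array([1]), np.zeros(1), traces, 0.95, 1e-3)
        assert z[0] == pytest.approx(1e-3)
        assert lr[0] == pytest.approx(math.log(0.475 / 1e-3))


class TestGlobalSignals:
    def _setup(self, n=4):
        net = NetworkConfig(n_neurons=n, p_max=0.95, p0=0.05)
        learn = LearningConfig(T=1000.0)
        coeffs = scale_coefficients(learn.c_kappa, learn.c_eta, learn.c_zeta, n, net.p0)
        traces = TraceState.zeros(n, n)
        return net, learn, coeffs, traces

    def test_silent_step_zeroes_activity_gated_terms(self):
        net, learn, coeffs, traces = self._setup()
        x = np.zeros(4, dtype=np.uint8)
        g = global_signals(x, np.full(4, net.s0), None, traces, coeffs, net, learn)
        assert g.gamma2 == 0.0 and g.gamma3 == 0.0

    def test_reference_input_zeroes_gamma4(self):
        net, learn, coeffs, traces = self._setup()
        x = np.ones(4, dtype=np.uint8)
        g = global_signals(x, np.full(4, net.s0), None, traces, coeffs, net, learn)
        assert g.gamma4 == 0.0

    def test_gamma2_reference_value(self):
        """gamma2 = kappa (m(m-1)/2 - (<m>_T - p0) m) at m=2, <m>=2.5."""
        net = NetworkConfig(n_neurons=50, p_max=0.95, p0=0.05)
        learn = LearningConfig()
        coeffs = scale_coefficients(1.0, 1.5, 3.0, 50, 0.05)
        traces = TraceState.zeros(50, 50)
        traces.avg_m = 2.5
        x = np.zeros(50, dtype=np.uint8)
        x[[3, 17]] = 1
        g = global_signals(x, np.full(50, net.s0), None, traces, coeffs, net, learn)
        expected = coeffs.kappa * (1.0 - (2.5 - 0.05) * 2.0)
        assert g.gamma2 == pytest.approx(expected, rel=1e-12)
        assert g.gamma2 == pytest.approx(-63.67, abs=0.05)

    def test_gamma4_nonnegative(self, rng):
        net, learn, coeffs, traces = self._setup()
        for _ in range(10):
            x = (rng.random(4) < 0.5).astype(np.uint8)
            g = global_signals(x, rng.normal(size=4), rng.normal(size=4), traces, coeffs, net, learn)
            assert g.gamma4 >= 0.0

    def test_scope_restricts_sums(self):
        net, learn, coeffs, traces = self._setup()
        learn_scoped = LearningConfig(T=1000.0, gamma_scope=(0, 1))
        x = np.zeros(4, dtype=np.uint8)
        x[2] = 1  # outside scope
        s = np.full(4, net.s0)
        s[3] = net.s0 + 5.0  # outside scope
        g = global_signals(x, s, None, traces, coeffs, net, learn_scoped)
        assert g.gamma2 == 0.0 and g.gamma3 == 0.0 and g.gamma4 == 0.0


class TestApplyUpdate:
    def test_quiescent_reference_state_is_fixed_point(self):
        net = NetworkConfig(n_neurons=3, p_max=0.95, p0=0.05)
        learn = LearningConfig()
        coeffs = scale_coefficients(1.0, 1.5, 3.0, 3, 0.05)
        params = make_params(3, seed=1)
        traces = TraceState.zeros(3, 3)
        sig = GlobalSignals(1.0, 2.0, 3.0, 4.0)
        out = apply_update(
            params, traces, sig, np.full(3, net.s0), np.zeros(3, dtype=np.uint8),
            coeffs, net, learn,
        )
        np.testing.assert_array_equal(out.weights, params.weights)
        np.testing.assert_array_equal(out.thresholds, params.thresholds)

    def test_zero_combined_signal_leaves_only_fluctuation_term(self):
        net = NetworkConfig(n_neurons=2, p_max=0.95, p0=0.05)
        learn = LearningConfig(epsilon=0.01, T=100.0)
        coeffs = scale_coefficients(1.0, 1.5, 3.0, 2, 0.05)
        params = SynapticParameters(np.zeros((2, 2)), np.zeros(2))
        traces = TraceState.zeros(2, 2)
        traces.elig_pair[:] = 0.5  # must be ignored when combined signal is 0
        s = np.array([net.s0 + 1.0, net.s0])
        x = np.array([0, 1], dtype=np.uint8)
        out = apply_update(params, traces, GlobalSignals(0, 0, 0, 0), s, x, coeffs, net, learn)
        expected01 = -0.01 * coeffs.zeta / 100.0 * 1.0 * 1.0  # -eps zeta/T (s_0-s0) x_1
        assert out.weights[0, 1] == pytest.approx(expected01, rel=1e-12)
        assert out.weights[1, 0] == pytest.approx(0.0, abs=1e-15)

    def test_single_synapse_reference_value(self):
        """dw = eps (tau/T) G <psi x>_tau = 0.01 * (15/50000) * 3 * 0.2."""
        net = NetworkConfig(n_neurons=2, p_max=0.95, p0=0.05)
        learn = LearningConfig(epsilon=0.01, tau=15.0, T=50000.0)
        coeffs = scale_coefficients(1.0, 1.5, 3.0, 2, 0.05)
        params = SynapticParameters(np.zeros((2, 2)), np.zeros(2))
        traces = TraceState.zeros(2, 2)
        traces.elig_pair[0, 1] = 0.2
        sig = GlobalSignals(3.0, 0.0, 0.0, 0.0)
        out = apply_update(
            params, traces, sig, np.full(2, net.s0), np.zeros(2, dtype=np.uint8),
            coeffs, net, learn,
        )
        assert out.weights[0, 1] == pytest.approx(1.8e-6, rel=1e-9)

    def test_masked_entries_conserved(self):
        net = NetworkConfig(n_neurons=4, p_max=0.95, p0=0.05)
        learn = LearningConfig(epsilon=0.1, T=10.0, plastic_rows=(0, 1), plastic_cols=(0, 1, 2))
        coeffs = scale_coefficients(1.0, 1.5, 3.0, 4, 0.05)
        params = make_params(4, seed=5)
        before = params.copy()
        traces = TraceState.zeros(4, 4)
        traces.elig_pair[:] = 0.3
        traces.elig_post[:] = 0.1
        out = apply_update(
            params, traces, GlobalSignals(5, 0, 0, 0), np.ones(4), np.ones(4, dtype=np.uint8),
            coeffs, net, learn,
        )
        np.testing.assert_array_equal(out.weights[2:], before.weights[2:])
        np.testing.assert_array_equal(out.weights[:, 3], before.weights[:, 3])
        np.testing.assert_array_equal(out.thresholds[2:], before.thresholds[2:])
        assert np.any(out.weights[0, 1:3] != before.weights[0, 1:3])
        assert np.all(np.diagonal(out.weights) == 0.0)


class TestKernelAgainstReference:
    """The compiled training kernel must reproduce the pure-numpy schedule."""

    @pytest.mark.parametrize("variant", ["standard", "a_prime"])
    def test_full_state_agreement_with_external_input(self, variant):
        net = NetworkConfig(n_neurons=5, p_max=0.9, p0=0.05, n_external=3)
        learn = LearningConfig(
            epsilon=0.01, c_eta=1.5, c_kappa=1.0, c_zeta=3.0, tau=5.0, T=100.0,
            variant=variant,
        )
        seed = 7
        stim_cfg = EpisodicSequenceConfig(gap_min=5, gap_max=10)
        trainer = InfomaxTrainer(
            net, learn, seed=seed,
            stimulus_source=EpisodicSequenceStream(stim_cfg, np.random.default_rng(3)),
        )
        ref = ReferenceLearner(trainer.params, net, learn)
        from infomaxnet.network import split_streams

        _, dyn, _ = split_streams(seed, 3)
        stim = EpisodicSequenceStream(stim_cfg, np.random.default_rng(3))
        n = 300
        U = dyn.random((n, net.n_neurons))
        S = stim.next_block(n)
        for t in range(n):
            ref.step(U[t], S[t])
        trainer.run(n, chunk=37)  # deliberately odd chunking
        np.testing.assert_allclose(trainer.params.weights, ref.params.weights, atol=1e-12)
        np.testing.assert_allclose(trainer.params.thresholds, ref.params.thresholds, atol=1e-12)
        np.testing.assert_allclose(trainer.elig_pair, ref.traces.elig_pair, atol=1e-12)
        np.testing.assert_allclose(trainer.avg_lr, ref.traces.avg_log_surprise, atol=1e-12)
        np.testing.assert_allclose(trainer.avg_p, ref.traces.avg_fire_prob, atol=1e-12)
        assert trainer.avg_m[0] == pytest.approx(ref.traces.avg_m, abs=1e-12)


class TestTrain:
    def test_zero_learning_rate_preserves_initialization(self):
        net = NetworkConfig(n_neurons=6, p_max=0.95, p0=0.05)
        learn = LearningConfig(epsilon=0.0, T=1000.0)
        trainer = InfomaxTrainer(net, learn, seed=3)
        before = trainer.params.copy()
        trainer.run(5000)
        np.testing.assert_array_equal(trainer.params.weights, before.weights)
        np.testing.assert_array_equal(trainer.params.thresholds, before.thresholds)

    def test_train_wrapper_returns_metrics(self):
        net = NetworkConfig(n_neurons=5, p_max=0.95, p0=0.05)
        learn = LearningConfig(T=1000.0)
        params, metrics = train(net, learn, n_steps=4000, seed=0, log_every=2000)
        assert len(metrics) == 2
        assert {"step", "i_gauss", "mean_rate", "w_l2"} <= set(metrics[0])

    def test_masked_entries_bit_identical_after_training(self):
        net = NetworkConfig(n_neurons=6, p_max=0.95, p0=0.05)
        learn = LearningConfig(
            epsilon=0.05, T=200.0, plastic_rows=(0, 1, 2), plastic_cols=(0, 1, 2, 3)
        )
        trainer = InfomaxTrainer(net, learn, seed=9)
        before = trainer.params.copy()
        trainer.run(20_000)
        np.testing.assert_array_equal(trainer.params.weights[3:], before.weights[3:])
        np.testing.assert_array_equal(trainer.params.weights[:, 4:], before.weights[:, 4:])
        assert np.any(trainer.params.weights[:3, :4] != before.weights[:3, :4])

    def test_leaky_averages_converge_to_stream_mean(self):
        """<q>_T over a stationary stream approaches the stream mean."""
        net = NetworkConfig(n_neurons=5, p_max=0.95, p0=0.2)
        learn = LearningConfig(epsilon=0.0, T=500.0)
        trainer = InfomaxTrainer(net, learn, seed=4)
        trainer.run(20 * 500)
        # uncoupled-ish network at rate ~p0: avg_m ~ N p0, avg_p ~ p0
        assert trainer.avg_m[0] == pytest.approx(5 * 0.2, rel=0.15)
        np.testing.assert_allclose(trainer.avg_p, 0.2, rtol=0.2)

    def test_resume_from_snapshot_bit_identical(self):
        net = NetworkConfig(n_neurons=5, p_max=0.9, p0=0.05, n_external=3)
        learn = LearningConfig(epsilon=0.02, tau=5.0, T=200.0)
        cfg = EpisodicSequenceConfig(gap_min=5, gap_max=10)

        def fresh():
            return InfomaxTrainer(
                net, learn, seed=21,
                stimulus_source=EpisodicSequenceStream(cfg, np.random.default_rng(2)),
            )

        a = fresh()
        a.run(5000, chunk=1024)
        b = fresh()
        b.run(2000, chunk=777)
        snap = b.snapshot()
        c = fresh()
        c.restore(snap)
        c.run(3000, chunk=1999)
        np.testing.assert_array_equal(a.params.weights, c.params.weights)
        np.testing.assert_array_equal(a.params.thresholds, c.params.thresholds)
        np.testing.assert_array_equal(a.x, c.x)
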