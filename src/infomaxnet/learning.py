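"""Trace-based Infomax plasticity for stochastic binary recurrent networks.

The learning rule performs stochastic gradient ascent on an approximate
information-retention objective

    A = A1 - A2 - A3 - A4,

where A1 sums the logarithms of per-neuron mutual-information terms between
the current state and the previous network state (predictability), A2
penalises pairwise correlations (decorrelation / population sparseness), A3
pins mean firing rates to the target ``p0``, and A4 confines fluctuations of
the membrane input around the reference ``s0``.

Each synapse maintains a leaky eligibility trace <psi_i x_j>_tau of a purely
local score term psi (the derivative of the log firing likelihood with
respect to the membrane input), and the traces are gated at every step by a
single global scalar gamma1 - gamma2 - gamma3 - gamma4 assembled from
population-level signals.  All slow statistics are leaky running averages
with leak constant T >> tau.

The heavy lifting for long runs is done by the compiled kernels in
:mod:`infomaxnet._kernels`; this module also contains a pure-numpy reference
implementation of the identical step schedule (:class:`ReferenceLearner`)
used as an independent cross-check, and exact enumeration oracles for tiny
networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .config import LearningConfig, NetworkConfig
from .network import (
    SpikeRaster,
    SynapticParameters,
    membrane_input,
    split_streams,
    transmission_probability,
    _stable_sigmoid,
)

__all__ = [
    "PenaltyCoefficients",
    "TraceState",
    "GlobalSignals",
    "scale_coefficients",
    "leaky_update",
    "eligibility_psi",
    "surprise_terms",
    "global_signals",
    "apply_update",
    "InfomaxTrainer",
    "train",
    "ReferenceLearner",
    "objective_diagnostics",
    "exact_objective",
    "exact_objective_gradient",
    "TrainingDiverged",
]


class TrainingDiverged(RuntimeError):
    """Raised when weights or thresholds become non-finite during training."""


@dataclass(frozen=True)
class PenaltyCoefficients:
    """Raw objective coefficients (kappa, eta, zeta) plus the reference input."""

    kappa: float
    eta: float
    zeta: float
    s0: float = 0.0


@dataclass
class GlobalSignals:
    """The four population-level modulatory scalars of one time step."""

    gamma1: float
    gamma2: float
    gamma3: float
    gamma4: float

    @property
    def combined(self) -> float:
        return self.gamma1 - self.gamma2 - self.gamma3 - self.gamma4


@dataclass
class TraceState:
    """All leaky running averages the learning rule maintains.

    ``elig_pair[i, j]`` is the eligibility trace <psi_i x_j>_tau over plastic
    pairs, ``elig_post[i]`` the per-neuron trace <psi_i>_tau; ``avg_m``,
    ``avg_fire_prob`` and ``avg_log_surprise`` are the slow (leak T) averages
    of the population count, the per-neuron firing probability and the
    per-neuron log-likelihood ratio.  Everything starts at zero.
    """

    elig_pair: np.ndarray
    elig_post: np.ndarray
    avg_m: float
    avg_fire_prob: np.ndarray
    avg_log_surprise: np.ndarray

    @classmethod
    def zeros(cls, n_rec: int, n_total: int) -> "TraceState":
        return cls(
            elig_pair=np.zeros((n_rec, n_total)),
            elig_post=np.zeros(n_rec),
            avg_m=0.0,
            avg_fire_prob=np.zeros(n_rec),
            avg_log_surprise=np.zeros(n_rec),
        )


def scale_coefficients(
    c_kappa: float, c_eta: float, c_zeta: float, n_neurons: int, p0: float
) -> PenaltyCoefficients:
    """Convert the size- and rate-free coefficients into raw ones.

    kappa = 2 / ((N-1) c_kappa p0^2),  eta = 1 / (c_eta^2 p0^4),
    zeta = 1 / c_zeta^2.  The scaling makes every penalty term O(N) and
    independent of the target rate, so comparable c-values mean comparable
    pressure across experiments.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2 (kappa undefined for N < 2)")
    for name, v in (("c_kappa", c_kappa), ("c_eta", c_eta), ("c_zeta", c_zeta), ("p0", p0)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    kappa = 2.0 / ((n_neurons - 1) * c_kappa * p0 ** 2)
    eta = 1.0 / (c_eta ** 2 * p0 ** 4)
    zeta = 1.0 / c_zeta ** 2
    return PenaltyCoefficients(kappa=kappa, eta=eta, zeta=zeta)


def leaky_update(avg, new_value, leak: float):
    """One step of leaky integration: (1/leak) new + (1 - 1/leak) avg."""
    if leak < 1:
        raise ValueError(f"leak must be >= 1, got {leak}")
    return new_value / leak + (1.0 - 1.0 / leak) * np.asarray(avg)


def eligibility_psi(s_post, fired_next, p_max: float):
    """Score term psi: derivative of log p(x^{t+1} | s) with respect to s.

    Equals ``1 - sigma(s)`` when the neuron fired at the next step and
    ``-p_max sigma(s)(1 - sigma(s)) / (1 - p_max sigma(s))`` when it stayed
    quiescent.  Positive exactly when the neuron fired, and averages to zero
    under the model's own firing probability (score-function identity).
    """
    s_post = np.asarray(s_post, dtype=np.float64)
    fired = np.asarray(fired_next)
    sig = _stable_sigmoid(np.atleast_1d(s_post))
    sig = sig.reshape(s_post.shape) if s_post.shape else sig[0]
    denom = 1.0 - p_max * sig
    if np.any((np.asarray(fired) == 0) & (np.asarray(denom) <= 0.0)):
        raise FloatingPointError(
            "psi undefined: p_max * sigma(s) reached 1 for a quiescent neuron"
        )
    psi_fire = 1.0 - sig
    psi_quiet = -p_max * sig * (1.0 - sig) / denom
    return np.where(fired == 1, psi_fire, psi_quiet) if np.ndim(fired) else (
        psi_fire if fired == 1 else psi_quiet
    )


def surprise_terms(
    x_now: np.ndarray,
    s_prev: np.ndarray,
    traces: TraceState,
    p_max: float,
    delta: float,
):
    """Per-neuron log-likelihood ratio log[p(x_i^t | x^{t-1}) / Z_i] and Z.

    ``p`` is the model's transition probability evaluated at the input that
    generated ``x_now``; ``Z_i`` is the slow estimate of the marginal firing
    probability (or its complement for quiescent neurons), floored at
    ``delta`` to remove the cold-start singularity.
    """
    x_now = np.asarray(x_now)
    p = transmission_probability(s_prev, p_max)
    p_obs = np.where(x_now == 1, p, 1.0 - p)
    Z = np.where(x_now == 1, traces.avg_fire_prob, 1.0 - traces.avg_fire_prob)
    Z = np.maximum(Z, delta)
    p_obs = np.maximum(p_obs, 1e-300)
    return np.log(p_obs / Z), Z


def global_signals(
    x_now: np.ndarray,
    s_now: np.ndarray,
    s_prev: Optional[np.ndarray],
    traces: TraceState,
    coeffs: PenaltyCoefficients,
    net: NetworkConfig,
    learn: LearningConfig,
) -> GlobalSignals:
    """Assemble the four global modulatory scalars for the current step.

    gamma1 rewards transitions that are better predicted than the marginal
    (normalised per neuron by the slow average of the same quantity, or by
    the population sum in the ``a_prime`` variant); gamma2 penalises
    population synchrony; gamma3 penalises rate deviations from p0; gamma4
    penalises large membrane-input fluctuations.  All sums run only over the
    configured scope.
    """
    n_rec = net.n_neurons
    scope = learn.scope_mask(n_rec)
    x = np.asarray(x_now)[:n_rec]
    delta = learn.delta
    if s_prev is None:
        lr = np.zeros(n_rec)
    else:
        lr, _ = surprise_terms(x, s_prev, traces, net.p_max, delta)
    if learn.variant == "a_prime":
        den = np.sum(traces.avg_log_surprise[scope])
        g1 = np.sum(lr[scope]) / max(den, delta)
    else:
        den = np.maximum(traces.avg_log_surprise[scope], delta)
        g1 = float(np.sum(lr[scope] / den))
    m = float(np.sum(x[scope]))
    g2 = coeffs.kappa * (0.5 * m * (m - 1.0) - (traces.avg_m - net.p0) * m)
    g3 = coeffs.eta * float(np.sum((traces.avg_fire_prob[scope] - net.p0) * x[scope]))
    ds = s_now[scope] - net.s0
    g4 = 0.5 * coeffs.zeta * float(np.sum(ds * ds))
    return GlobalSignals(gamma1=float(g1), gamma2=float(g2), gamma3=float(g3), gamma4=float(g4))


def apply_update(
    params: SynapticParameters,
    traces: TraceState,
    signals: GlobalSignals,
    s_now: np.ndarray,
    x_now: np.ndarray,
    coeffs: PenaltyCoefficients,
    net: NetworkConfig,
    learn: LearningConfig,
) -> SynapticParameters:
    """One parameter update; returns a new :class:`SynapticParameters`.

    dw_ij = eps (tau/T) (g1-g2-g3-g4) <psi_i x_j>_tau - eps (zeta/T)(s_i-s0) x_j
    dh_i  = -eps (tau/T) (g1-g2-g3-g4) <psi_i>_tau  + eps (zeta/T)(s_i-s0)

    Only entries selected by the plastic row/column masks change, and the
    recurrent diagonal is never touched.
    """
    n_rec, n_tot = params.n_rec, params.n_total
    rows = learn.row_mask(n_rec)
    cols = learn.col_mask(n_tot)
    c1 = learn.epsilon * learn.tau / learn.T * signals.combined
    c2 = learn.epsilon * coeffs.zeta / learn.T
    ds = s_now - net.s0
    x = np.asarray(x_now, dtype=np.float64)

    dW = c1 * traces.elig_pair - c2 * np.outer(ds, x)
    dW[~rows, :] = 0.0
    dW[:, ~cols] = 0.0
    np.fill_diagonal(dW[:, :n_rec], 0.0)
    dh = -c1 * traces.elig_post + c2 * ds
    dh = np.where(rows, dh, 0.0)

    new_w = params.weights + dW
    new_h = params.thresholds + dh
    if not (np.all(np.isfinite(new_w)) and np.all(np.isfinite(new_h))):
        raise TrainingDiverged("non-finite parameter update")
    return SynapticParameters(new_w, new_h)


class ReferenceLearner:
    """Pure-numpy implementation of the canonical step schedule.

    Composes the module-level operations exactly as the compiled kernel does;
    it exists as a readable specification of the schedule and as the oracle
    the kernel is tested against.  Usable only for short runs.
    """

    def __init__(
        self,
        params: SynapticParameters,
        net: NetworkConfig,
        learn: LearningConfig,
        x0: Optional[np.ndarray] = None,
    ):
        self.params = params.copy()
        self.net = net
        self.learn = learn
        self.coeffs = scale_coefficients(
            learn.c_kappa, learn.c_eta, learn.c_zeta, net.n_neurons, net.p0
        )
        self.traces = TraceState.zeros(net.n_neurons, net.n_total)
        self.x = (
            np.zeros(net.n_total, dtype=np.uint8) if x0 is None else np.asarray(x0, dtype=np.uint8).copy()
        )
        self.s_prev: Optional[np.ndarray] = None
        self.t = 0

    def step(self, u_row: np.ndarray, stim_row: Optional[np.ndarray] = None, apply_updates: bool = True):
        net, learn, coeffs = self.net, self.learn, self.coeffs
        n_rec = net.n_neurons
        x_t = self.x.copy()
        s_now = membrane_input(x_t, self.params)
        signals = global_signals(x_t, s_now, self.s_prev, self.traces, coeffs, net, learn)
        if apply_updates:
            self.params = apply_update(
                self.params, self.traces, signals, s_now, x_t, coeffs, net, learn
            )
        # sample x^{t+1}
        p = transmission_probability(s_now, net.p_max)
        x_next = np.empty(net.n_total, dtype=np.uint8)
        x_next[:n_rec] = u_row < p
        if net.n_external:
            x_next[n_rec:] = stim_row
        # fold (psi^t, x^t) into the eligibility traces
        psi = eligibility_psi(s_now, x_next[:n_rec], net.p_max)
        self.traces.elig_pair = leaky_update(
            self.traces.elig_pair, np.outer(psi, x_t.astype(np.float64)), learn.tau
        )
        self.traces.elig_post = leaky_update(self.traces.elig_post, psi, learn.tau)
        # fold step-t quantities into the slow averages
        scope = learn.scope_mask(n_rec)
        m = float(np.sum(x_t[:n_rec][scope]))
        if self.s_prev is None:
            lr = np.zeros(n_rec)
        else:
            lr, _ = surprise_terms(x_t[:n_rec], self.s_prev, self.traces, net.p_max, learn.delta)
        self.traces.avg_m = float(leaky_update(self.traces.avg_m, m, learn.T))
        self.traces.avg_fire_prob = leaky_update(
            self.traces.avg_fire_prob, transmission_probability(s_now, net.p_max), learn.T
        )
        self.traces.avg_log_surprise = leaky_update(self.traces.avg_log_surprise, lr, learn.T)
        self.s_prev = s_now
        self.x = x_next
        self.t += 1
        return signals


class InfomaxTrainer:
    """Chunked, compiled driver of the learning rule.

    Owns the parameters, the trace state and three independent RNG streams
    (initialization, dynamics, stimulus) deterministically derived from one
    root seed, so runs are bit-reproducible and resumable.
    """

    def __init__(
        self,
        net: NetworkConfig,
        learn: LearningConfig,
        seed: int = 0,
        params: Optional[SynapticParameters] = None,
        stimulus_source=None,
    ):
        from .network import initialize_network

        self.net = net
        self.learn = learn
        self.seed = seed
        init_rng, self.dyn_rng, self.stim_rng = split_streams(seed, 3)
        self.params = params.copy() if params is not None else initialize_network(net, init_rng)
        if self.params.n_ext != net.n_external or self.params.n_rec != net.n_neurons:
            raise ValueError("parameter shapes do not match the network config")
        self.stimulus_source = stimulus_source
        if net.n_external and stimulus_source is None:
            raise ValueError("network has external neurons but no stimulus source")
        self.coeffs = scale_coefficients(
            learn.c_kappa, learn.c_eta, learn.c_zeta, net.n_neurons, net.p0
        )
        n_rec, n_tot = net.n_neurons, net.n_total
        self.x = np.zeros(n_tot, dtype=np.uint8)
        self.s_prev = np.zeros(n_rec)
        self.elig_pair = np.zeros((n_rec, n_tot))
        self.elig_post = np.zeros(n_rec)
        self.avg_m = np.zeros(1)
        self.avg_p = np.zeros(n_rec)
        self.avg_lr = np.zeros(n_rec)
        self.t = 0
        self._row_mask = learn.row_mask(n_rec)
        self._col_mask = learn.col_mask(n_tot)
        self._scope_mask = learn.scope_mask(n_rec)
        self._buf: Optional[np.ndarray] = None  # rolling raster window

    @property
    def traces(self) -> TraceState:
        return TraceState(
            elig_pair=self.elig_pair.copy(),
            elig_post=self.elig_post.copy(),
            avg_m=float(self.avg_m[0]),
            avg_fire_prob=self.avg_p.copy(),
            avg_log_surprise=self.avg_lr.copy(),
        )

    def _stim_block(self, b: int) -> np.ndarray:
        if self.net.n_external == 0:
            return np.zeros((b, 0), dtype=np.uint8)
        block = np.asarray(self.stimulus_source.next_block(b), dtype=np.uint8)
        if block.shape != (b, self.net.n_external):
            raise ValueError("stimulus source yielded a block of the wrong shape")
        return block

    def run(
        self,
        n_steps: int,
        chunk: int = 100_000,
        log_every: Optional[int] = None,
        window: int = 50_000,
        callbacks: Optional[list[Callable]] = None,
        apply_updates: bool = True,
        accumulate_gradient: bool = False,
        warmup: int = 0,
    ):
        """Run ``n_steps`` learning steps; returns a list of metric records.

        When ``log_every`` is set, a metric record {step, i_gauss, mean_rate,
        gamma means, weight norms} is computed every ``log_every`` steps from
        a rolling raster of the most recent ``window`` steps.  With
        ``accumulate_gradient`` the per-step updates are summed (for frozen
        parameters) into :attr:`grad_W` / :attr:`grad_h` from global step
        ``warmup`` on.
        """
        from ._kernels import train_chunk

        if n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {n_steps}")
        net, learn = self.net, self.learn
        n_rec, n_tot = net.n_neurons, net.n_total
        if accumulate_gradient:
            self.grad_W = np.zeros((n_rec, n_tot))
            self.grad_h = np.zeros(n_rec)
            self.n_accumulated = 0
        else:
            self.grad_W = np.zeros((0, 0))
            self.grad_h = np.zeros(0)
        if log_every is not None:
            keep = min(window, n_steps)
            self._buf = np.zeros((keep, n_tot), dtype=np.uint8)
            self._buf_fill = 0
        metrics: list[dict] = []
        acc = np.zeros(8)
        done = 0
        next_log = log_every if log_every is not None else None
        while done < n_steps:
            b = min(chunk, n_steps - done)
            if next_log is not None:
                b = min(b, next_log - done)
            u = self.dyn_rng.random((b, n_rec))
            stim = self._stim_block(b)
            record = self._buf is not None
            out_spikes = np.empty((b, n_tot), dtype=np.uint8) if record else np.empty((0, 0), dtype=np.uint8)
            train_chunk(
                self.params.weights, self.params.thresholds, self.x, self.s_prev,
                self.elig_pair, self.elig_post, self.avg_m, self.avg_p, self.avg_lr,
                u, stim,
                net.p_max, net.p0, net.s0, learn.epsilon,
                self.coeffs.kappa, self.coeffs.eta, self.coeffs.zeta,
                learn.tau, learn.T, learn.delta,
                self._row_mask, self._col_mask, self._scope_mask,
                learn.variant == "a_prime", apply_updates,
                self.grad_W, self.grad_h, accumulate_gradient, warmup,
                self.t,
                out_spikes, np.empty((0, 0)), record, False,
                acc,
            )
            if not (np.all(np.isfinite(self.params.weights)) and np.all(np.isfinite(self.params.thresholds))):
                raise TrainingDiverged(
                    f"non-finite parameters at step {self.t + b}; last finite "
                    "snapshot is the trainer state before this run"
                )
            if record:
                self._roll_buffer(out_spikes)
            self.t += b
            done += b
            if next_log is not None and done >= next_log:
                rec = self._metric_record(acc)
                metrics.append(rec)
                for cb in callbacks or []:
                    cb(self, rec)
                acc = np.zeros(8)
                next_log = min(next_log + log_every, n_steps)
                if next_log <= done:
                    next_log = done + log_every
        if accumulate_gradient:
            self.n_accumulated = int(acc[7]) if acc[7] else getattr(self, "n_accumulated", 0)
        return metrics

    def _roll_buffer(self, out_spikes: np.ndarray) -> None:
        buf = self._buf
        keep = buf.shape[0]
        b = out_spikes.shape[0]
        if b >= keep:
            buf[:] = out_spikes[-keep:]
            self._buf_fill = keep
        else:
            buf[: keep - b] = buf[b:]
            buf[keep - b :] = out_spikes
            self._buf_fill = min(keep, self._buf_fill + b)

    def recent_raster(self) -> SpikeRaster:
        """Raster of the most recent recorded window (requires log_every)."""
        if self._buf is None or self._buf_fill == 0:
            raise RuntimeError("no rolling raster: run() with log_every set")
        return SpikeRaster(spikes=self._buf[-self._buf_fill :].copy())

    def _metric_record(self, acc: np.ndarray) -> dict:
        from .analysis import i_gauss

        n = max(acc[6], 1.0)
        raster = self.recent_raster()
        rec_spikes = raster.spikes[:, : self.net.n_neurons]
        try:
            ig = float(i_gauss(SpikeRaster(spikes=rec_spikes)))
        except (ValueError, np.linalg.LinAlgError):
            ig = float("nan")
        w = self.params.weights
        return {
            "step": int(self.t),
            "i_gauss": ig,
            "mean_rate": float(rec_spikes.mean()),
            "gamma1_mean": float(acc[0] / n),
            "gamma2_mean": float(acc[1] / n),
            "gamma3_mean": float(acc[2] / n),
            "gamma4_mean": float(acc[3] / n),
            "combined_mean": float(acc[4] / n),
            "m_mean": float(acc[5] / n),
            "w_l2": float(np.sqrt(np.mean(w * w))),
            "w_max": float(np.abs(w).max()),
        }

    # -- snapshot / resume ---------------------------------------------------

    def snapshot(self) -> dict:
        """Everything needed to resume bit-for-bit: arrays, counters, RNG states."""
        snap = {
            "weights": self.params.weights.copy(),
            "thresholds": self.params.thresholds.copy(),
            "x": self.x.copy(),
            "s_prev": self.s_prev.copy(),
            "elig_pair": self.elig_pair.copy(),
            "elig_post": self.elig_post.copy(),
            "avg_m": self.avg_m.copy(),
            "avg_p": self.avg_p.copy(),
            "avg_lr": self.avg_lr.copy(),
            "t": self.t,
            "dyn_rng_state": self.dyn_rng.bit_generator.state,
        }
        if self.stimulus_source is not None and hasattr(self.stimulus_source, "get_state"):
            snap["stim_state"] = self.stimulus_source.get_state()
        return snap

    def restore(self, snap: dict) -> None:
        self.params = SynapticParameters(snap["weights"].copy(), snap["thresholds"].copy())
        self.x = snap["x"].copy()
        self.s_prev = snap["s_prev"].copy()
        self.elig_pair = snap["elig_pair"].copy()
        self.elig_post = snap["elig_post"].copy()
        self.avg_m = snap["avg_m"].copy()
        self.avg_p = snap["avg_p"].copy()
        self.avg_lr = snap["avg_lr"].copy()
        self.t = int(snap["t"])
        self.dyn_rng.bit_generator.state = snap["dyn_rng_state"]
        if "stim_state" in snap and self.stimulus_source is not None:
            self.stimulus_source.set_state(snap["stim_state"])


def train(
    net: NetworkConfig,
    learn: LearningConfig,
    stimulus_source=None,
    n_steps: int = 1_000_000,
    seed: int = 0,
    callbacks: Optional[list[Callable]] = None,
    log_every: Optional[int] = None,
    params: Optional[SynapticParameters] = None,
):
    """Train a network from scratch; returns (parameters, metrics log)."""
    trainer = InfomaxTrainer(net, learn, seed=seed, params=params, stimulus_source=stimulus_source)
    metrics = trainer.run(n_steps, log_every=log_every, callbacks=callbacks)
    return trainer.params, metrics


# -- objective estimation and enumeration oracles ----------------------------


def _binary_entropy_nats(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=np.float64), 1e-300, 1.0)
    q = np.clip(1.0 - p, 1e-300, 1.0)
    return -(p * np.log(p) + q * np.log(q))


def objective_diagnostics(
    raster: SpikeRaster,
    coeffs: PenaltyCoefficients,
    net: NetworkConfig,
    exact_params: Optional[SynapticParameters] = None,
) -> dict:
    """Estimate the objective terms A1..A4 (natural log) from a recorded run.

    Requires the raster's membrane-input history: the per-neuron conditional
    firing probability at each step is then known exactly, so the per-neuron
    information I[x_i^t; x^{t-1}] is estimated as the binary entropy of the
    empirical rate minus the mean conditional entropy.  With ``exact_params``
    given and N <= 12, A1 is instead computed by full state enumeration of
    the stationary chain.
    """
    if raster.inputs is None:
        raise ValueError("objective_diagnostics requires a raster with recorded inputs")
    n_rec = net.n_neurons
    spikes = raster.spikes[:, :n_rec].astype(np.float64)
    s_hist = raster.inputs
    rates = spikes.mean(axis=0)
    if exact_params is not None:
        if n_rec > 12:
            raise ValueError("exact mode limited to N <= 12")
        info = _enumerated_per_neuron_information(exact_params, net)
    else:
        p_cond = transmission_probability(s_hist.ravel(), net.p_max).reshape(s_hist.shape)
        info = _binary_entropy_nats(rates) - _binary_entropy_nats(p_cond).mean(axis=0)
    a1 = float(np.sum(np.log(np.maximum(info, 1e-12))))
    cov = np.cov(spikes.T, bias=True) if n_rec > 1 else np.zeros((1, 1))
    a2 = float(coeffs.kappa * np.sum(np.triu(cov, k=1)))
    a3 = float(0.5 * coeffs.eta * np.sum((rates - net.p0) ** 2))
    ds = s_hist - net.s0
    a4 = float(0.5 * coeffs.zeta * np.sum(np.mean(ds * ds, axis=0)))
    return {"A1": a1, "A2": a2, "A3": a3, "A4": a4, "A": a1 - a2 - a3 - a4, "info": info}


def _all_states(n: int) -> np.ndarray:
    idx = np.arange(2 ** n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(np.float64)


def _transition_matrix(params: SynapticParameters, net: NetworkConfig) -> tuple[np.ndarray, np.ndarray]:
    """Dense transition matrix P[a, b] over all 2^N states, and the per-state
    firing probabilities p[a, i].  Recurrent-only networks."""
    n = net.n_neurons
    if params.n_ext:
        raise ValueError("enumeration supports recurrent-only networks")
    if n > 12:
        raise ValueError("enumeration limited to N <= 12")
    X = _all_states(n)
    S = X @ params.weights.T - params.thresholds
    P_fire = transmission_probability(S.ravel(), net.p_max).reshape(S.shape)
    # P[a, b] = prod_i p_fire[a, i]^x_b_i (1 - p_fire[a, i])^(1 - x_b_i)
    logp = np.log(np.clip(P_fire, 1e-300, 1.0))
    logq = np.log(np.clip(1.0 - P_fire, 1e-300, 1.0))
    P = np.exp(logp @ X.T + logq @ (1.0 - X.T))
    P /= P.sum(axis=1, keepdims=True)
    return P, P_fire


def _stationary(P: np.ndarray) -> np.ndarray:
    n = P.shape[0]
    A = P.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.maximum(pi, 0.0)
    s = pi.sum()
    if s <= 0 or not np.all(np.isfinite(pi)):
        raise RuntimeError("stationary distribution solve failed")
    return pi / s


def _enumerated_per_neuron_information(params: SynapticParameters, net: NetworkConfig) -> np.ndarray:
    """Exact I[x_i^t; x^{t-1}] (nats) per neuron via full enumeration."""
    P, P_fire = _transition_matrix(params, net)
    pi = _stationary(P)
    marg = pi @ P_fire  # stationary firing probability per neuron
    info = _binary_entropy_nats(marg) - pi @ _binary_entropy_nats(P_fire)
    return np.maximum(info, 0.0)


def exact_objective(
    params: SynapticParameters, net: NetworkConfig, coeffs: PenaltyCoefficients
) -> float:
    """Exact objective A (natural log) for a tiny recurrent-only network,
    with all expectations taken under the enumerated stationary distribution."""
    P, P_fire = _transition_matrix(params, net)
    pi = _stationary(P)
    X = _all_states(net.n_neurons)
    info = _binary_entropy_nats(pi @ P_fire) - pi @ _binary_entropy_nats(P_fire)
    a1 = float(np.sum(np.log(np.maximum(info, 1e-300))))
    rates = pi @ X
    second = (X * pi[:, None]).T @ X
    cov = second - np.outer(rates, rates)
    a2 = float(coeffs.kappa * np.sum(np.triu(cov, k=1)))
    a3 = float(0.5 * coeffs.eta * np.sum((rates - net.p0) ** 2))
    S = X @ params.weights.T - params.thresholds
    ds2 = (S - net.s0) ** 2
    a4 = float(0.5 * coeffs.zeta * np.sum(pi @ ds2))
    return a1 - a2 - a3 - a4


def exact_objective_gradient(
    params: SynapticParameters,
    net: NetworkConfig,
    coeffs: PenaltyCoefficients,
    fd_eps: float = 1e-5,
):
    """Central-finite-difference gradient of the exact objective with respect
    to every off-diagonal weight and every threshold."""
    n = net.n_neurons
    gW = np.zeros_like(params.weights)
    gh = np.zeros_like(params.thresholds)
    for i in range(n):
        for j in range(params.n_total):
            if j == i:
                continue
            p_plus = params.copy()
            p_plus.weights[i, j] += fd_eps
            p_minus = params.copy()
            p_minus.weights[i, j] -= fd_eps
            gW[i, j] = (
                exact_objective(p_plus, net, coeffs) - exact_objective(p_minus, net, coeffs)
            ) / (2 * fd_eps)
        p_plus = params.copy()
        p_plus.thresholds[i] += fd_eps
        p_minus = params.copy()
        p_minus.thresholds[i] -= fd_eps
        gh[i] = (
            exact_objective(p_plus, net, coeffs) - exact_objective(p_minus, net, coeffs)
        ) / (2 * fd_eps)
    return gW, gh
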