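"""Stochastic binary network dynamics.

The network is a vector ``x^t`` of N binary neurons (plus optional external
input neurons appended at trailing indices).  Each recurrent neuron i receives
a membrane input ``s_i = sum_{j != i} w_ij x_j - h_i`` and fires at the next
step independently with probability ``p_max * sigma(s_i)``, where ``sigma`` is
the logistic function.  External neurons are never sampled; their states are
copied from a stimulus stream.

Also provides the leaky integrate-and-fire f-I curve that motivates reading
``s`` as an input current and the sigmoid as a firing-rate transfer function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import NetworkConfig

__all__ = [
    "SynapticParameters",
    "NetworkState",
    "SpikeRaster",
    "membrane_input",
    "transmission_probability",
    "initialize_network",
    "step_network",
    "simulate",
    "lif_fi_curve",
    "split_streams",
]


def split_streams(seed: int, n: int = 3) -> list[np.random.Generator]:
    """Deterministically split one root seed into independent RNG streams.

    Streams are ordered (initialization, dynamics, stimulus, ...); consuming
    draws from one stream never perturbs another, so e.g. turning recording on
    or off cannot change a trajectory.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass
class SynapticParameters:
    """Learnable weight matrix and threshold vector of one network.

    ``weights`` has one row per postsynaptic recurrent neuron and one column
    per presynaptic neuron (recurrent first, then external).  The diagonal of
    the recurrent block is identically zero: no self-connections.
    """

    weights: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        n_rec = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] < n_rec:
            raise ValueError(
                f"weights must be (n_rec, n_rec + n_ext), got {self.weights.shape}"
            )
        if self.thresholds.shape != (n_rec,):
            raise ValueError(
                f"thresholds must have shape ({n_rec},), got {self.thresholds.shape}"
            )
        if not np.all(np.isfinite(self.weights)) or not np.all(np.isfinite(self.thresholds)):
            raise ValueError("non-finite synaptic parameters")
        diag = np.diagonal(self.weights[:, :n_rec])
        if np.any(diag != 0.0):
            raise ValueError("recurrent diagonal must be exactly zero (no self-connections)")

    @property
    def n_rec(self) -> int:
        return self.weights.shape[0]

    @property
    def n_ext(self) -> int:
        return self.weights.shape[1] - self.weights.shape[0]

    @property
    def n_total(self) -> int:
        return self.weights.shape[1]

    def copy(self) -> "SynapticParameters":
        return SynapticParameters(self.weights.copy(), self.thresholds.copy())


@dataclass
class NetworkState:
    """Instantaneous state: firing vector x, membrane inputs s, time index t.

    ``s`` is the membrane input computed from the *previous* firing vector —
    the input that generated ``x`` — so that the learning rule can evaluate
    the transition likelihood p(x^t | x^{t-1}) without recomputation.
    """

    x: np.ndarray
    s: Optional[np.ndarray] = None
    t: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.uint8)
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("state entries must be binary")
        if self.s is not None:
            self.s = np.asarray(self.s, dtype=np.float64)


@dataclass
class SpikeRaster:
    """A time-by-neuron binary firing history, optionally with input history.

    ``spikes[t, i]`` is 1 when neuron i fired at step ``t0 + t``.  When
    present, ``inputs[t]`` holds the membrane inputs that generated row t
    (recurrent neurons only), aligned row-for-row with ``spikes``.
    """

    spikes: np.ndarray
    inputs: Optional[np.ndarray] = None
    t0: int = 0

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        if self.spikes.dtype != np.uint8:
            if not np.isin(self.spikes, (0, 1)).all():
                raise ValueError("spike entries must be binary")
            self.spikes = self.spikes.astype(np.uint8)
        if self.inputs is not None:
            self.inputs = np.asarray(self.inputs, dtype=np.float64)
            if self.inputs.shape[0] != self.spikes.shape[0]:
                raise ValueError("inputs must align row-for-row with spikes")

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[1]


def _stable_sigmoid(s: np.ndarray) -> np.ndarray:
    # evaluate the logistic in a branch that never overflows exp
    out = np.empty_like(s, dtype=np.float64)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out


def membrane_input(x: np.ndarray, params: SynapticParameters) -> np.ndarray:
    """Membrane input ``s_i = sum_{j != i} w_ij x_j - h_i`` for every
    recurrent neuron, given the current firing vector of all neurons."""
    x = np.asarray(x)
    if x.shape != (params.n_total,):
        raise ValueError(
            f"firing vector has shape {x.shape}, expected ({params.n_total},)"
        )
    return params.weights @ x.astype(np.float64) - params.thresholds


def transmission_probability(s: np.ndarray, p_max: float) -> np.ndarray:
    """Firing probability ``p_max * sigma(s)`` elementwise; bounded by p_max."""
    if not (0.0 < p_max <= 1.0):
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite membrane input")
    return p_max * _stable_sigmoid(s)


def initialize_network(config: NetworkConfig, rng: np.random.Generator) -> SynapticParameters:
    """Weak random initial connectivity: ``w ~ U[-0.1, 0.1]`` with a zeroed
    recurrent diagonal, and every threshold at ``log((p_max - p0)/p0)`` so
    that neurons initially fire near-independently at rate p0."""
    n, m = config.n_neurons, config.n_total
    w = rng.uniform(-0.1, 0.1, size=(n, m))
    np.fill_diagonal(w[:, :n], 0.0)
    h = np.full(n, config.h_init, dtype=np.float64)
    return SynapticParameters(w, h)


def step_network(
    state: NetworkState,
    params: SynapticParameters,
    stimulus: Optional[np.ndarray],
    rng: np.random.Generator,
    p_max: float,
) -> NetworkState:
    """Advance the network one step.

    Samples each recurrent entry of the next firing vector independently with
    probability ``p_max * sigma(s_i)`` (one uniform draw per recurrent neuron,
    in index order), copies external entries from ``stimulus``, and returns a
    state carrying the membrane input ``s`` that generated it.
    """
    n_rec, n_ext = params.n_rec, params.n_ext
    if n_ext:
        stimulus = np.asarray(stimulus)
        if stimulus.shape != (n_ext,):
            raise ValueError(f"stimulus must have shape ({n_ext},), got {stimulus.shape}")
        if not np.isin(stimulus, (0, 1)).all():
            raise ValueError("stimulus entries must be binary")
    elif stimulus is not None and np.size(stimulus):
        raise ValueError("network has no external neurons but stimulus given")
    s = membrane_input(state.x, params)
    p = transmission_probability(s, p_max)
    u = rng.random(n_rec)
    x_next = np.empty(params.n_total, dtype=np.uint8)
    x_next[:n_rec] = u < p
    if n_ext:
        x_next[n_rec:] = stimulus
    return NetworkState(x=x_next, s=s, t=state.t + 1)


def simulate(
    params: SynapticParameters,
    n_steps: int,
    stimulus_source=None,
    rng: Optional[np.random.Generator] = None,
    p_max: float = 0.95,
    record_inputs: bool = False,
    x0: Optional[np.ndarray] = None,
    use_kernel: bool = True,
) -> SpikeRaster:
    """Simulate ``n_steps`` steps with frozen parameters and return the raster.

    Row t of the raster is the firing vector x^{t+1} sampled from the state at
    step t (the initial state itself is not recorded).  With
    ``record_inputs=True`` each row is accompanied by the membrane input that
    generated it.  The stimulus source is consulted exactly once per step.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if rng is None:
        rng = np.random.default_rng()
    n_rec, n_ext, n_tot = params.n_rec, params.n_ext, params.n_total
    if x0 is None:
        x = np.zeros(n_tot, dtype=np.uint8)
    else:
        x = np.asarray(x0, dtype=np.uint8).copy()
    if n_ext and stimulus_source is None:
        raise ValueError("network has external neurons but no stimulus source")

    if use_kernel:
        from ._kernels import simulate_chunk

        spikes = np.empty((n_steps, n_tot), dtype=np.uint8)
        inputs = np.empty((n_steps, n_rec), dtype=np.float64) if record_inputs else np.empty((0, 0))
        chunk = 200_000
        done = 0
        while done < n_steps:
            b = min(chunk, n_steps - done)
            u = rng.random((b, n_rec))
            if n_ext:
                stim = _draw_stimulus_block(stimulus_source, b, n_ext)
            else:
                stim = np.zeros((b, 0), dtype=np.uint8)
            simulate_chunk(
                params.weights, params.thresholds, x, u, stim, p_max,
                spikes[done : done + b],
                inputs[done : done + b] if record_inputs else np.empty((0, 0)),
                record_inputs,
            )
            done += b
        return SpikeRaster(spikes=spikes, inputs=inputs if record_inputs else None)

    # pure-python reference path
    state = NetworkState(x=x, t=0)
    spikes = np.empty((n_steps, n_tot), dtype=np.uint8)
    inputs = np.empty((n_steps, n_rec), dtype=np.float64) if record_inputs else None
    for t in range(n_steps):
        stim = _draw_stimulus_block(stimulus_source, 1, n_ext)[0] if n_ext else None
        state = step_network(state, params, stim, rng, p_max)
        spikes[t] = state.x
        if record_inputs:
            inputs[t] = state.s
    return SpikeRaster(spikes=spikes, inputs=inputs)


def _draw_stimulus_block(stimulus_source, n: int, n_ext: int) -> np.ndarray:
    block = stimulus_source.next_block(n)
    block = np.asarray(block, dtype=np.uint8)
    if block.shape != (n, n_ext):
        raise ValueError(
            f"stimulus source yielded shape {block.shape}, expected ({n}, {n_ext})"
        )
    return block


def lif_fi_curve(
    currents,
    tau_m: float = 15.0,
    theta: float = -50.0,
    v_rest: float = -70.0,
    noise_coef: float = 3.0,
    t_ref: float = 1.0,
    dt: float = 0.01,
    duration: float = 20000.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """f-I curve of a leaky integrate-and-fire neuron (Euler-Maruyama).

    Integrates ``tau_m dV = (-V + V_rest + I) dt + D dxi`` with reset to
    ``V_rest`` and an absolute refractory hold of ``t_ref`` ms after each
    threshold crossing.  Returns one firing frequency (cycles/ms) per input
    current.  With noise the curve is a saturating sigmoid in I, which is the
    continuous-time motivation for the discrete model's logistic transfer.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt >= tau_m:
        raise ValueError(f"dt={dt} >= tau_m={tau_m}: unstable integration")
    if rng is None:
        rng = np.random.default_rng()
    from ._kernels import lif_run

    currents = np.atleast_1d(np.asarray(currents, dtype=np.float64))
    n_steps = int(round(duration / dt))
    freqs = np.empty_like(currents)
    for k, current in enumerate(currents):
        if noise_coef == 0.0:
            noise = np.zeros(0)
        else:
            noise = rng.standard_normal(n_steps)
        n_spikes = lif_run(
            current, tau_m, theta, v_rest, noise_coef, t_ref, dt, n_steps, noise
        )
        freqs[k] = n_spikes / duration
    return freqs
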