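"""Spike-train and connectivity readouts.

Everything the experiments report: the Gaussian mutual-information estimate
I_gauss, exact mutual information for tiny networks by state enumeration,
avalanche (burst) statistics with a log-log slope fit, censuses of exact
firing patterns and pattern sequences, autocorrelograms, coefficients of
variation of inter-spike intervals, weight-shuffle controls, spike-triggered
averages with the fixed gray-level rescaling, and breadth-first extraction of
strong poly-synaptic transmission chains.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import NetworkConfig
from .network import SpikeRaster, SynapticParameters

__all__ = [
    "BurstCatalog",
    "SequenceCensus",
    "ReceptiveFieldMap",
    "ChainGraph",
    "i_gauss",
    "exact_mutual_information",
    "detect_bursts",
    "fit_power_law_slope",
    "count_patterns_and_sequences",
    "autocorrelogram",
    "cv_isi",
    "shuffle_weights",
    "spike_triggered_average",
    "extract_strong_chains",
]


# -- mutual information ------------------------------------------------------


def i_gauss(raster: SpikeRaster, warn_short: bool = True) -> float:
    """Gaussian estimate of the information one step retains about the last.

    I_gauss = log2 |C| - (1/2) log2 |D|, with C the covariance matrix of x^t
    and D the covariance of the concatenated (x^t, x^{t-1}).  Exact when both
    distributions are Gaussian; zero in expectation for temporally
    independent data.  Neurons with zero variance in the window are dropped
    (their determinant contribution is degenerate and carries no
    information).
    """
    spikes = raster.spikes.astype(np.float64)
    T, N = spikes.shape
    if T < 3:
        raise ValueError("raster too short for covariance estimation")
    if warn_short and T < 10 * N:
        import warnings

        warnings.warn(f"raster length {T} < 10 N = {10 * N}; I_gauss will be noisy", stacklevel=2)
    live = spikes.std(axis=0) > 0
    spikes = spikes[:, live]
    if spikes.shape[1] == 0:
        return 0.0
    C = np.cov(spikes.T, bias=True)
    joint = np.concatenate([spikes[1:], spikes[:-1]], axis=1)
    D = np.cov(joint.T, bias=True)
    sign_c, logdet_c = np.linalg.slogdet(np.atleast_2d(C))
    sign_d, logdet_d = np.linalg.slogdet(np.atleast_2d(D))
    if sign_c <= 0 or sign_d <= 0:
        raise np.linalg.LinAlgError(
            "singular covariance after dropping zero-variance neurons "
            f"(signs {sign_c}, {sign_d}); window too short or activity degenerate"
        )
    return (logdet_c - 0.5 * logdet_d) / math.log(2.0)


def exact_mutual_information(params: SynapticParameters, config: NetworkConfig) -> float:
    """Exact I[x^t; x^{t-1}] in bits by full 2^N enumeration (N <= 12).

    Builds the transition kernel of the chain, solves for the stationary
    distribution, and evaluates the discrete mutual information between
    consecutive states."""
    from .learning import _transition_matrix, _stationary

    n = config.n_neurons
    if n > 12:
        raise ValueError(f"enumeration limited to N <= 12, got N={n}")
    P, _ = _transition_matrix(params, config)
    pi = _stationary(P)
    joint = pi[:, None] * P
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, P / np.maximum(pi[None, :], 1e-300), 1.0)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(max(terms.sum(), 0.0))


# -- avalanches --------------------------------------------------------------


@dataclass
class BurstCatalog:
    """Sizes and durations of population bursts, with the size histogram.

    A burst is a maximal run of consecutive steps each containing at least
    one spike; its size is the total spike count in the run, its duration the
    run length.  Size >= duration always.  Bursts touching the raster
    boundary are censored and discarded."""

    sizes: np.ndarray
    durations: np.ndarray

    @property
    def n_bursts(self) -> int:
        return len(self.sizes)

    @property
    def size_histogram(self) -> dict:
        if self.n_bursts == 0:
            return {}
        vals, counts = np.unique(self.sizes, return_counts=True)
        total = counts.sum()
        return {int(v): c / total for v, c in zip(vals, counts)}


def detect_bursts(raster: SpikeRaster) -> BurstCatalog:
    """Partition the raster into bursts separated by silent steps."""
    counts = raster.spikes.sum(axis=1).astype(np.int64)
    active = counts > 0
    if not active.any():
        return BurstCatalog(sizes=np.array([], dtype=np.int64), durations=np.array([], dtype=np.int64))
    padded = np.concatenate([[0], active.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    # censor bursts touching the first or last step: their extent is unknown
    keep = (starts > 0) & (ends < len(active))
    starts, ends = starts[keep], ends[keep]
    cum = np.concatenate([[0], np.cumsum(counts)])
    sizes = cum[ends] - cum[starts]
    durations = ends - starts
    return BurstCatalog(sizes=sizes, durations=durations)


def fit_power_law_slope(
    catalog: BurstCatalog, s_min: int = 1, s_max: int = 50
) -> tuple[float, float]:
    """Ordinary least squares on (log s, log p(s)) over occupied integer
    sizes in [s_min, s_max]; returns (slope, standard error).

    A slope near -3/2 over these scales is the signature of a critical
    branching process.  Requires at least 10 distinct occupied sizes.
    """
    hist = catalog.size_histogram
    sizes = np.array(sorted(s for s in hist if s_min <= s <= s_max), dtype=np.float64)
    if len(sizes) < 10:
        raise ValueError(
            f"only {len(sizes)} occupied sizes in [{s_min}, {s_max}]; need >= 10"
        )
    logs = np.log(sizes)
    logp = np.log([hist[int(s)] for s in sizes])
    A = np.vstack([logs, np.ones_like(logs)]).T
    coef, res, *_ = np.linalg.lstsq(A, logp, rcond=None)
    slope = float(coef[0])
    n = len(sizes)
    resid = logp - A @ coef
    s2 = float(resid @ resid) / max(n - 2, 1)
    sxx = float(np.sum((logs - logs.mean()) ** 2))
    stderr = math.sqrt(s2 / sxx) if sxx > 0 else float("inf")
    return slope, stderr


# -- pattern and sequence censuses -------------------------------------------


@dataclass
class SequenceCensus:
    """Distinct/repeated counts of exact firing patterns and sequences.

    ``distinct[L]`` is the number of distinct length-L sequences in the
    window (L=1 rows are single patterns); ``repeated[L]`` counts those whose
    occurrence exceeds ``repeat_threshold``; ``occurrences[L]`` maps each
    distinct key's occurrence count (multiset, keys are opaque)."""

    window: int
    repeat_threshold: int
    distinct: dict
    repeated: dict
    occurrences: dict


def count_patterns_and_sequences(
    raster: SpikeRaster,
    lengths: Sequence[int] = (2, 3, 5, 10),
    window: Optional[int] = None,
    repeat_threshold: int = 2,
) -> SequenceCensus:
    """Census of exact firing patterns and length-L pattern sequences.

    A pattern is the exact binary configuration of one step; a length-L
    sequence is the exact concatenation of L consecutive patterns, counted
    over a sliding window of stride 1.  ``repeated[L]`` counts sequences
    occurring strictly more than ``repeat_threshold`` times (the census
    convention); pass ``repeat_threshold=1`` to count every recurrence.
    Pattern counts are reported under L=1.
    """
    T = raster.n_steps
    if window is None:
        window = T
    if window > T:
        raise ValueError(f"window {window} exceeds raster length {T}")
    spikes = raster.spikes[:window]
    packed = np.packbits(spikes, axis=1)
    row_bytes = packed.tobytes()
    width = packed.shape[1]
    rows = [row_bytes[k * width : (k + 1) * width] for k in range(window)]
    all_lengths = sorted(set([1, *lengths]))
    distinct: dict = {}
    repeated: dict = {}
    occurrences: dict = {}
    for L in all_lengths:
        if L > window:
            raise ValueError(f"sequence length {L} exceeds window {window}")
        if L == 1:
            counter = Counter(rows)
        else:
            counter = Counter(
                b"".join(rows[t : t + L]) for t in range(window - L + 1)
            )
        distinct[L] = len(counter)
        repeated[L] = sum(1 for c in counter.values() if c > repeat_threshold)
        occurrences[L] = sorted(counter.values(), reverse=True)
    return SequenceCensus(
        window=window,
        repeat_threshold=repeat_threshold,
        distinct=distinct,
        repeated=repeated,
        occurrences=occurrences,
    )


# -- single-train statistics -------------------------------------------------


def autocorrelogram(spike_train: np.ndarray, max_lag: int) -> np.ndarray:
    """C(rho) = (1/(T - rho)) sum_t x^t x^{t-rho} for rho = 0..max_lag.

    C(0) is the firing rate; for an independent train C(rho >= 1) is the
    squared rate."""
    x = np.asarray(spike_train, dtype=np.float64).ravel()
    T = len(x)
    if max_lag >= T:
        raise ValueError(f"max_lag {max_lag} must be < train length {T}")
    out = np.empty(max_lag + 1)
    for rho in range(max_lag + 1):
        if rho == 0:
            out[0] = x.mean()
        else:
            out[rho] = float(x[rho:] @ x[:-rho]) / (T - rho)
    return out


def cv_isi(spike_train: np.ndarray) -> float:
    """Coefficient of variation of inter-spike intervals: SD(l)/mean(l).

    Uses the population (1/U) normalisation of the standard deviation.  A
    memoryless train at rate p has geometric ISIs with CV -> sqrt(1 - p),
    i.e. ~1 at low rates (the Poisson reference value); a perfectly periodic
    train has CV = 0.  Requires at least 3 spikes (2 intervals)."""
    x = np.asarray(spike_train).ravel()
    times = np.flatnonzero(x)
    if len(times) < 3:
        raise ValueError(f"need >= 3 spikes for a CV, got {len(times)}")
    isis = np.diff(times).astype(np.float64)
    mean = isis.mean()
    sd = isis.std()  # population normalisation
    return float(sd / mean)


# -- controls ----------------------------------------------------------------


def shuffle_weights(params: SynapticParameters, rng: np.random.Generator) -> SynapticParameters:
    """Uniformly permute the off-diagonal recurrent weights.

    The multiset of recurrent weights is preserved exactly while their
    positions are randomised; the diagonal stays zero, thresholds and any
    external-input columns are untouched.  Used to ask whether a learned
    network outperforms random networks with the same weight distribution."""
    n = params.n_rec
    new = params.copy()
    mask = ~np.eye(n, dtype=bool)
    vals = new.weights[:, :n][mask]
    new.weights[:, :n][mask] = rng.permutation(vals)
    return new


# -- receptive fields --------------------------------------------------------


@dataclass
class ReceptiveFieldMap:
    """Raw and gray-rescaled spike-triggered averages per recurrent neuron.

    ``rescaled[i]`` is a real-valued patch in [1, 255] with pixel mean
    exactly 128 and maximal absolute deviation exactly 127 (gray levels;
    quantised to integers only at image export); neurons with no spikes
    (or a perfectly flat STA) are flagged degenerate and carry no rescaled
    patch."""

    raw: np.ndarray
    rescaled: dict
    degenerate: np.ndarray


def spike_triggered_average(
    raster: SpikeRaster, patches: np.ndarray, n_neurons: Optional[int] = None
) -> ReceptiveFieldMap:
    """Reverse correlation: STA_j^(i) = <y_j^{t-1} x_i^t> over the window.

    ``patches[t]`` must be the (flattened) input presented at the step that
    generated raster row t, so the patch preceding a spike at row t is
    ``patches[t-1]``.  The raw average is rescaled per neuron to the fixed
    gray-level contract (mean 128, maximal deviation 127, range [1, 255])."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 3:
        patches = patches.reshape(patches.shape[0], -1)
    T = raster.n_steps
    if patches.shape[0] != T:
        raise ValueError(
            f"patch stream length {patches.shape[0]} does not match raster length {T}"
        )
    spikes = raster.spikes if n_neurons is None else raster.spikes[:, :n_neurons]
    N = spikes.shape[1]
    n_spikes = spikes[1:].sum(axis=0).astype(np.float64)
    raw = (spikes[1:].astype(np.float64).T @ patches[:-1]) / (T - 1)
    degenerate = n_spikes == 0
    rescaled: dict = {}
    for i in range(N):
        if degenerate[i]:
            continue
        sta = raw[i]
        mean = sta.mean()
        dev = np.abs(sta - mean).max()
        if dev == 0:
            degenerate[i] = True
            continue
        rescaled[i] = 128.0 + (sta - mean) * (127.0 / dev)
    return ReceptiveFieldMap(raw=raw, rescaled=rescaled, degenerate=degenerate)


# -- strong chains -----------------------------------------------------------


@dataclass
class ChainGraph:
    """Poly-synaptic transmission graph over strong excitatory edges.

    ``depths[node]`` is the first-reach depth from the root set by
    breadth-first expansion over edges with weight above the threshold;
    ``edges`` lists (pre, post, weight) between included nodes."""

    depths: dict
    edges: list
    threshold: float
    max_depth: int


def extract_strong_chains(
    params: SynapticParameters,
    roots: Sequence[int],
    threshold: float = 8.0,
    max_depth: int = 6,
) -> ChainGraph:
    """Breadth-first expansion from ``roots`` along edges w_ij > threshold
    (presynaptic j -> postsynaptic i), up to ``max_depth`` hops."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    W = params.weights
    n_rec, n_tot = W.shape
    roots = list(roots)
    for r in roots:
        if not (0 <= r < n_tot):
            raise ValueError(f"root index {r} out of range")
    depths = {r: 0 for r in roots}
    frontier = list(roots)
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        nxt = []
        for j in frontier:
            post = np.flatnonzero(W[:, j] > threshold)
            for i in post:
                if int(i) not in depths:
                    depths[int(i)] = depth
                    nxt.append(int(i))
        frontier = nxt
    nodes = set(depths)
    edges = []
    for j in sorted(nodes):
        if j < n_tot:
            post = np.flatnonzero(W[:, j] > threshold)
            for i in post:
                if int(i) in nodes:
                    edges.append((j, int(i), float(W[i, j])))
    return ChainGraph(depths=depths, edges=edges, threshold=threshold, max_depth=max_depth)
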