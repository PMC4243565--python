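"""Configuration objects for networks and learning runs.

Two dataclasses carry everything a run needs: :class:`NetworkConfig` fixes the
architecture (number of recurrent neurons, maximal transmission probability
``p_max``, target mean rate ``p0``, number of appended non-plastic external
input neurons), and :class:`LearningConfig` fixes the plasticity rule
(learning rate, scaled penalty coefficients, leak constants of the eligibility
traces and long-time averages, the singularity floor, plasticity masks and the
scope of the global modulatory signals).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional


class ConfigError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of one stochastic binary recurrent network.

    Parameters
    ----------
    n_neurons:
        Number of recurrent (plastic, sampled) neurons, ``N >= 1``.
    p_max:
        Maximal probability of firing transmission, in ``(0, 1]``.  A neuron
        with infinitely strong drive fires with at most this probability.
    p0:
        Target mean firing rate, in ``(0, p_max)``.  Thresholds are
        initialised so that an uncoupled network fires at this rate.
    n_external:
        Number of external input neurons appended after the recurrent ones.
        Their states are never sampled, only copied from a stimulus stream.
    """

    n_neurons: int
    p_max: float = 0.95
    p0: float = 0.05
    n_external: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if not (0.0 < self.p_max <= 1.0):
            raise ConfigError(f"p_max must be in (0, 1], got {self.p_max}")
        if not (0.0 < self.p0 < self.p_max):
            raise ConfigError(
                f"p0 must be in (0, p_max), got p0={self.p0}, p_max={self.p_max}"
            )
        if self.n_external < 0:
            raise ConfigError(f"n_external must be >= 0, got {self.n_external}")

    @property
    def n_total(self) -> int:
        """Recurrent plus external neuron count (weight-matrix columns)."""
        return self.n_neurons + self.n_external

    @property
    def s0(self) -> float:
        """Reference membrane input: a neuron with ``s = s0`` fires at ``p0``."""
        return math.log(self.p0 / (self.p_max - self.p0))

    @property
    def h_init(self) -> float:
        """Initial threshold ``log((p_max - p0)/p0)``; equals ``-s0``."""
        return math.log((self.p_max - self.p0) / self.p0)


@dataclass(frozen=True)
class LearningConfig:
    """Parameters of the trace-based Infomax plasticity rule.

    ``c_kappa``, ``c_eta`` and ``c_zeta`` are the scaled penalty coefficients;
    the raw coefficients of the objective are recovered by
    :func:`infomaxnet.learning.scale_coefficients`.  ``tau`` is the leak
    constant (in steps) of the synapse-local eligibility traces, ``T`` the
    leak constant of the slow population averages; the stochastic
    approximation assumes ``T >> tau``.  ``delta`` floors the denominator of
    the predictability signal (and, by extension, the cold-start marginal
    estimate) to remove a removable singularity.

    ``plastic_rows`` / ``plastic_cols`` restrict which weight entries are
    updated (defaults: all recurrent rows, all columns).  ``gamma_scope``
    restricts which neurons enter the global-signal sums (default: all
    recurrent neurons).  ``variant`` selects the standard per-neuron
    normalisation of the predictability signal or the ``a_prime`` variant
    that normalises the population sum instead.
    """

    epsilon: float = 0.006
    c_kappa: float = 1.0
    c_eta: float = 1.5
    c_zeta: float = 3.0
    tau: float = 15.0
    T: float = 50000.0
    delta: float = 1.0e-3
    plastic_rows: Optional[tuple] = None
    plastic_cols: Optional[tuple] = None
    gamma_scope: Optional[tuple] = None
    variant: str = "standard"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ConfigError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.tau < 1:
            raise ConfigError(f"tau must be >= 1, got {self.tau}")
        if self.T < 1:
            raise ConfigError(f"T must be >= 1, got {self.T}")
        if self.delta <= 0:
            raise ConfigError(f"delta must be > 0, got {self.delta}")
        if self.variant not in ("standard", "a_prime"):
            raise ConfigError(f"variant must be 'standard' or 'a_prime', got {self.variant!r}")
        for name in ("c_kappa", "c_eta", "c_zeta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.T < 10 * self.tau:
            warnings.warn(
                f"T={self.T} is less than 10*tau={10 * self.tau}; the "
                "stochastic-approximation separation of time scales is weak",
                stacklevel=2,
            )

    def row_mask(self, n_rec: int):
        import numpy as np

        mask = np.zeros(n_rec, dtype=np.bool_)
        if self.plastic_rows is None:
            mask[:] = True
        else:
            mask[list(self.plastic_rows)] = True
        return mask

    def col_mask(self, n_total: int):
        import numpy as np

        mask = np.zeros(n_total, dtype=np.bool_)
        if self.plastic_cols is None:
            mask[:] = True
        else:
            mask[list(self.plastic_cols)] = True
        return mask

    def scope_mask(self, n_rec: int):
        import numpy as np

        mask = np.zeros(n_rec, dtype=np.bool_)
        if self.gamma_scope is None:
            mask[:] = True
        else:
            idx = np.asarray(list(self.gamma_scope), dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= n_rec):
                raise ConfigError("gamma_scope must index recurrent neurons")
            mask[idx] = True
        return mask


def configs_to_dict(net: NetworkConfig, learn: LearningConfig, seed: int | None = None) -> dict:
    d = {"network": asdict(net), "learning": asdict(learn)}
    if seed is not None:
        d["seed"] = int(seed)
    for key in ("plastic_rows", "plastic_cols", "gamma_scope"):
        if d["learning"][key] is not None:
            d["learning"][key] = list(d["learning"][key])
    return d


_NETWORK_KEYS = {"n_neurons", "p_max", "p0", "n_external"}
_LEARNING_KEYS = {
    "epsilon", "c_kappa", "c_eta", "c_zeta", "tau", "T", "delta",
    "plastic_rows", "plastic_cols", "gamma_scope", "variant",
}


def configs_from_dict(d: dict) -> tuple[NetworkConfig, LearningConfig, Optional[int]]:
    """Build typed configs from a raw (already parsed) mapping.

    Unknown keys are rejected with the offending field path so that typos in
    config files fail loudly rather than silently falling back to defaults.
    """
    errors = []
    net_raw = dict(d.get("network", {}))
    learn_raw = dict(d.get("learning", {}))
    for k in set(d) - {"network", "learning", "seed"}:
        errors.append(f"unknown top-level key: {k!r}")
    for k in set(net_raw) - _NETWORK_KEYS:
        errors.append(f"unknown key: network.{k}")
    for k in set(learn_raw) - _LEARNING_KEYS:
        errors.append(f"unknown key: learning.{k}")
    if errors:
        raise ConfigError("; ".join(errors))
    for key in ("plastic_rows", "plastic_cols", "gamma_scope"):
        if learn_raw.get(key) is not None:
            learn_raw[key] = tuple(learn_raw[key])
    net = NetworkConfig(**net_raw)
    learn = LearningConfig(**learn_raw)
    seed = d.get("seed")
    return net, learn, None if seed is None else int(seed)
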