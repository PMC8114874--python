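"""Synthetic memory sequences and noise realizations.

The stochastic substrate of the model: Bernoulli memory sequences, balanced
spiking-error injection, synaptic weight noise with variance proportional to
the mean weight magnitude, Gaussian threshold noise, and log-normal sampling
of heterogeneous parameter populations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import NetworkSpec, spawn_rng

__all__ = [
    "MemorySequence",
    "NoiseRealization",
    "generate_sequence",
    "inject_spiking_errors",
    "sample_synaptic_noise",
    "sample_threshold_noise",
    "sample_lognormal_params",
    "save_sequence",
    "load_sequence",
]


@dataclass(frozen=True)
class MemorySequence:
    """(m+1) x N binary matrix of target network states.

    Association mu (1-based) maps row mu-1 (input state X^mu) to row mu
    (target state X^(mu+1)).
    """

    states: np.ndarray
    m: int

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 2 or states.shape[0] != self.m + 1:
            raise ValueError("states must be an (m+1) x N matrix")
        if not np.isin(states, (0, 1)).all():
            raise ValueError("states must be binary")
        object.__setattr__(self, "states", states.astype(np.int8))

    @property
    def n(self) -> int:
        return self.states.shape[1]

    def inputs(self) -> np.ndarray:
        """m x N matrix of association input states X^1 .. X^m."""
        return self.states[:-1]

    def targets(self) -> np.ndarray:
        """m x N matrix of association target states X^2 .. X^(m+1)."""
        return self.states[1:]


@dataclass(frozen=True)
class NoiseRealization:
    """One draw of all noise sources: corrupted states, noisy weights,
    noisy thresholds."""

    X_star: np.ndarray
    J_star: np.ndarray
    h_star: np.ndarray


def generate_sequence(spec: NetworkSpec, m: int, seed: int | None = None) -> MemorySequence:
    """Draw an (m+1) x N sequence of independent Bernoulli(f_i) states.

    Entry (mu, i) is 1 with probability f_i of neuron i, independently
    across neurons and time steps.
    """
    if m < 1:
        raise ValueError("need at least one association (m >= 1)")
    rng = spawn_rng(spec.seed if seed is None else seed, "sequence")
    f = spec.f
    states = (rng.random((m + 1, spec.n)) < f[None, :]).astype(np.int8)
    return MemorySequence(states=states, m=m)


def inject_spiking_errors(
    X: np.ndarray,
    f: np.ndarray | float,
    r: np.ndarray | float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Apply balanced spiking errors to a binary state array.

    A 1 flips to 0 with probability r/(2f); a 0 flips to 1 with probability
    r/(2(1-f)).  Flips are independent, and because f*p_minus = (1-f)*p_plus
    the firing probability f is preserved.  ``f`` and ``r`` broadcast along
    the last (neuron) axis of ``X``.
    """
    X = np.asarray(X)
    f = np.broadcast_to(np.asarray(f, dtype=float), X.shape[-1:])
    r = np.broadcast_to(np.asarray(r, dtype=float), X.shape[-1:])
    p_minus = np.where(f > 0, r / (2.0 * f), 0.0)
    p_plus = np.where(f < 1, r / (2.0 * (1.0 - f)), 0.0)
    if (p_minus > 1).any() or (p_plus > 1).any():
        raise ValueError("flip probabilities exceed 1; require r < 2f(1-f)")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "flips")
    u = rng.random(X.shape)
    flip = np.where(X == 1, u < p_minus, u < p_plus)
    return np.where(flip, 1 - X, X).astype(np.int8)


def sample_synaptic_noise(
    J: np.ndarray,
    beta_syn: float,
    h: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw noisy weights J* with mean J and var = (h*beta_syn/N)*|J|.

    The distribution family is Gaussian (the large-N reformulation only uses
    the first two moments).  Absent connections (J = 0) carry no noise and
    are returned as exactly 0.
    """
    if beta_syn < 0:
        raise ValueError("beta_syn must be >= 0")
    J = np.asarray(J, dtype=float)
    if beta_syn == 0:
        return J.copy()
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "synapse")
    sd = np.sqrt(h * beta_syn / n * np.abs(J))
    return J + sd * rng.standard_normal(J.shape)


def sample_threshold_noise(
    h: float | np.ndarray,
    beta_int: float | np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
    size: int | tuple | None = None,
) -> np.ndarray | float:
    """Gaussian threshold draw(s) with mean h and var h^2 beta_int^2 / N."""
    if np.any(np.asarray(beta_int) < 0):
        raise ValueError("beta_int must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "threshold")
    h = np.asarray(h, dtype=float)
    sd = h * np.asarray(beta_int, dtype=float) / np.sqrt(n)
    shape = np.broadcast_shapes(h.shape, np.shape(sd)) if size is None else size
    return h + sd * rng.standard_normal(shape)


def sample_lognormal_params(
    mean: float,
    cv: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Log-normal draws with given arithmetic mean and coefficient of
    variation, for building heterogeneous r or beta populations.

    Moment matching: sigma_log^2 = ln(1 + cv^2), mu_log = ln(mean) -
    sigma_log^2 / 2.
    """
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "misc")
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def draw_noise_realization(
    seq: MemorySequence, spec: NetworkSpec, seed: int
) -> NoiseRealization:
    """Sample one full noise realization for a sequence and network: flipped
    states, one noisy N x N weight draw per mean-weight matrix of ones-scale
    (mean weights must be supplied separately in practice; this helper is
    used by tests on statistical invariants)."""
    X_star = inject_spiking_errors(seq.states, spec.f, spec.r, seed)
    J = np.zeros((spec.n, spec.n))
    h_star = sample_threshold_noise(spec.h, spec.beta_int, spec.n, seed)
    return NoiseRealization(X_star=X_star, J_star=J, h_star=np.asarray(h_star))


# -- I/O -------------------------------------------------------------------

def save_sequence(seq: MemorySequence, path: str | Path, meta: dict | None = None) -> None:
    """Write the sequence as a CSV of 0/1 (rows = time steps, columns =
    neurons) with a JSON side-car recording metadata."""
    path = Path(path)
    np.savetxt(path, seq.states, fmt="%d", delimiter=",")
    sidecar = {"m": seq.m, "n": seq.n}
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_sequence(path: str | Path) -> MemorySequence:
    path = Path(path)
    states = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2)
    return MemorySequence(states=states, m=states.shape[0] - 1)
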