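"""Model parameters for noisy associative-memory networks.

A network of N McCulloch–Pitts neurons stores a sequence of binary states
X^1 -> X^2 -> ... -> X^(m+1).  Each neuron i is characterised by its firing
probability f_i, its tolerated spiking-error probability r_i, synaptic and
intrinsic noise strengths (beta_syn, beta_int), a Dale sign g_i (+1
excitatory, -1 inhibitory), a firing threshold h_i and a fixed average
absolute input weight w_i (l1-norm homeostatic constraint).

Spiking errors are balanced: a 1 flips to 0 with probability p_minus =
r/(2f) and a 0 flips to 1 with probability p_plus = r/(2(1-f)), so that
f*p_minus = (1-f)*p_plus and the firing probability is preserved.  The
replica solution is stable only for r < 2 f (1-f), which is enforced at
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkSpec",
    "child_seed",
    "spawn_rng",
]


def _check_prob(name: str, value: float, open_interval: bool = True) -> None:
    lo_ok = value > 0 if open_interval else value >= 0
    hi_ok = value < 1 if open_interval else value <= 1
    if not (lo_ok and hi_ok):
        bounds = "(0, 1)" if open_interval else "[0, 1]"
        raise ValueError(f"{name} = {value!r} must lie in {bounds}")


@dataclass(frozen=True)
class NeuronParams:
    """Per-neuron parameters of the storage model.

    Raises ``ValueError`` if the replica stability condition
    ``r < 2 f (1 - f)`` is violated or any parameter is out of range.
    """

    f: float = 0.2
    r: float = 0.0
    beta_syn: float = 0.0
    beta_int: float = 0.0
    g: int = 1
    h: float = 1.0
    w: float = 0.1

    def __post_init__(self) -> None:
        _check_prob("f", self.f)
        if not 0.0 <= self.r < 2.0 * self.f * (1.0 - self.f):
            raise ValueError(
                f"spiking error probability r = {self.r!r} must lie in "
                f"[0, 2f(1-f)) = [0, {2 * self.f * (1 - self.f)!r}) for "
                f"f = {self.f!r} (replica stability condition)"
            )
        if self.beta_syn < 0 or self.beta_int < 0:
            raise ValueError("noise strengths beta_syn, beta_int must be >= 0")
        if self.g not in (-1, 1):
            raise ValueError("sign label g must be -1 (inhibitory) or +1 (excitatory)")
        if self.h <= 0:
            raise ValueError("firing threshold h must be > 0")
        if self.w <= 0:
            raise ValueError("average absolute weight w must be > 0")

    @property
    def p_plus(self) -> float:
        """Probability of an erroneous spike, P(X*=1 | X=0) = r/(2(1-f))."""
        return self.r / (2.0 * (1.0 - self.f))

    @property
    def p_minus(self) -> float:
        """Probability of a spike failure, P(X*=0 | X=1) = r/(2f)."""
        return self.r / (2.0 * self.f)

    def with_(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NetworkSpec:
    """A full network: N neurons, the first ``n_inh`` of which are inhibitory
    by default (any arrangement is allowed as long as the g labels agree)."""

    n: int
    n_inh: int
    neurons: tuple[NeuronParams, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("N must be >= 1")
        if not 0 <= self.n_inh <= self.n:
            raise ValueError("N_inh must satisfy 0 <= N_inh <= N")
        if len(self.neurons) != self.n:
            raise ValueError("need exactly N NeuronParams entries")
        n_inh_actual = sum(1 for p in self.neurons if p.g == -1)
        if n_inh_actual != self.n_inh:
            raise ValueError(
                f"{n_inh_actual} neurons have g = -1 but n_inh = {self.n_inh}"
            )

    @classmethod
    def homogeneous_network(
        cls,
        n: int,
        frac_inh: float = 0.2,
        seed: int = 0,
        **neuron_kwargs,
    ) -> "NetworkSpec":
        """All neurons identical apart from the sign label; the first
        ``round(frac_inh * n)`` neurons are inhibitory."""
        n_inh = int(round(frac_inh * n))
        neurons = tuple(
            NeuronParams(g=(-1 if i < n_inh else 1), **neuron_kwargs)
            for i in range(n)
        )
        return cls(n=n, n_inh=n_inh, neurons=neurons, seed=seed)

    def homogeneous(self) -> bool:
        """True iff all neurons are identical apart from their sign label."""
        ref = self.neurons[0].with_(g=1)
        return all(p.with_(g=1) == ref for p in self.neurons)

    # -- convenience array views -------------------------------------------
    @property
    def g(self) -> np.ndarray:
        return np.array([p.g for p in self.neurons], dtype=np.int64)

    @property
    def f(self) -> np.ndarray:
        return np.array([p.f for p in self.neurons], dtype=float)

    @property
    def r(self) -> np.ndarray:
        return np.array([p.r for p in self.neurons], dtype=float)

    @property
    def beta_syn(self) -> np.ndarray:
        return np.array([p.beta_syn for p in self.neurons], dtype=float)

    @property
    def beta_int(self) -> np.ndarray:
        return np.array([p.beta_int for p in self.neurons], dtype=float)

    @property
    def h(self) -> np.ndarray:
        return np.array([p.h for p in self.neurons], dtype=float)

    @property
    def w(self) -> np.ndarray:
        return np.array([p.w for p in self.neurons], dtype=float)

    @property
    def w_tilde(self) -> np.ndarray:
        """Scaled l1-norm targets, w~ = N w / h."""
        return self.n * self.w / self.h


# -- seeding ---------------------------------------------------------------
# A single master seed spawns named child streams so that the sequence draw,
# the spiking-error flips, the synaptic noise and the threshold noise can be
# reproduced independently of one another.

_PURPOSES = ("sequence", "flips", "synapse", "threshold", "misc")


def child_seed(master_seed: int, purpose: str, index: int = 0) -> np.random.SeedSequence:
    """Deterministic child SeedSequence for a named purpose."""
    if purpose not in _PURPOSES:
        raise ValueError(f"unknown stream purpose {purpose!r}; use one of {_PURPOSES}")
    return np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(_PURPOSES.index(purpose), int(index)),
    )


def spawn_rng(master_seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, purpose, index))
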