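"""Gaussian statistics of the noisy PSP margin.

In the large-N limit the deviation of the postsynaptic potential from the
firing threshold, I* = sum_j J*_j X*_j - h*, is Gaussian for every
association.  Its mean I and SD sigma follow in closed form from the flip
probabilities of the inputs and the synaptic/intrinsic noise moments.  A
target association (X, y) is learnable iff the Gaussian tail beyond the
threshold stays below the tolerated output error rate, which turns into a
margin inequality

    (2y - 1) I  >=  (D_minus y + D_plus (1 - y)) sigma

with D_minus = sqrt(2) erfinv(1 - r_out/f_out) (spike failures, y = 1) and
D_plus = sqrt(2) erfinv(1 - r_out/(1 - f_out)) (erroneous spikes, y = 0).

Internally everything is computed with h = 1 and scaled weights
J~ = (N/h) J; the margin decision is invariant to this convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfinv

__all__ = [
    "MarginMoments",
    "OutputMargins",
    "InputCoefficients",
    "flip_averaged_input",
    "flip_variance_input",
    "psp_moments",
    "output_margins",
    "input_coefficients",
    "margin_satisfied",
    "association_margins",
]


@dataclass(frozen=True)
class MarginMoments:
    """Mean and SD of the Gaussian margin, in units of the threshold h."""

    I_mu: float
    sigma_mu: float

    def __post_init__(self) -> None:
        if self.sigma_mu < 0:
            raise ValueError("sigma_mu must be >= 0")


@dataclass(frozen=True)
class OutputMargins:
    """Margin multipliers: D_plus applies to target 0, D_minus to target 1."""

    D_plus: float
    D_minus: float


@dataclass(frozen=True)
class InputCoefficients:
    """Spiking-error coefficients of one input:
    B = r (1 - r / (4 f (1-f))),  C = f (1-f) (1 - r / (2 f (1-f)))^2."""

    B: float | np.ndarray
    C: float | np.ndarray


def _validate_stability(f, r) -> None:
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("firing probability f must lie in (0, 1)")
    if np.any(r < 0) or np.any(r >= 2 * f * (1 - f)):
        raise ValueError(
            "spiking error probability must satisfy 0 <= r < 2 f (1-f); "
            "larger r makes the replica solution unstable"
        )


def flip_averaged_input(X, f, r) -> np.ndarray:
    """E[X* | X]: the spiking-error average of a binary input,
    (1 - r/(2f)) X + r/(2(1-f)) (1 - X).  Its mean over X is f."""
    X = np.asarray(X, dtype=float)
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    return (1.0 - r / (2.0 * f)) * X + r / (2.0 * (1.0 - f)) * (1.0 - X)


def flip_variance_input(X, f, r) -> np.ndarray:
    """Var[X* | X]: Bernoulli flip variance of a binary input."""
    X = np.asarray(X, dtype=float)
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    pm = r / (2.0 * f)
    pp = r / (2.0 * (1.0 - f))
    return (1.0 - pm) * pm * X + (1.0 - pp) * pp * (1.0 - X)


def psp_moments(
    J: np.ndarray,
    X: np.ndarray,
    f: np.ndarray | float,
    r: np.ndarray | float,
    g: np.ndarray | int,
    beta_syn: float,
    beta_int: float,
    h: float = 1.0,
) -> MarginMoments:
    """Closed-form mean and SD of the margin sum_j J_j X*_j - h* for raw
    weights ``J`` and a binary input state ``X``.

    The variance collects three contributions: input-flip variance,
    synaptic noise (proportional to |J| = J g under the sign constraints),
    and intrinsic threshold noise.
    """
    J = np.asarray(J, dtype=float)
    X = np.asarray(X, dtype=float)
    if J.shape != X.shape:
        raise ValueError("J and X must have the same length")
    n = J.shape[0]
    f = np.broadcast_to(np.asarray(f, dtype=float), J.shape)
    r = np.broadcast_to(np.asarray(r, dtype=float), J.shape)
    g = np.broadcast_to(np.asarray(g, dtype=float), J.shape)
    _validate_stability(f, r)

    A = flip_averaged_input(X, f, r)
    V = flip_variance_input(X, f, r)
    I_mu = float(J @ A - h)
    syn = h * beta_syn / n * float((J * g) @ A)
    if syn < -1e-12 * max(1.0, abs(h)):
        raise ValueError(
            "negative synaptic-noise variance: weights violate sign constraints"
        )
    var = float(J**2 @ V) + max(syn, 0.0) + h**2 * beta_int**2 / n
    return MarginMoments(I_mu=I_mu, sigma_mu=float(np.sqrt(max(var, 0.0))))


def output_margins(r_out: float, f_out: float) -> OutputMargins:
    """D_plus/D_minus via the inverse error function; requires the
    stability bound 0 < r_out < 2 f_out (1 - f_out)."""
    if not 0 < f_out < 1:
        raise ValueError("f_out must lie in (0, 1)")
    if not 0 < r_out < 2 * f_out * (1 - f_out):
        raise ValueError(
            f"r_out = {r_out!r} outside (0, {2 * f_out * (1 - f_out)!r}); "
            "the margin multipliers are defined only below the stability "
            "bound 2 f_out (1 - f_out) (and diverge at r_out = 0)"
        )
    D_minus = np.sqrt(2.0) * erfinv(1.0 - r_out / f_out)
    D_plus = np.sqrt(2.0) * erfinv(1.0 - r_out / (1.0 - f_out))
    return OutputMargins(D_plus=float(D_plus), D_minus=float(D_minus))


def input_coefficients(f: np.ndarray | float, r: np.ndarray | float) -> InputCoefficients:
    """Replica input coefficients B and C (see class docstring)."""
    f = np.asarray(f, dtype=float)
    r = np.asarray(r, dtype=float)
    _validate_stability(f, r)
    B = r * (1.0 - r / (4.0 * f * (1.0 - f)))
    C = f * (1.0 - f) * (1.0 - r / (2.0 * f * (1.0 - f))) ** 2
    if f.ndim == 0 and r.ndim == 0:
        return InputCoefficients(B=float(B), C=float(C))
    return InputCoefficients(B=B, C=C)


def margin_satisfied(mm: MarginMoments, y: int, om: OutputMargins) -> bool:
    """Feasibility of one association given its margin moments.

    With sigma = 0 the condition degenerates to a strict sign condition on
    I (Heaviside convention theta(0) = 0: I = 0 counts as no spike, hence a
    violation for y = 1 and a pass for y = 0).
    """
    if y not in (0, 1):
        raise ValueError("target bit y must be 0 or 1")
    if mm.sigma_mu == 0.0:
        return mm.I_mu > 0 if y == 1 else mm.I_mu <= 0
    D = om.D_minus if y == 1 else om.D_plus
    return (2 * y - 1) * mm.I_mu >= D * mm.sigma_mu


def association_margins(
    J_tilde: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    f: np.ndarray | float,
    r: np.ndarray | float,
    g: np.ndarray,
    beta_syn: float,
    beta_int: float,
    om: OutputMargins,
) -> np.ndarray:
    """Vectorized signed slack of every association for scaled weights.

    Returns the array (2y-1) I~ - D_y sigma~ for all m associations, where
    I~ = (1/N) sum J~_j A_j - 1 and sigma~ = sqrt((1/N) sum [J~^2 V +
    beta_syn J~ g A] + beta_int^2) / sqrt(N).  Non-negative entries are
    satisfied associations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[1]
    f = np.broadcast_to(np.asarray(f, dtype=float), (n,))
    r = np.broadcast_to(np.asarray(r, dtype=float), (n,))
    A = flip_averaged_input(X, f[None, :], r[None, :])
    V = flip_variance_input(X, f[None, :], r[None, :])
    I = A @ J_tilde / n - 1.0
    q = J_tilde * np.asarray(g, dtype=float)
    var = (V @ J_tilde**2 + beta_syn * (A @ q)) / n + beta_int**2
    sigma = np.sqrt(np.maximum(var, 0.0) / n)
    D = om.D_minus * y + om.D_plus * (1.0 - y)
    return (2.0 * y - 1.0) * I - D * sigma
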