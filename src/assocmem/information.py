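"""Mutual information of retrieved associative sequences.

One association maps a random network state X^mu to the next state
X^(mu+1); retrieval reproduces the target up to balanced spiking errors of
total rate r, which act as N parallel asymmetric binary channels.  For a
homogeneous network the per-association information is

    I = H(X^(mu+1)) - H(X^(mu+1) | X^mu)

with the closed forms (base-2 logarithms, bits)

    H(X)     = -N [f log2 f + (1-f) log2(1-f)]
    H(X|X')  = -N [ f h2(r/(2f)) + (1-f) h2(r/(2(1-f))) ]

where h2 is the binary entropy of the per-bit flip probability.  Expected
retrieved information per playout is reported in two ways: counting only
completely retrieved sequences (retrieval probability x m I) and crediting
partial retrievals in proportion to their length (mean retrieved length x I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InfoResult",
    "association_information",
    "expected_information",
    "optimal_beta_learn",
]


@dataclass(frozen=True)
class InfoResult:
    I_per_association: float
    H_marginal: float
    H_conditional: float


def _h2(p: float) -> float:
    """Binary entropy in bits; continuous extension h2(0) = h2(1) = 0."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def association_information(n: int, f: float, r: float) -> InfoResult:
    """Closed-form mutual information (bits) of one association for a
    homogeneous network of ``n`` neurons."""
    if not 0 < f < 1:
        raise ValueError("f must lie in (0, 1)")
    if not 0 <= r < 2 * f * (1 - f):
        raise ValueError("r must lie in [0, 2 f (1-f))")
    H_marg = n * _h2(f)
    H_cond = n * (f * _h2(r / (2.0 * f)) + (1.0 - f) * _h2(r / (2.0 * (1.0 - f))))
    return InfoResult(
        I_per_association=H_marg - H_cond,
        H_marginal=H_marg,
        H_conditional=H_cond,
    )


def expected_information(
    retr_prob: float,
    mean_len_fraction: float,
    m: int,
    I: float,
) -> tuple[float, float]:
    """(complete-only, with-partial) expected retrieved information per
    playout, in bits.  The first is retr_prob * m * I, the second
    mean_len_fraction * m * I; since every complete retrieval has full
    length, the first never exceeds the second."""
    if not 0 <= retr_prob <= 1 or not 0 <= mean_len_fraction <= 1:
        raise ValueError("probabilities/fractions must lie in [0, 1]")
    if retr_prob > mean_len_fraction + 1e-12:
        raise ValueError(
            "retrieval probability cannot exceed the mean length fraction"
        )
    return retr_prob * m * I, mean_len_fraction * m * I


def optimal_beta_learn(sweep) -> tuple[float, tuple[float, float]]:
    """Argmax of an information sweep over beta_learn.

    ``sweep`` is a sequence of (beta_learn, info, se) triples.  Returns the
    grid argmax and the 1-SE plateau interval: the range of beta values
    whose info estimate is within one combined SE of the maximum.
    """
    pts = sorted((float(b), float(v), float(se)) for b, v, se in sweep)
    if len(pts) < 3:
        raise ValueError("need at least 3 grid points")
    betas = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    ses = np.array([p[2] for p in pts])
    k = int(np.argmax(vals))
    comb = np.sqrt(ses**2 + ses[k] ** 2)
    within = vals >= vals[k] - comb
    return float(betas[k]), (float(betas[within].min()), float(betas[within].max()))
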