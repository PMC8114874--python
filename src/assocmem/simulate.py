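"""Network simulation: sequence retrieval and spontaneous dynamics.

A loaded network is iterated with the single-step map
X_i(t+1) = theta(sum_j J*_ij X*_j(t) - h*_i), sampling synaptic and
intrinsic noise freshly at every step.  Retrieval replays a loaded
sequence from its first state and classifies each trial as complete or
partial; the per-step error fraction is bimodal (it either fluctuates
around the learned error rate r or diverges to 2f(1-f), the distance
between two random states), so the deviation threshold is placed at the
midpoint of the two modes where the classification is insensitive to its
exact position.

Spontaneous runs start from a random state and summarize the dynamics by
the CV of inter-spike intervals, the mean pairwise zero-lag spike
cross-correlation, and the excitatory/inhibitory input anti-correlation
that characterizes the balanced regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loading import WeightMatrix, connection_mask
from .params import NetworkSpec, spawn_rng
from .synthesis import MemorySequence, inject_spiking_errors

__all__ = [
    "RetrievalResult",
    "ActivityRaster",
    "DynamicsStats",
    "step",
    "retrieve",
    "retrieval_statistics",
    "spontaneous_run",
    "dynamics_stats",
    "connectivity_stats",
]

TRANSIENT_DISCARD = 100  # steps dropped from spontaneous statistics


@dataclass(frozen=True)
class RetrievalResult:
    complete: bool
    retrieved_length: int
    error_fraction_trace: np.ndarray


@dataclass(frozen=True)
class ActivityRaster:
    states: np.ndarray  # T x N binary, row 0 = initial state

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def n(self) -> int:
        return self.states.shape[1]


@dataclass(frozen=True)
class DynamicsStats:
    cv_isi: float
    cross_corr: float
    ei_anticorr: float
    pcon_inh: float
    pcon_exc: float
    cv_w_inh: float
    cv_w_exc: float


def _resolve_retrieval_noise(
    spec: NetworkSpec, beta_retr: float | None, beta_syn: float | None, beta_int: float | None
) -> tuple[float, float]:
    """Retrieval noise strengths.  ``beta_retr`` is shorthand for a purely
    intrinsic decomposition (beta_int = beta_retr, beta_syn = 0); an
    explicit (beta_syn, beta_int) pair overrides it."""
    if beta_syn is None and beta_int is None:
        if beta_retr is None:
            raise ValueError("provide beta_retr or (beta_syn, beta_int)")
        return 0.0, float(beta_retr)
    return float(beta_syn or 0.0), float(beta_int or 0.0)


def step(
    Jmat: WeightMatrix | np.ndarray,
    state: np.ndarray,
    spec: NetworkSpec,
    beta_retr: float | None = None,
    r_step: float = 0.0,
    rng: np.random.Generator | int = 0,
    beta_syn: float | None = None,
    beta_int: float | None = None,
) -> np.ndarray:
    """One synchronous update of all neurons under retrieval noise.

    Scaled units: neuron i spikes iff sum_j J~*_ij X*_j > N_i-scaled noisy
    threshold, with theta(0) = 0.
    """
    J = Jmat.J_tilde if isinstance(Jmat, WeightMatrix) else np.asarray(Jmat)
    n = spec.n
    if J.shape != (n, n) or state.shape != (n,):
        raise ValueError("dimension mismatch between weights, state and spec")
    rng = rng if isinstance(rng, np.random.Generator) else spawn_rng(rng, "misc")
    bsyn, bint = _resolve_retrieval_noise(spec, beta_retr, beta_syn, beta_int)

    x = np.asarray(state, dtype=float)
    if r_step > 0:
        x = inject_spiking_errors(state, spec.f, spec.r * 0 + r_step, rng).astype(float)
    drive = J @ x
    if bsyn > 0:
        # noise variance of sum_j J~* X*_j over connections with X*=1
        var = bsyn * (np.abs(J) @ x)
        drive = drive + np.sqrt(var) * rng.standard_normal(n)
    thresh = n + np.sqrt(n) * bint * rng.standard_normal(n)
    return (drive - thresh > 0).astype(np.int8)


def deviation_threshold(spec: NetworkSpec) -> float:
    """Midpoint between the two modes of the retrieval error fraction:
    the learned rate r and the random-state distance 2f(1-f)."""
    f = float(spec.f.mean())
    r = float(spec.r.mean())
    return 0.5 * (r + 2.0 * f * (1.0 - f))


def retrieve(
    Jmat: WeightMatrix,
    seq: MemorySequence,
    spec: NetworkSpec,
    beta_retr: float | None = None,
    seed: int | np.random.Generator = 0,
    r_retr: float = 0.0,
    threshold: float | None = None,
    beta_syn: float | None = None,
    beta_int: float | None = None,
) -> RetrievalResult:
    """Replay a loaded sequence from its first state.

    The initial state X^1 carries no injected errors; at later steps only
    the network's own output errors propagate (``r_retr`` adds extra input
    flips from step 2 on and defaults to 0).  ``retrieved_length`` counts
    the steps before the error fraction first exceeds the deviation
    threshold.
    """
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, "misc")
    thr = deviation_threshold(spec) if threshold is None else threshold
    state = seq.states[0].astype(np.int8)
    errs = np.empty(seq.m)
    retrieved = seq.m
    for mu in range(seq.m):
        state = step(
            Jmat, state, spec,
            beta_retr=beta_retr, beta_syn=beta_syn, beta_int=beta_int,
            r_step=(r_retr if mu > 0 else 0.0), rng=rng,
        )
        errs[mu] = float(np.mean(state != seq.states[mu + 1]))
        if errs[mu] > thr and retrieved == seq.m:
            retrieved = mu  # steps completed before the first deviation
    complete = retrieved == seq.m
    return RetrievalResult(
        complete=complete, retrieved_length=retrieved, error_fraction_trace=errs
    )


def retrieval_statistics(
    Jmat: WeightMatrix,
    seq: MemorySequence,
    spec: NetworkSpec,
    beta_retr: float | None = None,
    trials: int = 100,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Monte-Carlo retrieval probability and mean retrieved length
    fraction with their standard errors."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = spawn_rng(seed, "misc")
    completes = np.empty(trials)
    fractions = np.empty(trials)
    for t in range(trials):
        res = retrieve(Jmat, seq, spec, beta_retr=beta_retr, seed=rng, **kwargs)
        completes[t] = res.complete
        fractions[t] = res.retrieved_length / seq.m
    p = completes.mean()
    return dict(
        retrieval_probability=float(p),
        retrieval_probability_se=float(np.sqrt(p * (1 - p) / trials)),
        mean_length_fraction=float(fractions.mean()),
        mean_length_fraction_se=float(fractions.std(ddof=1) / np.sqrt(trials))
        if trials > 1
        else np.nan,
        trials=trials,
    )


def spontaneous_run(
    Jmat: WeightMatrix,
    spec: NetworkSpec,
    f0: float = 0.2,
    T: int = 1000,
    beta_retr: float | None = None,
    seed: int = 0,
    **kwargs,
) -> ActivityRaster:
    """Free-running dynamics from a random initial state of firing
    probability ``f0``, recorded for ``T`` steps (row 0 = initial)."""
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = spawn_rng(seed, "misc")
    states = np.empty((T, spec.n), dtype=np.int8)
    states[0] = (rng.random(spec.n) < f0).astype(np.int8)
    for t in range(1, T):
        states[t] = step(Jmat, states[t - 1], spec, beta_retr=beta_retr, rng=rng, **kwargs)
    return ActivityRaster(states=states)


def _cv_isi(states: np.ndarray) -> float:
    cvs = []
    for i in range(states.shape[1]):
        times = np.flatnonzero(states[:, i])
        if times.size < 3:
            continue  # fewer than 2 ISIs
        isi = np.diff(times)
        mu = isi.mean()
        if mu > 0:
            cvs.append(isi.std(ddof=1) / mu)
    if not cvs:
        raise ValueError("no neuron has enough spikes for an ISI CV")
    return float(np.mean(cvs))


def _cross_corr(states: np.ndarray) -> float:
    var = states.std(axis=0)
    keep = var > 0
    if keep.sum() < 2:
        raise ValueError("fewer than two non-degenerate spike trains")
    cc = np.corrcoef(states[:, keep].T)
    iu = np.triu_indices_from(cc, k=1)
    return float(np.nanmean(cc[iu]))


def dynamics_stats(
    raster: ActivityRaster,
    Jmat: WeightMatrix,
    spec: NetworkSpec,
    transient: int = TRANSIENT_DISCARD,
) -> DynamicsStats:
    """Summary statistics of a spontaneous run (see module docstring).

    ``ei_anticorr`` is reported with the balanced-regime sign convention:
    the positive magnitude of the (negative) correlation between each
    neuron's summed excitatory input and its summed signed inhibitory
    input over time.
    """
    states = raster.states[transient:] if raster.T > transient + 2 else raster.states
    if states.sum() == 0:
        raise ValueError("all-silent raster: dynamics statistics undefined")
    J = Jmat.J_tilde
    g = spec.g
    exc_cols = g > 0
    inh_cols = g < 0

    cv = _cv_isi(states)
    cc = _cross_corr(states)

    X = states.astype(float)
    e_in = X[:, exc_cols] @ J[:, exc_cols].T  # T x N excitatory drive
    i_in = X[:, inh_cols] @ J[:, inh_cols].T  # T x N signed inhibitory drive
    cors = []
    for i in range(spec.n):
        if e_in[:, i].std() > 0 and i_in[:, i].std() > 0:
            c = np.corrcoef(e_in[:, i], i_in[:, i])[0, 1]
            cors.append(-c)  # balance: strongly negative correlation
    ei = float(np.mean(cors)) if cors else np.nan

    conn = connectivity_stats(Jmat, spec)
    return DynamicsStats(
        cv_isi=cv,
        cross_corr=cc,
        ei_anticorr=ei,
        pcon_inh=conn["inh"]["P_con"],
        pcon_exc=conn["exc"]["P_con"],
        cv_w_inh=conn["inh"]["cv"],
        cv_w_exc=conn["exc"]["cv"],
    )


def connectivity_stats(Jmat: WeightMatrix, spec: NetworkSpec) -> dict:
    """Connection probability and CV of non-zero weight magnitudes per
    presynaptic sign class (columns of the weight matrix)."""
    J = Jmat.J_tilde
    w_ref = float(spec.w_tilde.mean())
    mask = connection_mask(J, w_ref)
    out = {}
    for name, cols in (("inh", spec.g < 0), ("exc", spec.g > 0)):
        sub = np.abs(J[:, cols])
        present = mask[:, cols]
        p = float(present.mean()) if present.size else np.nan
        vals = sub[present]
        if vals.size >= 2 and vals.mean() > 0:
            cv = float(vals.std(ddof=1) / vals.mean())
        else:
            cv = np.nan
        out[name] = dict(P_con=p, cv=cv, n_present=int(present.sum()))
    return out
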