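"""Online perceptron-type learning under errors and noise.

The update is triggered by a mismatch between the noisy output
y* = theta(sum_j J*_j X*_j - h*) and the noise-free target y, and applies
four consecutive steps:

1. J_j += gamma (h/N) (2y - 1) X*_j        (stochastic perceptron step)
2. J_j  = 0 wherever J_j g_j < 0           (Dale sign projection)
3. J_j += (w - (1/N) sum |J_j|) g_j        (l1-norm restoration)
4. J_j  = 0 wherever J_j g_j < 0           (second sign projection)

Steps 3-4 are a single pass, exactly as the rule is stated; the residual
norm error they can leave behind is recorded per epoch.  Training presents
the associations in sequence order, one per step, with input flips,
synaptic and intrinsic noise redrawn independently at every presentation.
After each epoch the deterministic Gaussian feasibility criterion of the
current mean weights is evaluated and training stops once it holds (a
Monte-Carlo stopping alternative is available via ``stopping="mc"``).

All computations use scaled weights (h = 1, J~ = N J / h), in which the
update steps read J~_j += gamma (2y-1) X*_j etc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .loading import AssociationSet, estimate_capacity, CapacityEstimate
from .margin import (
    association_margins,
    flip_averaged_input,
    flip_variance_input,
    output_margins,
)
from .params import NetworkSpec

__all__ = [
    "TrainingState",
    "update_step",
    "train_neuron",
    "perceptron_capacity",
]


@dataclass
class TrainingState:
    weights: np.ndarray
    epoch: int
    error_trace: np.ndarray  # per-epoch Gaussian output-error probability
    norm_residual: np.ndarray  # per-epoch |mean|J~| - w~| after updates
    converged: bool


def update_step(
    J_tilde: np.ndarray,
    X_star: np.ndarray,
    y: int,
    gamma: float,
    g: np.ndarray,
    w_tilde: float,
) -> np.ndarray:
    """One four-step weight update in scaled units (pure-numpy reference;
    the training loop uses an equivalent compiled kernel)."""
    J = np.asarray(J_tilde, dtype=float).copy()
    g = np.asarray(g, dtype=float)
    J += gamma * (2 * y - 1) * np.asarray(X_star, dtype=float)
    J[J * g < 0] = 0.0
    J += (w_tilde - np.abs(J).mean()) * g
    J[J * g < 0] = 0.0
    return J


@njit(cache=True)
def _flip_subset(idx, p, p_max, out):  # pragma: no cover - numba helper
    """Sample the flipped entries of an index list by geometric skipping
    at rate p_max with per-entry thinning to p[idx]; returns the count."""
    k = 0
    cnt = 0
    size = idx.shape[0]
    if p_max <= 0.0:
        return 0
    log1mp = np.log1p(-p_max) if p_max < 1.0 else -np.inf
    while k < size:
        if p_max < 1.0:
            u = 1.0 - np.random.random()
            k += int(np.floor(np.log(u) / log1mp))
        if k >= size:
            break
        j = idx[k]
        if p_max >= 1.0 or np.random.random() * p_max < p[j]:
            out[cnt] = j
            cnt += 1
        k += 1
    return cnt


@njit(cache=True)
def _train_kernel(
    ones_flat, ones_off, zeros_flat, zeros_off, y, An, Vn, D, g,
    p_minus, p_plus, pm_max, pp_max,
    beta_syn, beta_int, w_tilde, gamma,
    max_epochs, seed, J, err_trace, norm_trace, record,
):  # pragma: no cover - exercised via train_neuron
    m = y.shape[0]
    n = J.shape[0]
    np.random.seed(seed)
    sqrt_n = np.sqrt(n)
    converged = False
    epochs = 0
    failed = np.empty(n, dtype=np.int64)
    added = np.empty(n, dtype=np.int64)
    Jg = np.empty(n)
    J2 = np.empty(n)
    for epoch in range(max_epochs):
        epochs = epoch + 1
        for mu in range(m):
            ones = ones_flat[ones_off[mu]:ones_off[mu + 1]]
            zeros = zeros_flat[zeros_off[mu]:zeros_off[mu + 1]]
            nf = _flip_subset(ones, p_minus, pm_max, failed)
            na = _flip_subset(zeros, p_plus, pp_max, added)
            # drive over X* = (ones minus failures) plus erroneous spikes;
            # failed entries are inactive and carry no synaptic noise
            dot = 0.0
            fi = 0
            for k in range(ones.shape[0]):
                j = ones[k]
                if fi < nf and failed[fi] == j:
                    fi += 1
                    continue
                if beta_syn > 0.0:
                    dot += J[j] + np.sqrt(beta_syn * abs(J[j])) * np.random.normal()
                else:
                    dot += J[j]
            for k in range(na):
                j = added[k]
                if beta_syn > 0.0:
                    dot += J[j] + np.sqrt(beta_syn * abs(J[j])) * np.random.normal()
                else:
                    dot += J[j]
            thresh = n + sqrt_n * beta_int * np.random.normal()
            y_star = 1 if dot - thresh > 0.0 else 0
            if y_star != y[mu]:
                sgn = 2.0 * y[mu] - 1.0
                # step 1 on the active inputs X* = 1, fused with the step-2
                # sign projection (element-wise, no cross-term dependence)
                fi = 0
                for k in range(ones.shape[0]):
                    j = ones[k]
                    if fi < nf and failed[fi] == j:
                        fi += 1
                        continue
                    J[j] += gamma * sgn
                    if J[j] * g[j] < 0.0:
                        J[j] = 0.0
                for k in range(na):
                    j = added[k]
                    J[j] += gamma * sgn
                    if J[j] * g[j] < 0.0:
                        J[j] = 0.0
                # steps 3-4: single-pass norm restoration + projection
                norm = 0.0
                for j in range(n):
                    norm += abs(J[j])
                c = w_tilde - norm / n
                for j in range(n):
                    J[j] += c * g[j]
                    if J[j] * g[j] < 0.0:
                        J[j] = 0.0
        # epoch end: deterministic Gaussian feasibility of the mean weights
        for j in range(n):
            Jg[j] = J[j] * g[j]
            J2[j] = J[j] * J[j]
        feasible = True
        err_sum = 0.0
        for mu in range(m):
            I = np.dot(J, An[mu]) - 1.0
            S = np.dot(J2, Vn[mu]) + beta_syn * np.dot(Jg, An[mu]) + beta_int * beta_int
            sig = np.sqrt(S / n)
            signed = (2.0 * y[mu] - 1.0) * I
            if signed < D[mu] * sig:
                feasible = False
            err_sum += 0.5 * math.erfc(signed / (sig * np.sqrt(2.0)))
        if record:
            err_trace[epoch] = err_sum / m
            norm = 0.0
            for j in range(n):
                norm += abs(J[j])
            norm_trace[epoch] = abs(norm / n - w_tilde)
        if feasible:
            converged = True
            break
    return converged, epochs


def _mc_feasible(J, assoc, f, r, g, beta_syn, beta_int, om, rng, draws=400):
    """Monte-Carlo stopping check: empirical output error rates of every
    association stay within the tolerated p+- bounds."""
    from .synthesis import inject_spiking_errors

    n = assoc.n
    y = assoc.y
    for mu in range(assoc.m):
        Xs = inject_spiking_errors(
            np.repeat(assoc.X[mu][None, :], draws, axis=0), f, r, rng
        ).astype(float)
        Js = J[None, :] + np.sqrt(beta_syn * np.abs(J))[None, :] * rng.standard_normal((draws, n))
        margins = (Xs * Js).sum(axis=1) - n - np.sqrt(n) * beta_int * rng.standard_normal(draws)
        errs = (margins > 0) != (y[mu] == 1)
        rate = errs.mean()
        # tolerated rate: p_minus for y=1 (failures), p_plus for y=0
        p_tol = r if np.isscalar(r) else float(np.mean(r))
        f_out = float(np.mean(f)) if not np.isscalar(f) else f
        bound = p_tol / (2 * f_out) if y[mu] == 1 else p_tol / (2 * (1 - f_out))
        if rate > bound:
            return False
    return True


def train_neuron(
    assoc: AssociationSet,
    f: np.ndarray | float,
    r: np.ndarray | float,
    g: np.ndarray,
    beta_syn: float,
    beta_int: float,
    w_tilde: float,
    f_out: float,
    r_out: float,
    gamma: float = 0.1,
    max_epochs: int = 10**6,
    seed: int = 0,
    record_trace: bool = True,
    stopping: str = "gaussian",
) -> TrainingState:
    """Train one neuron online until the stopping criterion holds or the
    epoch cap is reached.  Non-convergence is a reported state, not an
    error."""
    if stopping not in ("gaussian", "mc"):
        raise ValueError("stopping must be 'gaussian' or 'mc'")
    m, n = assoc.m, assoc.n
    f_arr = np.broadcast_to(np.asarray(f, dtype=float), (n,)).copy()
    r_arr = np.broadcast_to(np.asarray(r, dtype=float), (n,)).copy()
    g_arr = np.broadcast_to(np.asarray(g, dtype=float), (n,)).copy()
    A = flip_averaged_input(assoc.X, f_arr[None, :], r_arr[None, :])
    V = flip_variance_input(assoc.X, f_arr[None, :], r_arr[None, :])
    om = output_margins(r_out, f_out)
    y = assoc.y.astype(np.int8)
    D = om.D_minus * y + om.D_plus * (1 - y)
    p_minus = r_arr / (2.0 * f_arr)
    p_plus = r_arr / (2.0 * (1.0 - f_arr))
    J = np.full(n, w_tilde) * g_arr  # uniform start satisfying both constraints

    # ragged per-association index lists of active / silent inputs
    ones_lists = [np.flatnonzero(assoc.X[mu]).astype(np.int64) for mu in range(m)]
    zeros_lists = [np.flatnonzero(assoc.X[mu] == 0).astype(np.int64) for mu in range(m)]
    ones_off = np.concatenate([[0], np.cumsum([o.size for o in ones_lists])]).astype(np.int64)
    zeros_off = np.concatenate([[0], np.cumsum([z.size for z in zeros_lists])]).astype(np.int64)
    ones_flat = (
        np.concatenate(ones_lists) if ones_off[-1] else np.zeros(0, dtype=np.int64)
    )
    zeros_flat = (
        np.concatenate(zeros_lists) if zeros_off[-1] else np.zeros(0, dtype=np.int64)
    )
    An = np.ascontiguousarray(A / n)
    Vn = np.ascontiguousarray(V / n)
    kernel_args = (
        ones_flat, ones_off, zeros_flat, zeros_off, y, An, Vn,
        (om.D_minus * y + om.D_plus * (1 - y)).astype(float), g_arr,
        p_minus, p_plus, float(p_minus.max()), float(p_plus.max()),
    )

    if stopping == "gaussian":
        err_trace = np.zeros(max_epochs if record_trace else 1, dtype=np.float64)
        norm_trace = np.zeros_like(err_trace)
        converged, epochs = _train_kernel(
            *kernel_args,
            float(beta_syn), float(beta_int), float(w_tilde), float(gamma),
            int(max_epochs), int(seed) & 0x7FFFFFFF, J,
            err_trace, norm_trace, record_trace,
        )
    else:
        rng = np.random.default_rng(seed)
        chunk = 200
        err_list, norm_list = [], []
        converged, epochs = False, 0
        while epochs < max_epochs and not converged:
            todo = min(chunk, max_epochs - epochs)
            et = np.zeros(todo)
            nt = np.zeros(todo)
            _, ran = _train_kernel(
                *kernel_args,
                float(beta_syn), float(beta_int), float(w_tilde), float(gamma),
                todo, int(rng.integers(2**31)), J, et, nt, True,
            )
            epochs += ran
            err_list.append(et[:ran])
            norm_list.append(nt[:ran])
            converged = _mc_feasible(
                J, assoc, f_arr, r_arr, g_arr, beta_syn, beta_int, om, rng
            )
        err_trace = np.concatenate(err_list) if err_list else np.zeros(0)
        norm_trace = np.concatenate(norm_list) if norm_list else np.zeros(0)
        epochs_ran = epochs
        return TrainingState(
            weights=J, epoch=epochs_ran, error_trace=err_trace,
            norm_residual=norm_trace, converged=bool(converged),
        )

    return TrainingState(
        weights=J,
        epoch=epochs,
        error_trace=err_trace[:epochs] if record_trace else err_trace[:0],
        norm_residual=norm_trace[:epochs] if record_trace else norm_trace[:0],
        converged=bool(converged),
    )


def perceptron_capacity(
    spec: NetworkSpec,
    reps: int = 20,
    seed: int = 0,
    gamma: float = 0.1,
    max_epochs: int = 10**5,
    bracket: tuple[int, int] | None = None,
    stopping: str = "gaussian",
) -> CapacityEstimate:
    """Memory capacity with the perceptron trainer as the feasibility
    oracle (same bisection/logistic protocol as the optimizer route)."""

    def loader(assoc, seed=0, **prob):
        state = train_neuron(
            assoc,
            f=prob["f"], r=prob["r"], g=prob["g"],
            beta_syn=prob["beta_syn"], beta_int=prob["beta_int"],
            w_tilde=prob["w_tilde"], f_out=prob["f_out"], r_out=prob["r_out"],
            gamma=gamma, max_epochs=max_epochs, seed=seed, record_trace=False,
            stopping=stopping,
        )
        return state.converged

    return estimate_capacity(spec, reps=reps, seed=seed, loader=loader, bracket=bracket)
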