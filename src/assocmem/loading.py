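"""Finite-N memory loading by slack-sum minimization.

Each neuron independently finds scaled input weights J~ satisfying the
Gaussian margin inequality of every association, the Dale sign constraints
J~_j g_j >= 0 and the l1-norm equality (1/N) sum_j |J~_j| = w~.  The
problem is made always-feasible with one slack variable per association
and the slack sum is minimized; zero total slack means the association set
is learnable.

In the magnitude variables q_j = g_j J~_j >= 0 the margin constraint reads

    (2y-1) ((1/N) sum_j g_j q_j A_j - 1) + s >= (D_y / sqrt(N)) sigma(q)

with sigma(q) = sqrt((1/N) sum_j (q_j^2 V_j + beta_syn q_j A_j) + beta_int^2),
a convex (norm-like) function of q, so the whole program is convex and any
KKT point is the global optimum.  It is solved by sequential linear
programming: sigma is replaced by its first-order expansion around the
current iterate and the LP is solved exactly (HiGHS); at a fixed point the
LP optimality conditions are the KKT conditions of the original program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .margin import (
    OutputMargins,
    association_margins,
    flip_averaged_input,
    flip_variance_input,
    output_margins,
)
from .params import NetworkSpec, spawn_rng
from .synthesis import MemorySequence, generate_sequence

__all__ = [
    "AssociationSet",
    "LoadResult",
    "CapacityEstimate",
    "WeightMatrix",
    "load_neuron",
    "success_probability",
    "estimate_capacity",
    "load_network",
    "SolverError",
]

#: a scaled weight below this fraction of w~ counts as an absent connection
ZERO_WEIGHT_REL_TOL = 1e-8
#: slack_sum below this fraction of m * w~ declares the load feasible
FEASIBLE_REL_TOL = 1e-6


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class AssociationSet:
    """Inputs X (m x N binary) and target output bits y (length m)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.int8)
        y = np.asarray(self.y, dtype=np.int8)
        if X.ndim != 2 or y.shape != (X.shape[0],):
            raise ValueError("X must be m x N and y of length m")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_sequence(cls, seq: MemorySequence, neuron: int) -> "AssociationSet":
        """Association mu: input state X^mu -> the neuron's bit of X^(mu+1)."""
        return cls(X=seq.inputs(), y=seq.targets()[:, neuron])

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class LoadResult:
    weights: np.ndarray  # scaled weights J~
    slack_sum: float
    feasible: bool
    solver_status: dict = field(default_factory=dict)


@dataclass
class CapacityEstimate:
    alpha: float
    success_curve: list  # (m, success probability, repetitions)
    ci: tuple  # bootstrap interval on alpha


@dataclass
class WeightMatrix:
    """N x N matrix of scaled mean weights; row i holds the input weights
    of neuron i (column j = presynaptic neuron j)."""

    J_tilde: np.ndarray
    feasible: np.ndarray  # per-neuron flags
    spec: NetworkSpec | None = None


def _margin_terms(assoc: AssociationSet, f, r, g, beta_syn, beta_int):
    n = assoc.n
    f = np.broadcast_to(np.asarray(f, dtype=float), (n,))
    r = np.broadcast_to(np.asarray(r, dtype=float), (n,))
    g = np.broadcast_to(np.asarray(g, dtype=float), (n,))
    A = flip_averaged_input(assoc.X, f[None, :], r[None, :])
    V = flip_variance_input(assoc.X, f[None, :], r[None, :])
    return A, V, g


def load_neuron(
    assoc: AssociationSet,
    f: np.ndarray | float,
    r: np.ndarray | float,
    g: np.ndarray,
    beta_syn: float,
    beta_int: float,
    w_tilde: float,
    f_out: float,
    r_out: float,
    max_iter: int = 80,
    step_tol: float = 1e-10,
) -> LoadResult:
    """Load one neuron's associations by slack-sum minimization.

    Returns scaled weights satisfying the sign constraints exactly and the
    norm equality to ~1e-12 relative; ``feasible`` is True when the
    minimized slack sum is below ``FEASIBLE_REL_TOL * m * w_tilde``.
    """
    if assoc.m < 1:
        raise ValueError("need at least one association")
    om = output_margins(r_out, f_out)
    A, V, g = _margin_terms(assoc, f, r, g, beta_syn, beta_int)
    m, n = assoc.m, assoc.n
    y = assoc.y.astype(float)
    sgn = 2.0 * y - 1.0  # +1 for target 1, -1 for target 0
    D = om.D_minus * y + om.D_plus * (1.0 - y)
    gA = g[None, :] * A  # the inputs as seen through signed weights

    # linear part of the margin: (2y-1)((1/N) (gA) q - 1)
    lin = sgn[:, None] * gA / n

    noisy = beta_syn > 0 or beta_int > 0 or np.any(V > 0)
    feas_tol = FEASIBLE_REL_TOL * m * w_tilde

    def sigma_and_grad(q):
        S = (V @ (q * q) + beta_syn * (A @ q)) / n + beta_int**2
        sig = np.sqrt(np.maximum(S, 0.0) / n)
        denom = np.maximum(sig, 1e-300)
        grad = (2.0 * V * q[None, :] + beta_syn * A) / (2.0 * denom[:, None] * n**2)
        return sig, grad

    def merit(q):
        """Exact slack sum sum_mu max(0, D sigma - margin): convex in q."""
        S = (V @ (q * q) + beta_syn * (A @ q)) / n + beta_int**2
        sig = np.sqrt(np.maximum(S, 0.0) / n)
        return float(np.maximum(D * sig - (lin @ q - sgn) * 1.0, 0.0).sum())

    def solve_lp(q0, delta):
        if noisy:
            sig0, gsig = sigma_and_grad(q0)
            Arow = lin - D[:, None] * gsig
            rhs = sgn + D * (sig0 - gsig @ q0)
        else:
            Arow = lin
            rhs = sgn.copy()
        # constraints: Arow q + s >= rhs  ->  -Arow q - s <= -rhs
        A_ub = np.hstack([-Arow, -np.eye(m)])
        b_ub = -rhs
        A_eq = np.concatenate([np.full(n, 1.0 / n), np.zeros(m)])[None, :]
        c = np.concatenate([np.zeros(n), np.ones(m)])
        lo = np.maximum(q0 - delta, 0.0)
        hi = q0 + delta
        bounds = [(lo[j], hi[j]) for j in range(n)] + [(0, None)] * m
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[w_tilde],
            bounds=bounds, method="highs",
        )
        if not res.success:
            raise SolverError(f"LP subproblem failed: {res.message}")
        return res.x[:n], float(res.x[n:].sum())

    q = np.full(n, w_tilde)  # uniform start on the norm simplex
    phi = merit(q)
    delta = 4.0 * w_tilde
    iterations = 0
    if not noisy:
        q, _ = solve_lp(q, np.inf)
        phi = merit(q)
        iterations = 1
    else:
        for it in range(1, max_iter + 1):
            iterations = it
            if phi <= 0.25 * feas_tol or delta < 1e-12 * w_tilde:
                break
            try:
                q_new, phi_pred = solve_lp(q, delta)
            except SolverError:
                delta *= 0.25  # ill-conditioned subproblem: tighten and retry
                continue
            pred_red = phi - phi_pred  # >= 0: LP relaxes the constraints
            phi_new = merit(q_new)
            actual_red = phi - phi_new
            if pred_red <= step_tol * max(1.0, phi):
                break  # first-order optimal within the trust region
            if actual_red >= 0.1 * pred_red:
                q = np.maximum(q_new, 0.0)
                total = q.sum() / n
                if total > 0:
                    q *= w_tilde / total  # keep the norm equality exact
                phi = merit(q)
                if actual_red >= 0.7 * pred_red:
                    delta = min(delta * 2.0, 200.0 * w_tilde)
            else:
                delta *= 0.25

    # exact constraint restoration (LP tolerances can leave ~1e-12 dust)
    q = np.maximum(q, 0.0)
    total = q.sum() / n
    if total > 0:
        q *= w_tilde / total
    J_tilde = g * q

    # true nonlinear slacks of the returned weights
    margins = association_margins(
        J_tilde, assoc.X, y, f, r, g, beta_syn, beta_int, om
    )
    slack = float(np.maximum(-margins, 0.0).sum())
    feasible = slack < FEASIBLE_REL_TOL * m * w_tilde
    return LoadResult(
        weights=J_tilde,
        slack_sum=slack,
        feasible=feasible,
        solver_status=dict(iterations=iterations, converged_step=True),
    )


def centroid_solution(
    assoc: AssociationSet,
    result: LoadResult,
    f: np.ndarray | float,
    r: np.ndarray | float,
    g: np.ndarray,
    beta_syn: float,
    beta_int: float,
    w_tilde: float,
    f_out: float,
    r_out: float,
    n_vertices: int = 24,
    seed: int = 0,
) -> np.ndarray:
    """Centroid of the optimal face of the slack-minimization program.

    The minimized slack sum is attained on a face of the (linearized)
    constraint polytope; because the program is convex, every convex
    combination of minimizers is again a minimizer.  A single LP basic
    solution is an extreme point of that face with at most m+1 non-zero
    weights, which understates the connection probability of the typical
    solution; averaging basic solutions obtained under random auxiliary
    objectives approximates the face centroid, the analogue of the
    replica-typical weight vector.  Returns scaled weights J~.
    """
    om = output_margins(r_out, f_out)
    A, V, g = _margin_terms(assoc, f, r, g, beta_syn, beta_int)
    m, n = assoc.m, assoc.n
    y = assoc.y.astype(float)
    sgn = 2.0 * y - 1.0
    D = om.D_minus * y + om.D_plus * (1.0 - y)
    lin = sgn[:, None] * (g[None, :] * A) / n
    q_star = np.abs(result.weights)

    S = (V @ (q_star * q_star)) / n + beta_int**2
    sig = np.sqrt(np.maximum(S, 0.0) / n)
    dsig = (2.0 * V * q_star[None, :] + beta_syn * A) / (
        2.0 * np.maximum(sig, 1e-300)[:, None] * n**2
    )
    Arow = lin - D[:, None] * dsig
    rhs = sgn + D * (sig - dsig @ q_star)
    phi_star = float(np.maximum(rhs - Arow @ q_star, 0.0).sum())

    A_ub = np.vstack(
        [
            np.hstack([-Arow, -np.eye(m)]),
            np.concatenate([np.zeros(n), np.ones(m)])[None, :],
        ]
    )
    b_ub = np.concatenate([-rhs, [phi_star * (1 + 1e-9) + 1e-12]])
    A_eq = np.concatenate([np.full(n, 1.0 / n), np.zeros(m)])[None, :]
    rng = np.random.default_rng(seed)
    qs = []
    for _ in range(n_vertices):
        c = np.concatenate([rng.standard_normal(n), np.zeros(m)])
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[w_tilde],
            bounds=[(0, None)] * (n + m), method="highs",
        )
        if res.success:
            qs.append(res.x[:n])
    if not qs:
        return result.weights
    q = np.mean(qs, axis=0)
    q = np.maximum(q, 0.0)
    total = q.sum() / n
    if total > 0:
        q *= w_tilde / total
    return g * q


def _neuron_problem(spec: NetworkSpec, neuron: int):
    """Per-input and output parameters of one neuron in a network."""
    p = spec.neurons[neuron]
    return dict(
        f=spec.f, r=spec.r, g=spec.g.astype(float),
        beta_syn=p.beta_syn, beta_int=p.beta_int,
        w_tilde=float(spec.w_tilde[neuron]),
        f_out=p.f, r_out=p.r,
    )


def success_probability(
    spec: NetworkSpec,
    m: int,
    reps: int,
    seed: int,
    loader=None,
) -> tuple[float, float]:
    """Fraction of independent random sequences learnable by neuron 0 of
    ``spec``, with its binomial standard error.

    ``loader(assoc, **problem) -> bool`` may replace the default
    slack-minimization feasibility oracle (e.g. the perceptron trainer).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    prob = _neuron_problem(spec, 0)
    wins = 0
    for rep in range(reps):
        seq = generate_sequence(spec, m, seed=seed * 100003 + rep)
        assoc = AssociationSet.from_sequence(seq, 0)
        if loader is None:
            wins += load_neuron(assoc, **prob).feasible
        else:
            wins += bool(loader(assoc, **prob, seed=seed * 100003 + rep))
    p = wins / reps
    se = np.sqrt(p * (1 - p) / reps)
    return p, float(se)


def _logistic_fit(curve):
    """MLE logistic fit p(m) = 1/(1+exp((m - m50)/s)) on aggregated
    Bernoulli outcomes; returns m50 (falls back to None on failure)."""
    from scipy.optimize import minimize

    ms = np.array([c[0] for c in curve], dtype=float)
    ps = np.array([c[1] for c in curve], dtype=float)
    ks = np.array([round(c[1] * c[2]) for c in curve], dtype=float)
    ns = np.array([c[2] for c in curve], dtype=float)
    if len(ms) < 2 or ps.min() > 0.5 or ps.max() < 0.5:
        return None

    def nll(theta):
        m50, log_s = theta
        z = (ms - m50) / np.exp(log_s)
        # p = sigmoid(-z)
        logp = -np.logaddexp(0.0, z)
        log1mp = -np.logaddexp(0.0, -z)
        return -(ks * logp + (ns - ks) * log1mp).sum()

    w = ns.sum()
    m0 = float(np.interp(0.5, ps[::-1], ms[::-1])) if ps[0] > ps[-1] else ms.mean()
    best = minimize(nll, x0=[m0, np.log(max(ms.std(), 1.0) / 4 + 1)], method="Nelder-Mead")
    if not np.isfinite(best.fun):
        return None
    return float(best.x[0])


def estimate_capacity(
    spec: NetworkSpec,
    reps: int = 20,
    seed: int = 0,
    loader=None,
    bracket: tuple[int, int] | None = None,
    n_boot: int = 200,
) -> CapacityEstimate:
    """Memory capacity alpha = m*/N at 0.5 learning-success probability.

    Geometric bracketing of the 0.5 crossing, bisection to delta-m = 1,
    then a logistic fit over all evaluated load points; the bootstrap CI
    resamples the per-point binomial counts and refits.
    """
    n = spec.n
    lo, hi = bracket if bracket is not None else (max(n // 8, 1), 2 * n)
    curve = {}

    def success(m):
        if m not in curve:
            p, _ = success_probability(spec, m, reps, seed + m, loader=loader)
            curve[m] = (p, reps)
        return curve[m][0]

    m = lo
    # walk geometrically to straddle the 0.5 crossing
    while success(m) < 0.5 and m > 1:
        m = max(m // 2, 1)
    if success(m) < 0.5:
        raise ValueError("success probability below 0.5 even at m = 1")
    m_lo = m
    m_hi = m
    while success(m_hi) >= 0.5:
        m_lo = m_hi
        nxt = min(m_hi * 2, max(hi, m_hi + 1))
        if nxt == m_hi:
            nxt = min(m_hi * 2, 2 * n + 1)
        if nxt == m_hi:
            raise ValueError("no 0.5 crossing up to m = 2N")
        m_hi = nxt
    while m_hi - m_lo > 1:
        mid = (m_lo + m_hi) // 2
        if success(mid) >= 0.5:
            m_lo = mid
        else:
            m_hi = mid

    pts = sorted(curve.items())
    curve_list = [(mm, p, rr) for mm, (p, rr) in pts]
    m50 = _logistic_fit(curve_list)
    if m50 is None:
        m50 = 0.5 * (m_lo + m_hi)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bcurve = []
        for mm, p, rr in curve_list:
            k = rng.binomial(rr, p)
            bcurve.append((mm, k / rr, rr))
        b50 = _logistic_fit(bcurve)
        if b50 is not None:
            boots.append(b50 / n)
    ci = (
        tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    )
    return CapacityEstimate(alpha=m50 / n, success_curve=curve_list, ci=ci)


def load_network(
    seq: MemorySequence,
    spec: NetworkSpec,
    autapses: bool = True,
    **solver_opts,
) -> WeightMatrix:
    """Load every neuron of the network independently on the sequence.

    Row i of the result is neuron i's input weight vector.  With
    ``autapses=False`` the self-weight is clamped to zero by excluding it
    from the optimization.
    """
    n = spec.n
    J = np.zeros((n, n))
    ok = np.zeros(n, dtype=bool)
    X = seq.inputs()
    Y = seq.targets()
    failures = []
    for i in range(n):
        prob = _neuron_problem(spec, i)
        assoc = AssociationSet(X=X, y=Y[:, i])
        if not autapses:
            keep = np.arange(n) != i
            sub = AssociationSet(X=X[:, keep], y=Y[:, i])
            res = load_neuron(
                sub,
                f=prob["f"][keep], r=prob["r"][keep], g=prob["g"][keep],
                beta_syn=prob["beta_syn"], beta_int=prob["beta_int"],
                w_tilde=prob["w_tilde"], f_out=prob["f_out"],
                r_out=prob["r_out"], **solver_opts,
            )
            J[i, keep] = res.weights
        else:
            res = load_neuron(assoc, **prob, **solver_opts)
            J[i] = res.weights
        ok[i] = res.feasible
        if not res.feasible:
            failures.append(i)
    return WeightMatrix(J_tilde=J, feasible=ok, spec=spec)


def connection_mask(J_tilde: np.ndarray, w_tilde: float) -> np.ndarray:
    """Boolean mask of present connections (|J~| above the zero-calling
    threshold)."""
    return np.abs(J_tilde) > ZERO_WEIGHT_REL_TOL * w_tilde
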