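"""Replica-symmetric capacity of a sign- and norm-constrained noisy neuron.

At the critical memory load the space of admissible weight vectors shrinks
to a point and the saddle-point conditions of the replica (Gardner-type)
calculation reduce to a small nonlinear system.  Two parametrizations are
implemented:

* ``solve_homogeneous`` — all inputs share (f_in, r_in) and split into an
  inhibitory and an excitatory class.  Intrinsic and synaptic noise enter
  only through the postsynaptic noise strength
  ``beta = sqrt(beta_int^2 + w~ beta_syn f_in)``, and the spiking-error
  probabilities only through the parameters xi and zeta.
* ``solve_heterogeneous`` — an explicit list of inputs (f_j, r_j, g_j,
  beta_syn_j); the six saddle-point latents (u+, u-, x, eta, y, z) are
  solved for directly.

Both return the critical capacity alpha_c, per-class (or per-input)
connection probabilities and the parameters of the truncated-Gaussian
distribution of non-zero scaled weights: an input has probability
1 - P_con of exactly zero weight, and non-zero weights follow a Gaussian
of scale sigma * w~ truncated to the input's sign.

``solve_kappa`` implements the classical robustness-parameter model that
the present model reduces to when r_in = 0; the reduction eliminates the
output-margin factors analytically, so the two solvers agree exactly for
any (beta, r_out) pair with the same rho = beta * zeta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root
from scipy.special import erfcx, erfinv
from scipy.stats import truncnorm

from .margin import input_coefficients, output_margins

__all__ = [
    "efd",
    "postsynaptic_noise",
    "xi_zeta",
    "kappa_rho",
    "HomogeneousSolution",
    "HeterogeneousSolution",
    "solve_homogeneous",
    "solve_heterogeneous",
    "solve_kappa",
    "weight_distribution",
    "replica_sweep",
    "ReplicaConvergenceError",
]

_SQRT_PI = np.sqrt(np.pi)


class ReplicaConvergenceError(RuntimeError):
    """Raised when the saddle-point solver fails to converge; carries the
    best residual reached."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(f"{message} (best residual {best_residual:.3e})")
        self.best_residual = best_residual


def efd(x):
    """The special functions E, F, D of the saddle-point system.

    E(x) = (1 + erf x)/2,  F(x) = exp(-x^2)/sqrt(pi) + x (1 + erf x),
    D(x) = x F(x) + E(x).  Evaluated via erfcx on the negative branch so
    that the exponentially small tails stay accurate for x down to -30
    and beyond.
    """
    x = np.asarray(x, dtype=float)
    ex2 = np.exp(-np.minimum(x * x, 745.0))
    # 1 + erf(x) = erfc(-x) = erfcx(-x) * exp(-x^2); stable for x < 0.
    one_plus_erf = erfcx(-x) * ex2
    E = 0.5 * one_plus_erf
    # F and D are positive for all real x; the far negative tail can round
    # to a denormal of the wrong sign, so clamp at zero.
    F = np.maximum(ex2 / _SQRT_PI + x * one_plus_erf, 0.0)
    D = np.maximum(x * F + E, 0.0)
    if x.ndim == 0:
        return float(E), float(F), float(D)
    return E, F, D


def postsynaptic_noise(beta_int: float, beta_syn: float, f: float, w_tilde: float) -> float:
    """beta = sqrt(beta_int^2 + w~ beta_syn f): the single combination of
    the two noise sources that the capacity depends on."""
    if beta_int < 0 or beta_syn < 0:
        raise ValueError("noise strengths must be >= 0")
    return float(np.sqrt(beta_int**2 + w_tilde * beta_syn * f))


def _erfinv_sum(r_out: float, f_out: float) -> float:
    """erfinv(1 - r_out/(1-f_out)) + erfinv(1 - r_out/f_out) = K / sqrt(2)."""
    om = output_margins(r_out, f_out)
    return (om.D_plus + om.D_minus) / np.sqrt(2.0)


def xi_zeta(
    r_in: float, f_in: float, r_out: float, f_out: float, w_tilde: float
) -> tuple[float, float]:
    """Spiking-error parameters of the homogeneous solution.

    xi  = r_in (4 f_in (1-f_in) - r_in) / (2 (2 f_in (1-f_in) - r_in)^2) * S^2
    zeta = sqrt(2 f_in (1-f_in)) / (w~ (2 f_in (1-f_in) - r_in)) * S
    with S = erfinv(1 - r_out/(1-f_out)) + erfinv(1 - r_out/f_out).
    Equivalently xi = B K^2/(4C) and zeta = K/(2 w~ sqrt(C)).
    """
    if not 0 <= r_in < 2 * f_in * (1 - f_in):
        raise ValueError("r_in outside [0, 2 f_in (1 - f_in))")
    S = _erfinv_sum(r_out, f_out)
    c2 = 2.0 * f_in * (1.0 - f_in)
    xi = r_in * (2.0 * c2 - r_in) / (2.0 * (c2 - r_in) ** 2) * S**2
    zeta = np.sqrt(c2) / (w_tilde * (c2 - r_in)) * S
    return float(xi), float(zeta)


def kappa_rho(
    beta_int: float,
    beta_syn: float,
    f_in: float,
    w_tilde: float,
    r_out: float,
    f_out: float,
    h: float,
    n: int,
) -> tuple[float, float]:
    """Map the noise strengths onto the generic robustness parameters of the
    traditional model: kappa = h beta S / sqrt(2N) and
    rho = beta S / (w~ sqrt(2 f_in (1-f_in))), with S the erfinv sum.
    At r_in = 0, rho = beta * zeta."""
    beta = postsynaptic_noise(beta_int, beta_syn, f_in, w_tilde)
    if beta == 0.0:
        return 0.0, 0.0
    S = _erfinv_sum(r_out, f_out)
    kappa = h * beta * S / np.sqrt(2.0 * n)
    rho = beta * S / (w_tilde * np.sqrt(2.0 * f_in * (1.0 - f_in)))
    return float(kappa), float(rho)


# ---------------------------------------------------------------------------
# shared pieces

def _split_u(T: float, f_out: float) -> tuple[float, float]:
    """Given T = u+ + u-, solve (1-f_out) F(u+) = f_out F(u-) for the split.

    F is strictly increasing, so the equation has a unique root in u+.
    """

    def phi(up):
        _, Fp, _ = efd(up)
        _, Fm, _ = efd(T - up)
        return (1.0 - f_out) * Fp - f_out * Fm

    lo, hi = -40.0, 40.0 + abs(T)
    u_plus = brentq(phi, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return u_plus, T - u_plus


def _out_moments(u_plus: float, u_minus: float, f_out: float):
    Ep, Fp, Dp = efd(u_plus)
    Em, Fm, Dm = efd(u_minus)
    E_bar = f_out * Em + (1.0 - f_out) * Ep
    F_bar = f_out * Fm + (1.0 - f_out) * Fp
    D_bar = f_out * Dm + (1.0 - f_out) * Dp
    return E_bar, F_bar, D_bar


# ---------------------------------------------------------------------------
# homogeneous two-class solver

@dataclass(frozen=True)
class HomogeneousSolution:
    u_plus: float
    u_minus: float
    v_plus: float
    v_minus: float
    sigma_latent: float
    x: float
    beta: float
    xi: float
    zeta: float
    alpha_c: float
    P_con_inh: float
    P_con_exc: float
    mean_abs_weight_inh: float
    mean_abs_weight_exc: float
    f_in: float
    r_in: float
    f_out: float
    r_out: float | None
    w_tilde: float
    frac_inh: float
    residual: float


def solve_homogeneous(
    f_in: float,
    r_in: float,
    f_out: float,
    r_out: float,
    beta: float,
    w_tilde: float,
    frac_inh: float,
    tol: float = 1e-11,
) -> HomogeneousSolution:
    """Solve the homogeneous two-class saddle-point system at critical
    capacity.

    Parameters follow the model: input firing/error probabilities
    (f_in, r_in), output probabilities (f_out, r_out > 0), postsynaptic
    noise strength ``beta``, scaled l1-norm ``w_tilde = N w / h`` and
    inhibitory input fraction ``frac_inh``.
    """
    if not 0 < frac_inh < 1:
        raise ValueError(
            "frac_inh must lie strictly in (0, 1): with a single sign class "
            "the l1-norm equality pins the mean drive and the balance "
            "condition cannot hold"
        )
    if beta < 0:
        raise ValueError("beta must be >= 0")
    xi, zeta = xi_zeta(r_in, f_in, r_out, f_out, w_tilde)
    coeff = input_coefficients(f_in, r_in)
    C, B = coeff.C, coeff.B
    om = output_margins(r_out, f_out)
    K = om.D_plus + om.D_minus
    sol = _solve_homogeneous_core(
        f_in, f_out, w_tilde, frac_inh, C, B, K, xi,
        beta2zeta2=beta**2 * zeta**2, tol=tol,
    )
    return HomogeneousSolution(
        **sol,
        beta=beta,
        xi=xi,
        zeta=zeta,
        f_in=f_in,
        r_in=r_in,
        f_out=f_out,
        r_out=r_out,
        w_tilde=w_tilde,
        frac_inh=frac_inh,
    )


def _solve_homogeneous_core(
    f_in, f_out, w_tilde, frac_inh, C, B, K, xi, beta2zeta2, tol,
    kappa_mode: bool = False,
):
    """Shared core of the homogeneous and kappa-model solvers.

    In ``kappa_mode`` the output-margin factor K has been eliminated
    analytically (the r_in = 0 reduction); the system then depends only on
    rho^2 = beta2zeta2 and B = xi = 0.
    """
    phi_i, phi_e = frac_inh, 1.0 - frac_inh
    sqrtC = np.sqrt(C)

    def residuals(p):
        T, vp, vm = p
        u_plus, u_minus = _split_u(T, f_out)
        E_bar, F_barout, _ = _out_moments(u_plus, u_minus, f_out)
        Evp, Fvp, Dvp = efd(vp)
        Evm, Fvm, Dvm = efd(vm)
        F_bar = phi_i * Fvp + phi_e * Fvm
        F_tilde = phi_e * Fvm - phi_i * Fvp
        D_bar_v = phi_i * Dvp + phi_e * Dvm

        s2 = F_tilde - F_bar / (w_tilde * f_in)
        s4 = (T * T - 2.0 * xi) * D_bar_v - F_bar**2 * beta2zeta2 * C
        if kappa_mode:
            # RHS of S5 with a and x eliminated: F_barout F_bar sqrt(C) rho^2 / (T E_bar)
            rhs5 = (
                F_barout * F_bar * sqrtC * beta2zeta2 / max(T * E_bar, 1e-300)
            )
        else:
            x = 4.0 * T * E_bar / (K * K * F_barout)
            a = C / (C * x + B)
            # 2 a F_bar beta^2 zeta / (w~ K); beta^2 zeta = beta2zeta2 / zeta,
            # zeta = K / (2 w~ sqrt(C))  =>  beta^2 zeta / K = 2 w~ sqrt(C) beta2zeta2 / K^2
            rhs5 = 4.0 * a * F_bar * sqrtC * beta2zeta2 / (K * K)
        s5 = (vp - vm) / (w_tilde * f_in) - (vp + vm) - rhs5
        scale2 = F_bar * (1.0 + 1.0 / (w_tilde * f_in)) + 1e-30
        scale4 = (T * T + 2 * xi + 1e-3) * D_bar_v + F_bar**2 * beta2zeta2 * C + 1e-30
        scale5 = abs(vp) + abs(vm) + abs(rhs5) + 1e-2
        out = np.array([s2 / scale2, s4 / scale4, s5 / scale5])
        return np.where(np.isfinite(out), out, 1e6)

    def assemble(p):
        T, vp, vm = p
        u_plus, u_minus = _split_u(T, f_out)
        E_bar, F_barout, D_barout = _out_moments(u_plus, u_minus, f_out)
        Evp, Fvp, Dvp = efd(vp)
        Evm, Fvm, Dvm = efd(vm)
        F_bar = phi_i * Fvp + phi_e * Fvm
        D_bar_v = phi_i * Dvp + phi_e * Dvm
        if kappa_mode:
            xa = 1.0
            x = np.nan
        else:
            x = 4.0 * T * E_bar / (K * K * F_barout)
            xa = x * C / (C * x + B)
        alpha_c = xa**2 * (D_barout / E_bar**2) * D_bar_v
        sigma_latent = np.sqrt(2.0) / F_bar
        s = sigma_latent * w_tilde  # SD scale of non-zero weights
        mean_inh = s * Fvp / (np.sqrt(2.0) * Evp)
        mean_exc = s * Fvm / (np.sqrt(2.0) * Evm)
        return dict(
            u_plus=float(u_plus),
            u_minus=float(u_minus),
            v_plus=float(vp),
            v_minus=float(vm),
            sigma_latent=float(sigma_latent),
            x=float(x),
            alpha_c=float(alpha_c),
            P_con_inh=float(Evp),
            P_con_exc=float(Evm),
            mean_abs_weight_inh=float(mean_inh),
            mean_abs_weight_exc=float(mean_exc),
            residual=float(np.max(np.abs(residuals(p)))),
        )

    rho2 = beta2zeta2
    starts = []
    # heuristic: P_inh ~ 0.5, P_exc ~ 0.15..0.35, T from S4 with D_bar_v ~ 0.4
    for pe in (0.3, 0.15, 0.45):
        vp0 = 0.0
        vm0 = float(np.sqrt(2.0) * erfinv(2.0 * pe - 1.0))
        Fb0 = phi_i * efd(vp0)[1] + phi_e * efd(vm0)[1]
        T0 = np.sqrt(max(2.0 * xi + Fb0**2 * rho2 * C / 0.4, 1e-6))
        starts.append((T0, vp0, vm0))
    starts.append((max(np.sqrt(2 * xi + 0.01), 0.1), 0.3, -1.0))
    starts.append((1.0, 0.1, -0.5))

    best_res = np.inf
    for p0 in starts:
        try:
            res = root(residuals, p0, method="hybr", tol=1e-13)
        except Exception:
            continue
        if res.x[0] < -1e-8:
            # unphysical mirror branch (u+ + u- < 0): restart reflected
            try:
                res = root(
                    residuals, np.array([abs(res.x[0]), res.x[1], res.x[2]]),
                    method="hybr", tol=1e-13,
                )
            except Exception:
                continue
        r_now = float(np.max(np.abs(residuals(res.x))))
        if r_now < best_res:
            best_res = r_now
            best_x = res.x
        if r_now < tol and res.x[0] >= -1e-8:
            x_acc = res.x.copy()
            x_acc[0] = max(x_acc[0], 0.0)
            return assemble(x_acc)
    if best_res < 1e-8 and best_x[0] >= -1e-8:
        best_x = best_x.copy()
        best_x[0] = max(best_x[0], 0.0)
        return assemble(best_x)
    raise ReplicaConvergenceError(
        "homogeneous saddle-point solver did not converge", best_res
    )


def solve_kappa(
    rho: float, f_in: float, f_out: float, w_tilde: float, frac_inh: float,
    tol: float = 1e-11,
) -> HomogeneousSolution:
    """Critical capacity of the traditional robustness-parameter model.

    Equivalent to the noisy model at r_in = 0 for any (beta, r_out) with
    rho = beta * zeta; used as the independent cross-check of that
    reduction.
    """
    C = f_in * (1.0 - f_in)
    sol = _solve_homogeneous_core(
        f_in, f_out, w_tilde, frac_inh, C, 0.0, np.nan, 0.0,
        beta2zeta2=rho**2, tol=tol, kappa_mode=True,
    )
    return HomogeneousSolution(
        **sol,
        beta=np.nan,
        xi=0.0,
        zeta=np.nan,
        f_in=f_in,
        r_in=0.0,
        f_out=f_out,
        r_out=None,
        w_tilde=w_tilde,
        frac_inh=frac_inh,
    )


# ---------------------------------------------------------------------------
# heterogeneous solver

@dataclass(frozen=True)
class HeterogeneousSolution:
    u_plus: float
    u_minus: float
    x: float
    eta: float
    y_latent: float
    z: float
    alpha_c: float
    P_con: np.ndarray
    mean_nonzero_weight: np.ndarray
    sigma: np.ndarray
    f: np.ndarray
    r: np.ndarray
    g: np.ndarray
    beta_syn: np.ndarray
    beta_int: float
    f_out: float
    r_out: float
    w_tilde: float
    residual: float


def solve_heterogeneous(
    f: np.ndarray,
    r: np.ndarray,
    g: np.ndarray,
    beta_syn: np.ndarray | float,
    beta_int: float,
    f_out: float,
    r_out: float,
    w_tilde: float,
    tol: float = 1e-11,
    initial: HomogeneousSolution | None = None,
) -> HeterogeneousSolution:
    """Solve the six-latent saddle-point system for an explicit input list.

    ``f``, ``r``, ``g`` and ``beta_syn`` are per-input arrays (scalars
    broadcast); the per-input integrals of the saddle-point equations are
    finite sums (1/N) sum_j.  Returns per-input connection probabilities
    and truncated-Gaussian weight parameters.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    n = f.shape[0]
    r = np.broadcast_to(np.asarray(r, dtype=float), (n,)).copy()
    g = np.broadcast_to(np.asarray(g, dtype=float), (n,)).copy()
    bsyn = np.broadcast_to(np.asarray(beta_syn, dtype=float), (n,)).copy()
    if not np.isin(g, (-1.0, 1.0)).all():
        raise ValueError("sign labels g must be +-1")
    coeff = input_coefficients(f, r)
    C = np.asarray(coeff.C, dtype=float)
    B = np.asarray(coeff.B, dtype=float)
    om = output_margins(r_out, f_out)
    K = om.D_plus + om.D_minus
    sqrtC = np.sqrt(C)

    def unpack(p):
        T, eta, y, z = p
        u_plus, u_minus = _split_u(T, f_out)
        E_bar, F_barout, D_barout = _out_moments(u_plus, u_minus, f_out)
        x = 4.0 * T * E_bar / (K * K * F_barout)
        a = C / (C * x + B)
        v = -(eta + 2.0 * z * f * g + y * bsyn * f) / (2.0 * sqrtC)
        return T, eta, y, z, u_plus, u_minus, E_bar, F_barout, D_barout, x, a, v

    def residuals(p):
        T, eta, y, z, *_rest = p[0], p[1], p[2], p[3]
        T, eta, y, z, u_plus, u_minus, E_bar, F_barout, D_barout, x, a, v = unpack(p)
        Ev, Fv, Dv = efd(v)
        aF = a * Fv
        r3 = np.mean(aF) - 2.0 * w_tilde * y
        r4 = np.mean(f * g * aF) - 2.0 * y
        lhs5 = np.mean(a * a / C * (B / 2.0 - T * T * C / (K * K)) * Dv)
        rhs5 = beta_int**2 * y * y - y * w_tilde * eta - 2.0 * y * z
        r5 = lhs5 - rhs5
        r6 = np.mean(bsyn * f * aF) - (2.0 * w_tilde * eta + 4.0 * z - 4.0 * beta_int**2 * y)
        sc3 = np.mean(np.abs(aF)) + 2.0 * w_tilde * abs(y) + 1e-30
        sc4 = np.mean(np.abs(f * aF)) + 2.0 * abs(y) + 1e-30
        sc5 = np.mean(np.abs(a * a / C * (B / 2.0 + T * T * C / (K * K)) * np.abs(Dv))) + abs(rhs5) + 1e-30
        sc6 = np.mean(np.abs(bsyn * f * aF)) + abs(2 * w_tilde * eta) + 4 * abs(z) + 4 * beta_int**2 * abs(y) + 1e-10
        return np.array([r3 / sc3, r4 / sc4, r5 / sc5, r6 / sc6])

    # initial guess from the matching homogeneous problem
    if initial is None:
        fm, rm, bm = float(f.mean()), float(r.mean()), float(bsyn.mean())
        frac_inh = float(np.mean(g < 0))
        frac_inh = min(max(frac_inh, 1e-3), 1 - 1e-3)
        beta0 = postsynaptic_noise(beta_int, bm, fm, w_tilde)
        initial = solve_homogeneous(fm, rm, f_out, r_out, beta0, w_tilde, frac_inh)
    Cm = input_coefficients(float(f.mean()), float(r.mean())).C
    y0 = initial.sigma_latent and np.nan
    # recover (eta, y, z) from the homogeneous latents
    a0 = Cm / (Cm * initial.x + input_coefficients(float(f.mean()), float(r.mean())).B)
    F_bar0 = np.sqrt(2.0) / initial.sigma_latent
    y0 = a0 * F_bar0 / (2.0 * w_tilde)
    z0 = np.sqrt(Cm) * (initial.v_plus - initial.v_minus) / (2.0 * float(f.mean()))
    eta0 = -np.sqrt(Cm) * (initial.v_plus + initial.v_minus) - y0 * float(bsyn.mean()) * float(f.mean())
    T0 = initial.u_plus + initial.u_minus

    starts = [
        (T0, eta0, y0, z0),
        (max(T0, 0.1) * 1.5, eta0 * 0.5, y0 * 1.5, z0 * 0.5),
        (1.0, 0.0, 0.01, 0.1),
    ]
    best_res, best_x = np.inf, None
    for p0 in starts:
        try:
            res = root(residuals, p0, method="hybr", tol=1e-13)
        except Exception:
            continue
        r_now = float(np.max(np.abs(residuals(res.x))))
        if r_now < best_res:
            best_res, best_x = r_now, res.x
        if r_now < tol and res.x[0] >= 0 and res.x[2] > 0:
            best_x, best_res = res.x, r_now
            break
    if best_x is None or best_res > 1e-8 or best_x[0] < 0 or best_x[2] <= 0:
        raise ReplicaConvergenceError(
            "heterogeneous saddle-point solver did not converge", best_res
        )

    T, eta, y, z, u_plus, u_minus, E_bar, F_barout, D_barout, x, a, v = unpack(best_x)
    Ev, Fv, Dv = efd(v)
    alpha_c = x**2 * (D_barout / E_bar**2) * float(np.mean(a * a * Dv))
    sigma = a / (np.sqrt(2.0) * w_tilde * y)
    mean_nonzero = g * sigma * w_tilde * Fv / (np.sqrt(2.0) * Ev)
    return HeterogeneousSolution(
        u_plus=float(u_plus),
        u_minus=float(u_minus),
        x=float(x),
        eta=float(eta),
        y_latent=float(y),
        z=float(z),
        alpha_c=float(alpha_c),
        P_con=Ev,
        mean_nonzero_weight=mean_nonzero,
        sigma=sigma,
        f=f,
        r=r,
        g=g,
        beta_syn=bsyn,
        beta_int=float(beta_int),
        f_out=f_out,
        r_out=r_out,
        w_tilde=w_tilde,
        residual=best_res,
    )


# ---------------------------------------------------------------------------
# weight distribution

def weight_distribution(
    sol: HomogeneousSolution | HeterogeneousSolution,
    w_tilde: float | None = None,
) -> dict:
    """Truncated-Gaussian description of the weights at critical capacity.

    For each class (homogeneous) or input (heterogeneous) returns
    ``P_con`` (probability of a non-zero weight), the location/scale of
    the underlying Gaussian of the scaled weight magnitude q = g J~
    (truncated to q > 0), its conditional mean, and the CV of non-zero
    magnitudes.
    """
    w_tilde = sol.w_tilde if w_tilde is None else w_tilde

    def one(v: float, sigma: float) -> dict:
        s = sigma * w_tilde
        mu0 = np.sqrt(2.0) * s * v  # magnitude-scale Gaussian location
        tn = truncnorm((0.0 - mu0) / s, np.inf, loc=mu0, scale=s)
        mean = float(tn.mean())
        cv = float(tn.std() / mean)
        E, F, _ = efd(v)
        return dict(
            P_con=float(E), loc=float(mu0), scale=float(s), mean=mean, cv=cv,
            mean_closed_form=float(s * F / (np.sqrt(2.0) * E)),
        )

    if isinstance(sol, HomogeneousSolution):
        return {
            "inh": one(sol.v_plus, sol.sigma_latent),
            "exc": one(sol.v_minus, sol.sigma_latent),
        }
    v = np.sqrt(2.0) * erfinv(2.0 * sol.P_con - 1.0)
    return {
        "per_input": [one(float(vj), float(sj)) for vj, sj in zip(v, sol.sigma)]
    }


# ---------------------------------------------------------------------------
# sweep engine

def replica_sweep(
    points,
    f: float,
    w_tilde: float,
    frac_inh: float,
) -> "pd.DataFrame":
    """Solve the homogeneous system over a grid of (beta_learn, r_learn)
    points (with r_in = r_out = r, f_in = f_out = f, as in a recurrent
    network) and return a tidy table: one row per grid point with alpha_c,
    per-class connection probabilities and weight CVs."""
    import pandas as pd

    rows = []
    for beta, r_learn in points:
        sol = solve_homogeneous(f, r_learn, f, r_learn, beta, w_tilde, frac_inh)
        wd = weight_distribution(sol)
        rows.append(
            dict(
                beta_learn=beta,
                r_learn=r_learn,
                alpha_c=sol.alpha_c,
                P_con_inh=sol.P_con_inh,
                P_con_exc=sol.P_con_exc,
                cv_w_inh=wd["inh"]["cv"],
                cv_w_exc=wd["exc"]["cv"],
            )
        )
    return pd.DataFrame(rows)
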