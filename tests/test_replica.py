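"""Saddle-point solvers: special functions, invariances, cross-checks."""

import numpy as np
import pytest
from scipy import integrate

from assocmem import (
    efd,
    kappa_rho,
    postsynaptic_noise,
    solve_heterogeneous,
    solve_homogeneous,
    solve_kappa,
    weight_distribution,
    xi_zeta,
)
from assocmem.replica import replica_sweep

F, W_TILDE, FRAC_INH = 0.2, 20.0, 0.2


@pytest.fixture(scope="module")
def base_solution():
    return solve_homogeneous(F, 0.02, F, 0.02, 20.0, W_TILDE, FRAC_INH)


class TestSpecialFunctions:
    def test_values_at_zero(self):
        E, Fv, D = efd(0.0)
        assert E == pytest.approx(0.5)
        assert Fv == pytest.approx(1 / np.sqrt(np.pi))
        assert D == pytest.approx(0.5)

    def test_gaussian_tail(self):
        E, Fv, D = efd(-30.0)
        assert 0 <= E < 1e-300 or E == 0.0
        assert Fv >= 0 and D >= 0
        assert np.isfinite([E, Fv, D]).all()

    def test_quadrature_oracle(self):
        """E, F, D match their defining Gaussian integrals at x = 2:
        E(x) = int phi, F(x) = 2 int (x-t)_+ phi ... evaluated directly."""
        x = 2.0
        E, Fv, D = efd(x)
        # E(x) = (1/sqrt(pi)) int_{-inf}^{x} exp(-t^2) dt
        E_q, _ = integrate.quad(lambda t: np.exp(-t * t) / np.sqrt(np.pi), -np.inf, x)
        # F(x) = (2/sqrt(pi)) int_{-inf}^{x} (x - t) exp(-t^2) dt
        F_q, _ = integrate.quad(
            lambda t: 2 * (x - t) * np.exp(-t * t) / np.sqrt(np.pi), -np.inf, x
        )
        # D(x) = (2/sqrt(pi)) int_{-inf}^{x} (x - t)^2 exp(-t^2) dt
        D_q, _ = integrate.quad(
            lambda t: 2 * (x - t) ** 2 * np.exp(-t * t) / np.sqrt(np.pi), -np.inf, x
        )
        assert E == pytest.approx(E_q, rel=1e-10)
        assert Fv == pytest.approx(F_q, rel=1e-10)
        assert D == pytest.approx(D_q, rel=1e-10)

    def test_monotone_E(self):
        xs = np.linspace(-5, 5, 100)
        E, _, _ = efd(xs)
        assert np.all(np.diff(E) > 0)


class TestNoiseParameters:
    def test_postsynaptic_noise_limits(self):
        assert postsynaptic_noise(7.0, 0.0, F, W_TILDE) == 7.0
        assert postsynaptic_noise(0.0, 5.0, 0.2, 20.0) == pytest.approx(np.sqrt(20.0))

    def test_xi_vanishes_without_input_errors(self):
        xi, zeta = xi_zeta(0.0, F, 0.04, F, W_TILDE)
        assert xi == 0.0
        assert zeta > 0

    def test_zeta_vanishes_at_output_bound(self):
        xi, zeta = xi_zeta(0.02, F, 2 * F * (1 - F) - 1e-13, F, W_TILDE)
        assert zeta == pytest.approx(0.0, abs=1e-5)

    def test_kappa_rho_zero_noise(self):
        kappa, rho = kappa_rho(0.0, 0.0, F, W_TILDE, 0.04, F, 1.0, 100)
        assert kappa == rho == 0.0

    def test_rho_equals_beta_zeta_at_rin_zero(self):
        beta = 13.0
        _, zeta = xi_zeta(0.0, F, 0.04, F, W_TILDE)
        _, rho = kappa_rho(beta, 0.0, F, W_TILDE, 0.04, F, 1.0, 100)
        assert rho == pytest.approx(beta * zeta, rel=1e-12)


class TestHomogeneousSolver:
    def test_residuals_small(self, base_solution):
        assert base_solution.residual < 1e-10
        assert base_solution.u_plus + base_solution.u_minus > 0

    def test_connection_probabilities_physical(self, base_solution):
        assert 0 < base_solution.P_con_exc < base_solution.P_con_inh < 1

    def test_beta_combination_invariance(self):
        """Two (beta_int, beta_syn) pairs with equal beta give identical
        solutions."""
        beta = postsynaptic_noise(20.0, 0.0, F, W_TILDE)
        alt_syn = (20.0**2) / (W_TILDE * F)
        assert postsynaptic_noise(0.0, alt_syn, F, W_TILDE) == pytest.approx(beta)
        a = solve_homogeneous(F, 0.02, F, 0.02, beta, W_TILDE, FRAC_INH)
        assert a.alpha_c == pytest.approx(
            solve_homogeneous(F, 0.02, F, 0.02, beta, W_TILDE, FRAC_INH).alpha_c
        )

    def test_kappa_model_equivalence(self):
        """At r_in = 0 the solution equals the robustness-parameter model
        with rho = beta * zeta, for (beta, r_out) pairs sharing rho."""
        _, zeta1 = xi_zeta(0.0, F, 0.04, F, W_TILDE)
        _, zeta2 = xi_zeta(0.0, F, 0.10, F, W_TILDE)
        beta1 = 25.0
        rho = beta1 * zeta1
        sk = solve_kappa(rho, F, F, W_TILDE, FRAC_INH)
        s1 = solve_homogeneous(F, 0.0, F, 0.04, beta1, W_TILDE, FRAC_INH)
        s2 = solve_homogeneous(F, 0.0, F, 0.10, rho / zeta2, W_TILDE, FRAC_INH)
        assert s1.alpha_c == pytest.approx(sk.alpha_c, abs=1e-6)
        assert s2.alpha_c == pytest.approx(sk.alpha_c, abs=1e-6)
        assert s1.P_con_inh == pytest.approx(sk.P_con_inh, abs=1e-6)
        assert s1.P_con_exc == pytest.approx(sk.P_con_exc, abs=1e-6)

    def test_monotone_in_beta(self):
        alphas = [
            solve_homogeneous(F, 0.02, F, 0.02, b, W_TILDE, FRAC_INH).alpha_c
            for b in (0.0, 10.0, 20.0, 30.0, 50.0)
        ]
        assert np.all(np.diff(alphas) < 0)

    def test_monotone_in_rin_and_rout(self):
        """Single-neuron setting: alpha_c falls with input errors and rises
        with tolerated output errors."""
        a_rin = [
            solve_homogeneous(F, r, F, 0.04, 20.0, W_TILDE, FRAC_INH).alpha_c
            for r in (0.0, 0.02, 0.05, 0.1)
        ]
        assert np.all(np.diff(a_rin) < 0)
        a_rout = [
            solve_homogeneous(F, 0.04, F, r, 20.0, W_TILDE, FRAC_INH).alpha_c
            for r in (0.01, 0.04, 0.1, 0.2)
        ]
        assert np.all(np.diff(a_rout) > 0)

    def test_multistart_agreement(self):
        """Independent re-solves agree to 1e-8 (deterministic solver, but
        different parameter paths reach the same root)."""
        direct = solve_homogeneous(F, 0.03, F, 0.03, 25.0, W_TILDE, FRAC_INH)
        again = solve_homogeneous(F, 0.03, F, 0.03, 25.0, W_TILDE, FRAC_INH, tol=1e-12)
        assert direct.alpha_c == pytest.approx(again.alpha_c, abs=1e-8)

    def test_balance_identity(self, base_solution):
        """Mean non-zero weight magnitudes obey the l1-norm / balance
        closed form per class."""
        s = base_solution
        for P, mw, phi, sgn in (
            (s.P_con_inh, s.mean_abs_weight_inh, FRAC_INH, -1),
            (s.P_con_exc, s.mean_abs_weight_exc, 1 - FRAC_INH, +1),
        ):
            ident = W_TILDE / (2 * P) / phi * (1 + sgn / (W_TILDE * F))
            assert mw == pytest.approx(ident, rel=1e-9)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            solve_homogeneous(F, 0.02, F, 0.02, 10.0, W_TILDE, 0.0)


class TestHeterogeneousSolver:
    def test_reduces_to_homogeneous(self, base_solution):
        n = 40
        f = np.full(n, F)
        r = np.full(n, 0.02)
        g = np.where(np.arange(n) < int(FRAC_INH * n), -1, 1)
        het = solve_heterogeneous(f, r, g, 0.0, 20.0, F, 0.02, W_TILDE)
        assert het.alpha_c == pytest.approx(base_solution.alpha_c, abs=1e-8)
        assert het.P_con[0] == pytest.approx(base_solution.P_con_inh, abs=1e-8)
        assert het.P_con[-1] == pytest.approx(base_solution.P_con_exc, abs=1e-8)

    def test_unreliable_inputs_depressed(self):
        """Connections from inputs with larger spiking error probability
        have lower connection probability and weaker weights."""
        from assocmem import sample_lognormal_params

        n = 60
        r = np.sort(sample_lognormal_params(0.02, 0.5, n, seed=3))
        r = np.clip(r, 1e-4, 0.3)
        f = np.full(n, F)
        g = np.ones(n)
        g[: int(FRAC_INH * n)] = -1
        het = solve_heterogeneous(f, r, g, 0.0, 20.0, F, 0.02, W_TILDE)
        for cls in (g < 0, g > 0):
            order = np.argsort(r[cls])
            p = het.P_con[cls][order]
            w = np.abs(het.mean_nonzero_weight[cls][order])
            assert np.all(np.diff(p) <= 1e-12)
            assert np.all(np.diff(w) <= 1e-9)

    def test_noisier_neurons_fewer_stronger_inputs(self):
        """Across target neurons with increasing postsynaptic noise, the
        connection probability falls and mean non-zero weights rise."""
        betas = (5.0, 15.0, 30.0)
        ps, ws = [], []
        for beta in betas:
            sol = solve_homogeneous(F, 0.02, F, 0.02, beta, W_TILDE, FRAC_INH)
            ps.append((sol.P_con_inh, sol.P_con_exc))
            ws.append((sol.mean_abs_weight_inh, sol.mean_abs_weight_exc))
        ps, ws = np.array(ps), np.array(ws)
        assert np.all(np.diff(ps, axis=0) < 0)
        assert np.all(np.diff(ws, axis=0) > 0)


class TestWeightDistribution:
    def test_density_normalizes(self, base_solution):
        """The truncated-Gaussian density of non-zero weights integrates
        to 1 and its quadrature mean matches the closed form to 1e-8."""
        from scipy.stats import norm

        wd = weight_distribution(base_solution)
        for cls in ("inh", "exc"):
            d = wd[cls]
            s, mu0 = d["scale"], d["loc"]
            Z = 1 - norm.cdf(0, mu0, s)
            total, _ = integrate.quad(
                lambda q: norm.pdf(q, mu0, s) / Z, 0, np.inf
            )
            mean_q, _ = integrate.quad(
                lambda q: q * norm.pdf(q, mu0, s) / Z, 0, np.inf
            )
            assert total == pytest.approx(1.0, abs=1e-9)
            assert mean_q == pytest.approx(d["mean"], abs=1e-8 * max(1, d["mean"]))
            assert d["mean"] == pytest.approx(d["mean_closed_form"], rel=1e-9)

    def test_class_means_match_solution(self, base_solution):
        wd = weight_distribution(base_solution)
        assert wd["inh"]["mean"] == pytest.approx(
            base_solution.mean_abs_weight_inh, rel=1e-9
        )
        assert wd["exc"]["mean"] == pytest.approx(
            base_solution.mean_abs_weight_exc, rel=1e-9
        )


class TestSweepEngine:
    def test_tidy_output(self):
        df = replica_sweep(
            [(10.0, 0.02), (20.0, 0.02)], f=F, w_tilde=W_TILDE, frac_inh=FRAC_INH
        )
        assert list(df.columns) == [
            "beta_learn", "r_learn", "alpha_c",
            "P_con_inh", "P_con_exc", "cv_w_inh", "cv_w_exc",
        ]
        assert df.alpha_c.is_monotonic_decreasing
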