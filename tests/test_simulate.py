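"""Network simulation: retrieval classification and dynamics statistics."""

import numpy as np
import pytest

from assocmem import (
    NetworkSpec,
    connectivity_stats,
    dynamics_stats,
    generate_sequence,
    load_network,
    retrieval_statistics,
    retrieve,
    spontaneous_run,
    step,
)
from assocmem.loading import WeightMatrix
from assocmem.simulate import ActivityRaster, deviation_threshold

from conftest import make_spec


@pytest.fixture(scope="module")
def loaded_net():
    """A fully loadable small network: moderate noise, load well below
    capacity, draw re-seeded until every neuron learns its associations."""
    for seed in range(21, 27):
        spec = make_spec(100, beta=10.0, seed=seed)
        seq = generate_sequence(spec, 5, seed=seed)
        W = load_network(seq, spec)
        if W.feasible.all():
            return spec, seq, W
    raise RuntimeError("no fully loadable draw found")


class TestStep:
    def test_noise_free_transition(self, loaded_net):
        """A perfectly loaded network maps X^mu to X^(mu+1) exactly."""
        spec, seq, W = loaded_net
        state = seq.states[0].astype(np.int8)
        for mu in range(seq.m):
            state = step(W, state, spec, beta_retr=0.0, rng=1)
            assert (state == seq.states[mu + 1]).all()

    def test_silent_state_stays_silent(self, loaded_net):
        spec, _, W = loaded_net
        out = step(W, np.zeros(100, dtype=np.int8), spec, beta_retr=0.0, rng=2)
        assert (out == 0).all()

    def test_zero_weights_die_out(self):
        spec = make_spec(20)
        W = WeightMatrix(J_tilde=np.zeros((20, 20)), feasible=np.ones(20, bool), spec=spec)
        out = step(W, np.ones(20, dtype=np.int8), spec, beta_retr=0.0, rng=3)
        assert (out == 0).all()

    def test_noise_flip_statistics_match_margin_probabilities(self, loaded_net):
        """Per-neuron flip rates under noise agree with the Gaussian
        margin error probabilities."""
        from scipy.stats import norm

        from assocmem.margin import association_margins, output_margins
        from assocmem.margin import flip_averaged_input, flip_variance_input

        spec, seq, W = loaded_net
        beta = 20.0
        state = seq.states[0].astype(np.int8)
        target = seq.states[1]
        trials = 3000
        rng = np.random.default_rng(4)
        flips = np.zeros(100)
        for _ in range(trials):
            out = step(W, state, spec, beta_retr=beta, rng=rng)
            flips += out != target
        flips /= trials

        # closed-form error probability per neuron for this input state
        n = spec.n
        x = state.astype(float)
        I = W.J_tilde @ x / n - 1.0
        sig = np.sqrt(beta**2 / n) * np.ones(n)
        p_pred = norm.cdf(-np.abs(I) / sig)
        p_pred = np.where(
            target == 1, norm.cdf(-I / sig), norm.cdf(I / sig)
        )
        se = np.sqrt(np.maximum(p_pred * (1 - p_pred), 1e-6) / trials)
        assert np.mean(np.abs(flips - p_pred) < 4 * se + 0.01) > 0.95


class TestRetrieve:
    def test_noise_free_complete(self, loaded_net):
        spec, seq, W = loaded_net
        res = retrieve(W, seq, spec, beta_retr=0.0, seed=5)
        assert res.complete
        assert res.retrieved_length == seq.m
        assert (res.error_fraction_trace == 0).all()

    def test_partial_terminal_error_approaches_random_distance(self):
        """Once retrieval derails, the terminal error fraction approaches
        2f(1-f), the expected distance between random states."""
        spec = make_spec(200, beta=2.0, seed=23)  # fragile: low-noise loading
        seq = generate_sequence(spec, 30, seed=23)
        W = load_network(seq, spec)
        terminal = []
        for t in range(30):
            # moderate retrieval noise: derails fragile memories while the
            # network keeps firing near probability f
            res = retrieve(W, seq, spec, beta_retr=15.0, seed=100 + t)
            if not res.complete:
                terminal.append(res.error_fraction_trace[-1])
        assert len(terminal) > 10
        expect = 2 * 0.2 * 0.8
        se = np.sqrt(expect * (1 - expect) / 200)
        assert abs(np.mean(terminal) - expect) < 3 * se + 0.02

    def test_statistics_trivial_case(self, loaded_net):
        spec, seq, W = loaded_net
        stats = retrieval_statistics(W, seq, spec, beta_retr=0.0, trials=10, seed=6)
        assert stats["retrieval_probability"] == 1.0
        assert stats["mean_length_fraction"] == 1.0

    def test_deviation_threshold_midpoint(self, loaded_net):
        """The deviation threshold sits at the midpoint of the two error
        modes (full bimodality and its threshold-insensitivity are large-N
        properties exercised in the acceptance suite)."""
        spec, _, _ = loaded_net
        assert deviation_threshold(spec) == pytest.approx(0.5 * (0.02 + 0.32))


class TestSpontaneous:
    def test_raster_shape_and_determinism(self, loaded_net):
        spec, _, W = loaded_net
        a = spontaneous_run(W, spec, T=50, beta_retr=20.0, seed=7)
        b = spontaneous_run(W, spec, T=50, beta_retr=20.0, seed=7)
        assert a.states.shape == (50, 100)
        assert (a.states == b.states).all()

    def test_activity_persists(self, loaded_net):
        spec, _, W = loaded_net
        ras = spontaneous_run(W, spec, T=300, beta_retr=20.0, seed=8)
        assert ras.states[100:].mean() > 0.05

    def test_never_visits_loaded_states(self, loaded_net):
        """Spontaneous activity does not pass through any loaded state
        (state space is exponentially larger than the loaded set)."""
        spec, seq, W = loaded_net
        ras = spontaneous_run(W, spec, T=300, beta_retr=20.0, seed=9)
        loaded = {tuple(row) for row in seq.states}
        visited = {tuple(row) for row in ras.states[1:]}
        assert not (loaded & visited)


class TestDynamicsStats:
    def test_periodic_raster_zero_cv(self, loaded_net):
        spec, _, W = loaded_net
        states = np.zeros((120, 100), dtype=np.int8)
        states[::3, :] = 1  # perfectly periodic spiking
        ds = dynamics_stats(ActivityRaster(states=states), W, spec, transient=0)
        assert ds.cv_isi == pytest.approx(0.0, abs=1e-12)

    def test_independent_trains_uncorrelated(self, loaded_net):
        spec, _, W = loaded_net
        rng = np.random.default_rng(10)
        states = (rng.random((800, 100)) < 0.2).astype(np.int8)
        ds = dynamics_stats(ActivityRaster(states=states), W, spec, transient=0)
        assert abs(ds.cross_corr) < 3 / np.sqrt(800)

    def test_balanced_inputs_anticorrelated_vs_shuffle(self, loaded_net):
        """Loaded networks show stronger E/I anti-correlation than a
        sign-preserving weight-shuffled control."""
        spec, _, W = loaded_net
        ras = spontaneous_run(W, spec, T=400, beta_retr=20.0, seed=11)
        ds = dynamics_stats(ras, W, spec)
        rng = np.random.default_rng(12)
        J_shuf = W.J_tilde.copy()
        for cols in (spec.g < 0, spec.g > 0):
            block = J_shuf[:, cols].ravel()
            rng.shuffle(block)
            J_shuf[:, cols] = block.reshape(J_shuf[:, cols].shape)
        W_shuf = WeightMatrix(J_tilde=J_shuf, feasible=W.feasible, spec=spec)
        ras_s = spontaneous_run(W_shuf, spec, T=400, beta_retr=20.0, seed=11)
        ds_s = dynamics_stats(ras_s, W_shuf, spec)
        assert ds.ei_anticorr > ds_s.ei_anticorr

    def test_all_silent_raster_rejected(self, loaded_net):
        spec, _, W = loaded_net
        silent = ActivityRaster(states=np.zeros((50, 100), dtype=np.int8))
        with pytest.raises(ValueError):
            dynamics_stats(silent, W, spec, transient=0)


class TestConnectivityStats:
    def test_all_zero_flagged(self):
        spec = make_spec(20)
        W = WeightMatrix(J_tilde=np.zeros((20, 20)), feasible=np.ones(20, bool), spec=spec)
        out = connectivity_stats(W, spec)
        assert out["inh"]["P_con"] == 0.0
        assert np.isnan(out["inh"]["cv"])

    def test_inhibition_denser_than_excitation(self, loaded_net):
        spec, _, W = loaded_net
        out = connectivity_stats(W, spec)
        assert out["inh"]["P_con"] > out["exc"]["P_con"]
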