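"""Drift, Jacobian, edge-list loading and Langevin simulation."""

import numpy as np
import pytest

from drlandscape import (
    NetworkModel,
    SimulationConfig,
    fixture_misa,
    load_network,
    simulate_deterministic,
    simulate_langevin,
)
from drlandscape.fixtures import data_path
from drlandscape.grn_model import write_network

from conftest import random_network


class TestForce:
    def test_misa_at_origin_is_pure_inhibition_synthesis(self, misa):
        # self-activation vanishes at 0, each inhibition term contributes b
        np.testing.assert_allclose(misa.force(np.zeros(2)), [0.5, 0.5])

    def test_unregulated_network_decays_linearly(self, rng):
        model = NetworkModel(node_names=list("abc"), A=np.zeros((3, 3)),
                             B=np.zeros((3, 3)), k=1.0)
        x = rng.uniform(0, 2, 3)
        np.testing.assert_allclose(model.force(x), -x)

    def test_vanishes_at_stable_points(self, misa, misa_states):
        for s in misa_states:
            assert np.max(np.abs(misa.force(s.x_star))) < 1e-8

    def test_batched_evaluation_matches_loop(self, misa, rng):
        X = rng.uniform(0, 1.5, (10, 2))
        batch = misa.force(X)
        for i in range(10):
            np.testing.assert_allclose(batch[i], misa.force(X[i]))

    def test_permutation_equivariance(self, rng):
        model = random_network(rng, 4)
        perm = [2, 0, 3, 1]
        permuted = model.relabelled(perm)
        x = rng.uniform(0, 1.5, 4)
        np.testing.assert_allclose(
            permuted.force(x[perm]), model.force(x)[perm], atol=1e-12
        )

    def test_dimension_mismatch_raises(self, misa):
        with pytest.raises(ValueError):
            misa.force(np.zeros(3))


class TestJacobian:
    def test_unregulated_network_is_minus_k_identity(self):
        model = NetworkModel(node_names=list("ab"), A=np.zeros((2, 2)),
                             B=np.zeros((2, 2)), k=1.5)
        np.testing.assert_allclose(model.jacobian(np.ones(2)), -1.5 * np.eye(2))

    def test_misa_at_threshold_has_symmetric_hill_slope(self, misa):
        # at x = S the Hill derivative is n/(4S) = 2, so the analytic
        # entries are a*2 - k on the diagonal and -b*2 off it
        J = misa.jacobian(np.array([0.5, 0.5]))
        np.testing.assert_allclose(J, [[0.0, -1.0], [-1.0, 0.0]], atol=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_finite_differences(self, rng, trial):
        model = random_network(rng, int(rng.integers(2, 6)))
        x = rng.uniform(0.05, 1.5, model.n_nodes)
        J = model.jacobian(x)
        h = 1e-6
        for j in range(model.n_nodes):
            e = np.zeros(model.n_nodes)
            e[j] = h
            fd = (model.force(x + e) - model.force(x - e)) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-5, atol=1e-6)


class TestLoadNetwork:
    def test_bundled_misa_file_matches_programmatic_fixture(self, misa):
        loaded = load_network(data_path("misa.tsv"), data_path("misa.yaml"))
        np.testing.assert_allclose(loaded.A, misa.A)
        np.testing.assert_allclose(loaded.B, misa.B)
        np.testing.assert_allclose(loaded.S, misa.S)
        assert loaded.n == misa.n

    def test_empty_edge_list_gives_zero_matrices(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("source\ttarget\tsign\tstrength\n")
        model = load_network(p, {"k": 1.0}, node_names=["a", "b", "c"])
        assert model.n_nodes == 3
        assert not model.A.any() and not model.B.any()

    def test_blank_strength_uses_config_default(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("source\ttarget\tsign\tstrength\nx\ty\tactivate\t\ny\tx\tinhibit\t\n")
        model = load_network(p, {"a": 3.8, "b": 0.4})
        assert model.A[0, 1] == 3.8
        assert model.B[1, 0] == 0.4

    def test_duplicate_edge_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "source\ttarget\tsign\tstrength\nx\ty\tactivate\t1\nx\ty\tactivate\t2\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_network(p)

    def test_conflicting_sign_rejected(self, tmp_path):
        p = tmp_path / "conflict.tsv"
        p.write_text(
            "source\ttarget\tsign\tstrength\nx\ty\tactivate\t1\nx\ty\tinhibit\t2\n"
        )
        with pytest.raises(ValueError):
            load_network(p)

    def test_negative_strength_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("source\ttarget\tsign\tstrength\nx\ty\tactivate\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            load_network(p)

    def test_unknown_node_rejected_with_pinned_names(self, tmp_path):
        p = tmp_path / "unk.tsv"
        p.write_text("source\ttarget\tsign\tstrength\nx\tz\tactivate\t1\n")
        with pytest.raises(ValueError, match="unknown"):
            load_network(p, node_names=["x", "y"])

    def test_roundtrip_through_tsv(self, tmp_path, rng):
        model = random_network(rng, 4)
        p = tmp_path / "rt.tsv"
        write_network(model, p)
        loaded = load_network(
            p,
            {"S": float(model.S[0, 0]), "n": model.n, "k": 1.0},
            node_names=model.node_names,
        )
        np.testing.assert_allclose(loaded.A, model.A)
        np.testing.assert_allclose(loaded.B, model.B)


class TestValidation:
    def test_simultaneous_activation_and_inhibition_rejected(self):
        with pytest.raises(ValueError, match="both"):
            NetworkModel(node_names=["a"], A=np.array([[1.0]]), B=np.array([[1.0]]))

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            NetworkModel(node_names=["a"], A=np.zeros((1, 1)), B=np.zeros((1, 1)), S=0.0)

    def test_bad_sim_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(d=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(d=0.1, dt=0.5, t_end=0.1)


class TestSimulation:
    def test_small_noise_tracks_deterministic_solution(self, misa):
        x0 = np.array([0.9, 0.1])
        sim = SimulationConfig(d=1e-10, dt=0.01, t_end=20.0, seed=3)
        traj = simulate_langevin(misa, sim, x0)
        _, det = simulate_deterministic(misa, x0, 20.0)
        np.testing.assert_allclose(traj[-1, 0], det[-1], atol=1e-3)

    def test_ou_moments_match_closed_form(self):
        # pure degradation with basal synthesis is an OU process:
        # stationary mean g0/k, stationary variance d/k
        model = NetworkModel(
            node_names=["a"], A=np.zeros((1, 1)), B=np.zeros((1, 1)),
            k=1.0, g0=2.0,
        )
        sim = SimulationConfig(d=0.05, dt=0.01, t_end=600.0, seed=11,
                               n_trajectories=8)
        traj = simulate_langevin(model, sim, np.full((8, 1), 2.0))
        samples = traj[2000:].ravel()
        assert abs(samples.mean() - 2.0) < 0.02
        assert abs(samples.var() - 0.05) < 0.01

    def test_misa_occupancy_splits_evenly_between_mirror_basins(self, misa):
        sim = SimulationConfig(d=0.05, dt=0.01, t_end=400.0, seed=5,
                               n_trajectories=20)
        traj = simulate_langevin(misa, sim, np.full((20, 2), 0.5),
                                 record_every=10)
        samples = traj[400:].reshape(-1, 2)
        frac = np.mean(samples[:, 0] > samples[:, 1])
        assert 0.35 < frac < 0.65

    def test_divergence_detected(self):
        # a superlinear drift with a large step blows up Euler-Maruyama
        from drlandscape import CustomDrift

        model = CustomDrift(
            force_fn=lambda x: x**3,
            jacobian_fn=lambda x: np.diag(3 * x**2),
            n_nodes=1,
        )
        sim = SimulationConfig(d=1e-6, dt=1.0, t_end=50.0, seed=1)
        with pytest.raises(RuntimeError, match="diverged"):
            simulate_langevin(model, sim, np.array([2.0]))
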