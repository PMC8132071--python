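"""Eigenbasis, projection and gridded reduced landscapes."""

import dataclasses

import numpy as np
import pytest

from drlandscape import (
    GaussianComponent,
    MixtureDensity,
    build_mixture,
    compute_basis,
    density,
    find_stable_states,
    fixture_misa,
    fixture_quadrastable,
    grid_landscape,
    project_density,
    project_points,
)


def _mixture(rng, N=3, M=2, d_scale=0.05):
    comps = []
    w = rng.dirichlet(np.ones(M))
    for j in range(M):
        Q = np.linalg.qr(rng.standard_normal((N, N)))[0]
        sig = Q @ np.diag(rng.uniform(0.5, 2.0, N) * d_scale) @ Q.T
        comps.append(
            GaussianComponent(mu=rng.uniform(-1, 1, N), sigma=sig, weight=w[j])
        )
    return MixtureDensity(components=comps)


class TestComputeBasis:
    def test_diagonal_covariance_keeps_axes_and_contributions(self):
        basis = compute_basis(np.diag([4.0, 1.0]))
        np.testing.assert_allclose(np.abs(basis.W), np.eye(2), atol=1e-12)
        np.testing.assert_allclose(basis.contribution_rates, [80.0, 20.0])

    def test_misa_pc1_contribution_is_near_96_percent(self, misa_mixture):
        basis = compute_basis(misa_mixture)
        assert basis.contribution_rates[0] == pytest.approx(95.8, abs=0.3)

    def test_orthonormality_and_variance_identity(self, rng):
        mix = _mixture(rng)
        basis = compute_basis(mix)
        np.testing.assert_allclose(basis.W.T @ basis.W, np.eye(3), atol=1e-10)
        # variance of the mixture along w_i equals lambda_i exactly
        for i in range(3):
            w = basis.W[:, i]
            assert w @ mix.sigma @ w == pytest.approx(basis.lambdas[i], abs=1e-12)
        assert np.all(np.diff(basis.lambdas) <= 1e-12)
        assert basis.contribution_rates.sum() == pytest.approx(100.0)

    def test_sign_convention_largest_entry_positive(self, rng):
        basis = compute_basis(_mixture(rng))
        for i in range(basis.W.shape[1]):
            col = basis.W[:, i]
            assert col[np.argmax(np.abs(col))] > 0

    def test_contributions_invariant_to_relabeling_and_translation(self, rng):
        mix = _mixture(rng)
        basis = compute_basis(mix)
        perm = rng.permutation(3)
        permuted = MixtureDensity(
            components=[
                GaussianComponent(
                    mu=c.mu[perm] + 5.0,  # translation shifts means only
                    sigma=c.sigma[np.ix_(perm, perm)],
                    weight=c.weight,
                )
                for c in mix.components
            ]
        )
        basis_p = compute_basis(permuted)
        np.testing.assert_allclose(
            basis_p.contribution_rates, basis.contribution_rates, atol=1e-8
        )

    def test_nonsymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            compute_basis(np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_small_noise_limit_aligns_with_between_state_axis(self, misa):
        # as d -> 0 the leading PC converges to the inter-attractor axis
        states = find_stable_states(misa, n_starts=400, seed=1)
        states = [dataclasses.replace(s, weight=0.5) for s in states]
        basis = compute_basis(build_mixture(misa, states, d=1e-6))
        axis = states[0].x_star - states[1].x_star
        axis /= np.linalg.norm(axis)
        assert abs(abs(axis @ basis.W[:, 0]) - 1.0) < 1e-6


class TestProjectDensity:
    def test_full_rotation_preserves_density_pointwise(self, rng):
        mix = _mixture(rng)
        basis = compute_basis(mix)
        rotated = project_density(mix, basis, C=3)
        pts = rng.uniform(-1.5, 1.5, (50, 3))
        np.testing.assert_allclose(
            density(rotated, pts @ basis.W),  # z = W^T x
            density(mix, pts),
            rtol=1e-10,
        )

    def test_single_axis_marginal_of_axis_aligned_gaussian(self):
        c = GaussianComponent(
            mu=np.array([1.0, -2.0]), sigma=np.diag([4.0, 0.25]), weight=1.0
        )
        mix = MixtureDensity(components=[c])
        basis = compute_basis(mix)
        red = project_density(mix, basis, C=1)
        z = np.linspace(-6, 8, 50)[:, None]
        expected = np.exp(-((z.ravel() - 1.0) ** 2) / 8) / np.sqrt(8 * np.pi)
        np.testing.assert_allclose(density(red, z), expected, rtol=1e-10)

    def test_projected_density_matches_projected_monte_carlo(self, misa_mixture, rng):
        basis = compute_basis(misa_mixture)
        red = project_density(misa_mixture, basis, C=1)
        draws = misa_mixture.rvs(400_000, rng) @ basis.W[:, :1]
        hist, edges = np.histogram(draws.ravel(), bins=60, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        pred = density(red, centers[:, None])
        # compare where the histogram is well populated
        mask = hist > 0.05 * hist.max()
        np.testing.assert_allclose(pred[mask], hist[mask], rtol=0.1)

    def test_invalid_C_rejected(self, misa_mixture):
        basis = compute_basis(misa_mixture)
        with pytest.raises(ValueError):
            project_density(misa_mixture, basis, C=0)
        with pytest.raises(ValueError):
            project_density(misa_mixture, basis, C=5)


class TestProjectPoints:
    def test_round_trip_identity_at_full_dimension(self, rng):
        mix = _mixture(rng)
        basis = compute_basis(mix)
        pts = rng.uniform(-1, 1, (20, 3))
        z = project_points(pts, basis, C=3)
        np.testing.assert_allclose(z @ basis.W.T, pts, atol=1e-12)

    def test_stable_states_land_in_minimum_cells(self, misa_mixture):
        basis = compute_basis(misa_mixture)
        red = project_density(misa_mixture, basis, C=1)
        land = grid_landscape(red, resolution=200)
        z = project_points(
            np.array([c.mu for c in misa_mixture.components]), basis, C=1
        )
        ax = land.grid_axes[0]
        minima_pos = sorted(ax[i] for (i,) in land.minima)
        for zi in sorted(z.ravel()):
            assert min(abs(zi - m) for m in minima_pos) < 2 * (ax[1] - ax[0])

    def test_dimension_mismatch_rejected(self, misa_mixture):
        basis = compute_basis(misa_mixture)
        with pytest.raises(ValueError):
            project_points(np.zeros((3, 5)), basis, C=1)


class TestGridLandscape:
    def test_symmetric_switch_has_two_equal_depth_minima(self, misa):
        # equal analytic weights: sampling noise must not tilt the basins
        states = find_stable_states(misa, n_starts=400, seed=1)
        states = [dataclasses.replace(s, weight=0.5) for s in states]
        mix = build_mixture(misa, states, d=0.02)
        basis = compute_basis(mix)
        land = grid_landscape(project_density(mix, basis, C=1), resolution=301)
        assert len(land.minima) == 2
        depths = sorted(land.U[m] for m in land.minima)
        assert depths[1] - depths[0] < 1e-6

    def test_single_gaussian_is_a_paraboloid_with_one_minimum(self):
        c = GaussianComponent(mu=np.array([0.3, -0.7]), sigma=0.1 * np.eye(2),
                              weight=1.0)
        mix = MixtureDensity(components=[c])
        basis = compute_basis(mix)
        land = grid_landscape(project_density(mix, basis, 2), resolution=101)
        assert len(land.minima) == 1
        cell = land.minima[0]
        expected = project_points(c.mu, basis, 2)[0]
        np.testing.assert_allclose(land.axis_coords(cell), expected, atol=0.05)

    def test_quadrastable_network_shows_four_minima(self):
        model = fixture_quadrastable()
        states = find_stable_states(model, n_starts=600, seed=3)
        mix = build_mixture(model, states, d=0.005)
        basis = compute_basis(mix)
        land = grid_landscape(project_density(mix, basis, 2), resolution=150)
        assert len(land.minima) == 4

    def test_cap_and_shift_modes(self, misa_mixture):
        basis = compute_basis(misa_mixture)
        red = project_density(misa_mixture, basis, 1)
        raw = grid_landscape(red, resolution=64, u_cap=30.0)
        shifted = grid_landscape(red, resolution=64, u_cap=30.0, shift=True)
        assert raw.U.max() <= 30.0
        assert shifted.U.min() == pytest.approx(0.0, abs=1e-12)
        assert shifted.shifted and not raw.shifted

    def test_low_resolution_rejected(self, misa_mixture):
        basis = compute_basis(misa_mixture)
        red = project_density(misa_mixture, basis, 1)
        with pytest.raises(ValueError, match="resolution"):
            grid_landscape(red, resolution=8)
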