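"""Dimension reduction of the landscape.

The mixture's global covariance is eigendecomposed; the orthonormal
eigenvectors sorted by decreasing eigenvalue define the principal
coordinates.  Because an orthogonal change of variables maps Gaussians to
Gaussians, projecting the mixture onto the leading C coordinates is
closed-form: component j keeps its weight, its mean becomes the first C
entries of W^T mu_j and its covariance the leading C x C block of
W^T Sigma_j W.  The reduced landscape is U = -ln p evaluated on a regular
grid in the retained coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tme import GaussianComponent, MixtureDensity

__all__ = [
    "ProjectionBasis",
    "ReducedLandscape",
    "compute_basis",
    "project_density",
    "grid_landscape",
    "project_points",
]

DEFAULT_U_CAP = 50.0
DEGENERATE_REL = 1e-12  # eigenvalues below this fraction of lambda_1 count as 0


@dataclass
class ProjectionBasis:
    """Orthonormal eigenbasis of the mixture covariance.

    Columns of W are eigenvectors sorted by decreasing eigenvalue; each
    column's sign is fixed so its largest-magnitude entry is positive.
    ``contribution_rates`` are the eigenvalues' percentage shares of the
    total variance (the covariance trace).
    """

    W: np.ndarray
    lambdas: np.ndarray
    contribution_rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lam = np.where(
            self.lambdas < DEGENERATE_REL * max(self.lambdas[0], 0.0),
            0.0,
            self.lambdas,
        )
        self.lambdas = lam
        total = lam.sum()
        self.contribution_rates = (
            100.0 * lam / total if total > 0 else np.zeros_like(lam)
        )


@dataclass
class ReducedLandscape:
    """Gridded potential U = -ln p in the retained principal coordinates."""

    basis: ProjectionBasis
    C: int
    grid_axes: list[np.ndarray]
    U: np.ndarray
    P: np.ndarray
    minima: list[tuple[int, ...]]
    u_cap: float
    shifted: bool

    def axis_coords(self, cell: tuple[int, ...]) -> np.ndarray:
        return np.array([ax[i] for ax, i in zip(self.grid_axes, cell)])

    @property
    def cell_volume(self) -> float:
        return float(np.prod([ax[1] - ax[0] for ax in self.grid_axes]))


def compute_basis(mix: MixtureDensity | np.ndarray) -> ProjectionBasis:
    """Eigendecompose a mixture's global covariance (or a covariance matrix).

    Eigenvalues are sorted descending; exact ties keep ascending
    original-axis order (stable sort).  Raises on a non-symmetric matrix.
    """
    sigma = mix.sigma if isinstance(mix, MixtureDensity) else np.asarray(mix, float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    lam, vec = np.linalg.eigh(0.5 * (sigma + sigma.T))
    order = np.argsort(-lam, kind="stable")
    lam = lam[order]
    vec = vec[:, order]
    if lam[-1] < -1e-10:
        raise ValueError(f"covariance not PSD (min eigenvalue {lam[-1]:.3g})")
    lam = np.maximum(lam, 0.0)
    # sign convention: largest-magnitude entry of each eigenvector positive
    for i in range(vec.shape[1]):
        j = np.argmax(np.abs(vec[:, i]))
        if vec[j, i] < 0:
            vec[:, i] = -vec[:, i]
    return ProjectionBasis(W=vec, lambdas=lam)


def project_density(
    mix: MixtureDensity, basis: ProjectionBasis, C: int
) -> MixtureDensity:
    """Marginal of the rotated mixture on the leading C principal coordinates."""
    N = mix.n_dim
    if not (1 <= C <= N):
        raise ValueError(f"C must lie in [1, {N}]")
    WC = basis.W[:, :C]
    comps = [
        GaussianComponent(
            mu=WC.T @ c.mu,
            sigma=WC.T @ c.sigma @ WC,
            weight=c.weight,
            label=c.label,
        )
        for c in mix.components
    ]
    return MixtureDensity(components=comps, d=mix.d)


def project_points(points: np.ndarray, basis: ProjectionBasis, C: int) -> np.ndarray:
    """Project K x N points (paths, stable states) into the leading C coordinates."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    N = basis.W.shape[0]
    if points.shape[-1] != N:
        raise ValueError(f"points have dimension {points.shape[-1]}, basis has {N}")
    if not (1 <= C <= N):
        raise ValueError(f"C must lie in [1, {N}]")
    return points @ basis.W[:, :C]


def _local_minima(U: np.ndarray, u_cap: float) -> list[tuple[int, ...]]:
    """Grid cells strictly not above any full-connectivity neighbor."""
    ndim = U.ndim
    pad = np.pad(U, 1, mode="constant", constant_values=np.inf)
    is_min = np.ones_like(U, dtype=bool)
    core = tuple(slice(1, -1) for _ in range(ndim))
    for offset in np.ndindex(*(3,) * ndim):
        if all(o == 1 for o in offset):
            continue
        sl = tuple(slice(o, o + s) for o, s in zip(offset, U.shape))
        is_min &= U <= pad[sl]
    is_min &= U < u_cap
    # collapse plateaus: keep one representative per connected flat minimum
    cells = [tuple(int(v) for v in c) for c in np.argwhere(is_min)]
    kept: list[tuple[int, ...]] = []
    for c in cells:
        if not any(
            all(abs(a - b) <= 1 for a, b in zip(c, k)) and U[c] == U[k] for k in kept
        ):
            kept.append(c)
    return kept


def grid_landscape(
    reduced: MixtureDensity,
    resolution: int = 200,
    padding: float = 3.0,
    u_cap: float = DEFAULT_U_CAP,
    basis: ProjectionBasis | None = None,
    shift: bool = False,
) -> ReducedLandscape:
    """Evaluate U = -ln p on a regular grid in the reduced coordinates.

    The grid spans the projected component means plus/minus ``padding``
    standard deviations per axis.  Density underflow is capped at
    ``u_cap``; with ``shift=True`` the potential is shifted so its grid
    minimum is zero (the mode is recorded on the result).

    Restricted to C in {1, 2, 3}: beyond three retained coordinates a
    dense grid is no longer a sensible representation.
    """
    C = reduced.n_dim
    if C not in (1, 2, 3):
        raise ValueError("gridded landscapes support 1-3 retained coordinates")
    if resolution < 16:
        raise ValueError("resolution below 16 cannot resolve basins")
    axes = []
    for dim in range(C):
        mus = np.array([c.mu[dim] for c in reduced.components])
        sds = np.array([np.sqrt(c.sigma[dim, dim]) for c in reduced.components])
        lo = np.min(mus - padding * sds)
        hi = np.max(mus + padding * sds)
        axes.append(np.linspace(lo, hi, resolution))
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    P = reduced.pdf(pts).reshape(mesh[0].shape)
    floor = np.exp(-u_cap)
    U = np.where(P > floor, -np.log(np.maximum(P, floor)), u_cap)
    shiftval = U.min() if shift else 0.0
    U = U - shiftval
    cap = u_cap - shiftval
    minima = _local_minima(U, cap)
    if basis is None:
        basis = compute_basis(reduced)
    return ReducedLandscape(
        basis=basis,
        C=C,
        grid_axes=axes,
        U=U,
        P=P,
        minima=minima,
        u_cap=float(cap),
        shifted=shift,
    )
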