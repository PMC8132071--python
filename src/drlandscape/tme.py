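"""Gaussian-mixture approximation of the steady-state density.

For small constant diffusion d, the probability density around each
stable fixed point is approximated by a Gaussian whose mean sits at the
fixed point and whose covariance solves the stationary moment equation

    J Sigma + Sigma J^T + 2 d I = 0,

the algebraic continuous-time Lyapunov equation with J the drift Jacobian
at the fixed point.  A multistable system is represented by the weighted
mixture of these Gaussians, with weights given by the basin fractions.
The mixture's global mean and covariance follow the standard moment
identities and feed the eigendecomposition that defines the reduced
landscape coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_lyapunov

from .attractors import StableState

__all__ = [
    "GaussianComponent",
    "MixtureDensity",
    "stationary_covariance",
    "build_mixture",
    "density",
]


@dataclass
class GaussianComponent:
    """One Gaussian basin: weight phi_j, mean mu_j, covariance Sigma_j."""

    mu: np.ndarray
    sigma: np.ndarray
    weight: float
    label: str = ""

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (0 < self.weight <= 1):
            raise ValueError("component weight must lie in (0, 1]")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("component covariance must be symmetric")


@dataclass
class MixtureDensity:
    """Weighted Gaussian mixture with cached global moments.

    ``mu`` and ``sigma`` are the mixture mean and covariance:
    mu = sum_j phi_j mu_j and
    Sigma = sum_j phi_j (Sigma_j + mu_j mu_j^T) - mu mu^T.
    """

    components: list[GaussianComponent]
    d: float = float("nan")
    mu: np.ndarray = field(init=False)
    sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        w = np.array([c.weight for c in self.components])
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError(f"component weights sum to {w.sum()}, not 1")
        mus = np.array([c.mu for c in self.components])
        self.mu = w @ mus
        self.sigma = sum(
            c.weight * (c.sigma + np.outer(c.mu, c.mu)) for c in self.components
        ) - np.outer(self.mu, self.mu)

    @property
    def n_dim(self) -> int:
        return self.mu.shape[0]

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return density(self, x)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` samples from the mixture."""
        w = np.array([c.weight for c in self.components])
        counts = rng.multinomial(size, w)
        chunks = [
            rng.multivariate_normal(c.mu, c.sigma, size=m, method="cholesky")
            for c, m in zip(self.components, counts)
            if m > 0
        ]
        out = np.concatenate(chunks, axis=0)
        rng.shuffle(out, axis=0)
        return out

    def spread_diagnostic(self) -> float:
        """Ratio of component spread to inter-mean separation.

        The Gaussian-mixture closure assumes components are narrow
        relative to the distance between basins; this unitless ratio
        (largest component standard deviation over smallest inter-mean
        distance) is reported as a small-noise diagnostic.  No hard
        cutoff is applied.
        """
        if len(self.components) < 2:
            return 0.0
        sig = max(np.sqrt(np.linalg.eigvalsh(c.sigma)[-1]) for c in self.components)
        dmin = min(
            np.linalg.norm(a.mu - b.mu)
            for i, a in enumerate(self.components)
            for b in self.components[i + 1 :]
        )
        return float(sig / dmin) if dmin > 0 else float("inf")

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "d": self.d,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "components": [
                {
                    "weight": c.weight,
                    "label": c.label,
                    "mu": c.mu.tolist(),
                    "sigma": c.sigma.tolist(),
                }
                for c in self.components
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MixtureDensity":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        comps = [
            GaussianComponent(
                mu=np.array(c["mu"]),
                sigma=np.array(c["sigma"]),
                weight=c["weight"],
                label=c.get("label", ""),
            )
            for c in payload["components"]
        ]
        return cls(components=comps, d=payload.get("d", float("nan")))


def stationary_covariance(
    model,
    state: StableState,
    d: float,
    method: str = "lyapunov",
    t_end: float = 200.0,
) -> np.ndarray:
    """Stationary covariance of the linearized fluctuations around a stable state.

    Solves ``J Sigma + Sigma J^T = -2 d I`` for the Jacobian J at the fixed
    point (``method="lyapunov"``, the default: the exact stationary limit),
    or integrates the time-dependent covariance equation
    ``dSigma/dt = J Sigma + Sigma J^T + 2 d I`` from zero to ``t_end``
    (``method="integrate"``); both converge to the same matrix for a
    stable Jacobian.
    """
    if d <= 0:
        raise ValueError("diffusion coefficient d must be positive")
    J = model.jacobian(state.x_star)
    ev = np.linalg.eigvals(J)
    if np.max(ev.real) >= 0:
        raise ValueError(
            "Jacobian has an eigenvalue with non-negative real part "
            f"(max Re = {np.max(ev.real):.3g}); the stationary covariance "
            "exists only at a linearly stable fixed point"
        )
    if method == "lyapunov":
        sigma = solve_lyapunov(J, -2.0 * d * np.eye(model.n_nodes))
    elif method == "integrate":
        from scipy.integrate import solve_ivp

        N = model.n_nodes

        def rhs(t, s):
            S = s.reshape(N, N)
            return (J @ S + S @ J.T + 2.0 * d * np.eye(N)).ravel()

        sol = solve_ivp(rhs, (0.0, t_end), np.zeros(N * N), method="LSODA", rtol=1e-10)
        if not sol.success:
            raise RuntimeError(f"covariance integration failed: {sol.message}")
        sigma = sol.y[:, -1].reshape(N, N)
    else:
        raise ValueError(f"unknown method {method!r}")
    return 0.5 * (sigma + sigma.T)


def build_mixture(model, states: list[StableState], d: float) -> MixtureDensity:
    """One Gaussian component per stable state, weighted by basin fractions.

    Components are never pruned, however small their weight: shallow
    basins must still appear on the landscape.
    """
    if not states:
        raise ValueError("need at least one stable state")
    comps = [
        GaussianComponent(
            mu=s.x_star,
            sigma=stationary_covariance(model, s, d),
            weight=s.weight,
            label=s.label,
        )
        for s in states
    ]
    return MixtureDensity(components=comps, d=d)


def _gauss_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    N = mu.shape[0]
    L = np.linalg.cholesky(sigma)
    diff = np.atleast_2d(x) - mu
    y = np.linalg.solve(L, diff.T)
    maha = np.sum(y * y, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (N * np.log(2.0 * np.pi) + logdet + maha)


def density(mix: MixtureDensity, x: np.ndarray) -> np.ndarray:
    """Mixture probability density at x (single state or batch (..., N))."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x).reshape(-1, mix.n_dim)
    p = np.zeros(pts.shape[0])
    for c in mix.components:
        p += c.weight * np.exp(_gauss_logpdf(pts, c.mu, c.sigma))
    if single:
        return float(p[0])
    return p.reshape(x.shape[:-1])
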