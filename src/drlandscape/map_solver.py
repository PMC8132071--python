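"""Minimum action paths and transition actions between attractors.

For a drift f with weak additive noise, the probability of a transition
path x(t) on [0, T] is controlled by the Freidlin-Wentzell action

    S[x] = 1/2 * integral_0^T || dx/dt - f(x(t)) ||^2 dt

with the endpoints pinned to the two attractors.  The most probable
(minimum action) path at fixed terminal time T is found by quasi-Newton
minimization over the interior points of a uniformly discretized path.

Discretization (fixed, so results are bit-reproducible given a path):
with K points at spacing dt = T/(K-1), velocities are forward
differences v_m = (x_{m+1} - x_m)/dt, the drift is evaluated at segment
midpoints (x_m + x_{m+1})/2, and the action is the midpoint-rule sum
S = dt/2 * sum_m ||v_m - f(midpoint_m)||^2 over the K-1 segments.  The
gradient with respect to the interior points is assembled analytically
from the drift Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "TransitionPath",
    "ActionSummary",
    "action",
    "minimize_action",
    "t_scan",
    "path_distance",
    "normalize_path",
    "concatenate_paths",
    "resample_path",
]

GRAD_TOL = 1e-6
MAX_ITER = 10_000
DEFAULT_K = 101
DEFAULT_RESTARTS = 3


@dataclass
class TransitionPath:
    """A discretized path on a uniform time grid with its action."""

    points: np.ndarray  # (K, N)
    T: float
    action: float
    from_state: str = ""
    to_state: str = ""
    converged: bool = True
    n_iterations: int = 0

    @property
    def K(self) -> int:
        return self.points.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.K)


@dataclass
class ActionSummary:
    """Action-vs-terminal-time table for one attractor pair."""

    from_state: str
    to_state: str
    T_values: np.ndarray
    actions: np.ndarray
    paths: list[TransitionPath] = field(default_factory=list)

    @property
    def monotone_nonincreasing(self) -> bool:
        # the continuum action is non-increasing in T; at fixed K the
        # O((T/K)^2) discretization error can add sub-percent wiggles
        return bool(np.all(np.diff(self.actions) <= 1e-9 + 1e-2 * self.actions[:-1]))


def _action_and_grad(model, X: np.ndarray, dt: float):
    mid = 0.5 * (X[:-1] + X[1:])
    v = (X[1:] - X[:-1]) / dt
    F = np.array([model.force(m) for m in mid])
    r = v - F
    S = 0.5 * dt * float(np.sum(r * r))
    J = np.array([model.jacobian(m) for m in mid])  # (K-1, N, N)
    JTr = np.einsum("mji,mj->mi", J, r)
    g = np.zeros_like(X)
    g[1:] += r - 0.5 * dt * JTr
    g[:-1] += -r - 0.5 * dt * JTr
    return S, g


def action(model, path: TransitionPath | np.ndarray, T: float | None = None) -> float:
    """Discretized Freidlin-Wentzell action of a path (see module docstring)."""
    if isinstance(path, TransitionPath):
        X, T = path.points, path.T
    else:
        X = np.asarray(path, dtype=float)
        if T is None:
            raise ValueError("T is required when passing a bare point array")
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("path needs at least 3 points of shape (K, N)")
    if not np.all(np.isfinite(X)):
        raise ValueError("path contains non-finite values")
    dt = T / (X.shape[0] - 1)
    S, _ = _action_and_grad(model, X, dt)
    return S


def minimize_action(
    model,
    from_point: np.ndarray,
    to_point: np.ndarray,
    T: float,
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    init_path: np.ndarray | None = None,
    jitter: float = 0.05,
    labels: tuple[str, str] = ("", ""),
) -> TransitionPath:
    """Minimize the transition action between two fixed endpoints.

    Runs L-BFGS-B on the flattened interior points starting from the
    straight-line path, plus ``n_restarts - 1`` seeded jittered restarts;
    the lowest-action result is returned.  Convergence requires the
    projected-gradient infinity norm below 1e-6 (or the iteration cap);
    a non-converged best path is still returned, flagged.
    """
    x0 = np.asarray(from_point, dtype=float)
    x1 = np.asarray(to_point, dtype=float)
    N = x0.shape[0]
    if K < 3:
        raise ValueError("K must be at least 3")
    dt = T / (K - 1)
    base = (
        np.asarray(init_path, dtype=float)
        if init_path is not None
        else np.linspace(0, 1, K)[:, None] * (x1 - x0) + x0
    )
    if base.shape != (K, N):
        base = resample_path(base, K)
    rng = np.random.default_rng(seed)
    scale = max(float(np.max(np.abs(x1 - x0))), 1e-3)

    def objective(flat: np.ndarray):
        X = np.vstack([x0, flat.reshape(K - 2, N), x1])
        S, g = _action_and_grad(model, X, dt)
        return S, g[1:-1].ravel()

    best = None
    for trial in range(max(1, n_restarts)):
        init = base[1:-1].copy()
        if trial > 0:
            bump = rng.standard_normal((K - 2, N)) * jitter * scale
            taper = np.sin(np.pi * np.linspace(0, 1, K)[1:-1])[:, None]
            init = init + bump * taper
        res = minimize(
            objective,
            init.ravel(),
            jac=True,
            method="L-BFGS-B",
            options=dict(maxiter=MAX_ITER, ftol=1e-14, gtol=GRAD_TOL),
        )
        if best is None or res.fun < best.fun:
            best = res
    X = np.vstack([x0, best.x.reshape(K - 2, N), x1])
    return TransitionPath(
        points=X,
        T=T,
        action=float(best.fun),
        from_state=labels[0],
        to_state=labels[1],
        converged=bool(best.success),
        n_iterations=int(best.nit),
    )


def t_scan(
    model,
    from_point: np.ndarray,
    to_point: np.ndarray,
    T_list,
    K: int = DEFAULT_K,
    seed: int = 0,
    labels: tuple[str, str] = ("", ""),
) -> ActionSummary:
    """Minimized action at each terminal time, warm-starting from the last path.

    T values must be increasing; each optimization is initialized with the
    previous terminal time's minimizer resampled to K points (the first
    uses the straight line).
    """
    T_arr = np.asarray(list(T_list), dtype=float)
    if np.any(np.diff(T_arr) <= 0):
        raise ValueError("T_list must be strictly increasing")
    paths: list[TransitionPath] = []
    prev = None
    for T in T_arr:
        p = minimize_action(
            model,
            from_point,
            to_point,
            T,
            K=K,
            seed=seed,
            n_restarts=1 if prev is not None else DEFAULT_RESTARTS,
            init_path=None if prev is None else prev.points,
            labels=labels,
        )
        paths.append(p)
        prev = p
    return ActionSummary(
        from_state=labels[0],
        to_state=labels[1],
        T_values=T_arr,
        actions=np.array([p.action for p in paths]),
        paths=paths,
    )


def resample_path(points: np.ndarray, K: int) -> np.ndarray:
    """Linear resampling of a path to K points, uniform in arc-time."""
    points = np.asarray(points, dtype=float)
    old = np.linspace(0.0, 1.0, points.shape[0])
    new = np.linspace(0.0, 1.0, K)
    return np.stack(
        [np.interp(new, old, points[:, j]) for j in range(points.shape[1])], axis=1
    )


def path_distance(path_x: np.ndarray, path_y: np.ndarray) -> float:
    """Distance between two N-dimensional K-point paths.

    Dis = (1/N) * sum over points of the Euclidean distance between the
    paired points.  Paths of different length are first linearly resampled
    to a common K.
    """
    X = _points_of(path_x)
    Y = _points_of(path_y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"path dimensions differ: {X.shape[1]} vs {Y.shape[1]}")
    if X.shape[0] != Y.shape[0]:
        K = max(X.shape[0], Y.shape[0])
        X = resample_path(X, K)
        Y = resample_path(Y, K)
    N = X.shape[1]
    return float(np.sum(np.linalg.norm(X - Y, axis=1)) / N)


def _points_of(path) -> np.ndarray:
    return path.points if isinstance(path, TransitionPath) else np.asarray(path, float)


def normalize_path(path) -> np.ndarray:
    """Min-max scale each component of a path to [0, 1] along the path.

    Components constant along the path map to 0.5 everywhere (no dynamic
    range to display).  Used for heat-map views of which components move
    first along a transition.
    """
    X = _points_of(path)
    if X.shape[0] < 2:
        raise ValueError("path needs at least 2 points")
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    out = np.full_like(X, 0.5)
    moving = rng > 1e-12
    out[:, moving] = (X[:, moving] - lo[moving]) / rng[moving]
    return out


def concatenate_paths(first, second, K: int | None = None) -> np.ndarray:
    """Join two paths sharing an intermediate endpoint; resample to K points.

    The indirect route through an intermediate attractor is represented by
    the two independently minimized legs concatenated at that attractor.
    """
    A = _points_of(first)
    B = _points_of(second)
    if not np.allclose(A[-1], B[0], atol=1e-6):
        raise ValueError("paths do not share the intermediate point")
    joined = np.vstack([A, B[1:]])
    if K is not None:
        joined = resample_path(joined, K)
    return joined
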