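"""Stable fixed points of the deterministic network dynamics.

Attractors are located by integrating the ODE from many random initial
conditions, polishing the endpoints with Newton's method, deduplicating,
and keeping only the linearly stable roots.  The fraction of initial
conditions captured by each attractor estimates its basin weight phi_j,
which later serves as the mixture weight of the corresponding Gaussian
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

__all__ = ["StableState", "find_stable_states", "classify_states"]

ROOT_TOL = 1e-8  # infinity-norm residual accepted for a fixed point
DEDUP_RTOL = 1e-4  # relative L-inf tolerance for merging duplicate roots
STABILITY_EPS = -1e-9  # max Re(eig) must fall below this


@dataclass
class StableState:
    """A linearly stable fixed point with its basin weight."""

    x_star: np.ndarray
    jac_eigs: np.ndarray
    weight: float
    label: str

    @property
    def is_stable(self) -> bool:
        return float(np.max(self.jac_eigs.real)) < STABILITY_EPS


def _integrate_ensemble(model, x0: np.ndarray, t_end: float, dt: float) -> np.ndarray:
    """Fixed-step RK4 relaxation of a batch of states toward attractors.

    The relaxation only needs to deliver each start into the right basin
    (Newton polishing supplies the precision), so a robust fixed-step
    integrator over the whole batch is preferred over per-start adaptive
    solves.
    """
    x = x0.copy()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = model.force(x)
        k2 = model.force(x + 0.5 * dt * k1)
        k3 = model.force(x + 0.5 * dt * k2)
        k4 = model.force(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.maximum(x, 0.0, out=x)
    return x


def find_stable_states(
    model,
    n_starts: int = 1000,
    seed: int = 0,
    t_end: float = 80.0,
    dt: float = 0.05,
    x_max: np.ndarray | None = None,
) -> list[StableState]:
    """Locate all stable fixed points and estimate their basin weights.

    Initial conditions are sampled uniformly in ``[0, x_max]^N`` where
    ``x_max`` defaults to the model's steady-state upper bound (every Hill
    term is at most 1).  Weight = fraction of converged starts captured by
    each attractor.

    Raises
    ------
    RuntimeError
        If no start converges to a stable fixed point (limit cycle or
        divergence).
    """
    if n_starts < 100:
        raise ValueError("n_starts must be at least 100 for stable weights")
    N = model.n_nodes
    rng = np.random.default_rng(seed)
    if x_max is None:
        x_max = model.state_upper_bound()
    x0 = rng.uniform(0.0, 1.0, size=(n_starts, N)) * np.asarray(x_max)

    endpoints = _integrate_ensemble(model, x0, t_end, dt)

    scale = np.maximum(np.max(np.abs(endpoints), axis=0), 1.0)
    attractors: list[np.ndarray] = []
    eigs: list[np.ndarray] = []
    assignment = np.full(n_starts, -1)
    failed: list[int] = []
    for idx in range(n_starts):
        xe = endpoints[idx]
        # match against known attractors first
        matched = False
        for a_idx, xa in enumerate(attractors):
            if np.max(np.abs(xe - xa) / scale) < 100 * DEDUP_RTOL:
                assignment[idx] = a_idx
                matched = True
                break
        if matched:
            continue
        sol = root(model.force, xe, jac=model.jacobian, method="hybr")
        xs = np.maximum(sol.x, 0.0)
        if not sol.success or np.max(np.abs(model.force(xs))) > ROOT_TOL:
            failed.append(idx)
            continue
        ev = np.linalg.eigvals(model.jacobian(xs))
        if np.max(ev.real) >= STABILITY_EPS:
            failed.append(idx)
            continue
        dup = None
        for a_idx, xa in enumerate(attractors):
            if np.max(np.abs(xs - xa) / scale) < DEDUP_RTOL:
                dup = a_idx
                break
        if dup is None:
            attractors.append(xs)
            eigs.append(ev)
            assignment[idx] = len(attractors) - 1
        else:
            assignment[idx] = dup

    if not attractors:
        raise RuntimeError(
            "no stable fixed point found (limit cycle or divergence); "
            f"non-convergent starts: {failed[:10]}{'...' if len(failed) > 10 else ''}"
        )
    if failed:
        warnings.warn(
            f"{len(failed)} of {n_starts} starts did not converge to a stable "
            "fixed point and are excluded from the weights",
            stacklevel=2,
        )
    counts = np.bincount(assignment[assignment >= 0], minlength=len(attractors))
    weights = counts / counts.sum()
    order = np.argsort(-weights, kind="stable")
    return [
        StableState(
            x_star=attractors[i],
            jac_eigs=eigs[i],
            weight=float(weights[i]),
            label=f"state_{rank + 1}",
        )
        for rank, i in enumerate(order)
    ]


def classify_states(
    states: list[StableState],
    markers: dict[str, dict[str, str]],
    node_names: list[str],
) -> list[str]:
    """Label stable states by qualitative high/low marker rules.

    ``markers`` maps a label to per-node rules, e.g.
    ``{"M": {"HIF1": "high", "ZEB1": "high"}}``.  "High" and "low" are
    decided against the midpoint of each node's range across the supplied
    states (the convention for turning qualitative descriptions into
    thresholds).  States matching no rule keep their own label and are
    flagged with a warning; two states matching one label are both
    reported under it with a warning.
    """
    if not markers:
        return [s.label for s in states]
    name_idx = {n: i for i, n in enumerate(node_names)}
    for label, rules in markers.items():
        for node in rules:
            if node not in name_idx:
                raise ValueError(f"marker rule for {label} references unknown node {node}")
    X = np.array([s.x_star for s in states])
    lo, hi = X.min(axis=0), X.max(axis=0)
    mid = 0.5 * (lo + hi)

    labels = []
    for s in states:
        hits = []
        for label, rules in markers.items():
            ok = True
            for node, level in rules.items():
                i = name_idx[node]
                high = s.x_star[i] > mid[i]
                if (level.lower() == "high") != high:
                    ok = False
                    break
            if ok:
                hits.append(label)
        if not hits:
            warnings.warn(f"state {s.label} matches no marker rule", stacklevel=2)
            labels.append(s.label)
        else:
            if len(hits) > 1:
                warnings.warn(
                    f"state {s.label} matches several rules {hits}; keeping first",
                    stacklevel=2,
                )
            labels.append(hits[0])
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = [lab for lab, c in seen.items() if c > 1 and lab in markers]
    if dups:
        warnings.warn(f"labels assigned to several states: {dups}", stacklevel=2)
    return labels
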