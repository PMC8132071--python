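"""Parameter-perturbation robustness and link-strength sensitivity.

Three analyses around a default parameterization:

* ``perturb_and_collect`` — draw many parameter sets with every nonzero
  regulation strength scaled independently and uniformly within a
  fractional range, pool the stable states of all sets, and hierarchically
  cluster the pooled state matrix (per-node z-score, Euclidean distance,
  average linkage) to check that the default attractor groups persist.
* ``robust_paths`` — the same sampling at a tighter range, additionally
  computing minimum action paths per set and projecting states and paths
  onto the principal components of the pooled states.
* ``global_sensitivity`` — one-at-a-time +/-delta scaling of each nonzero
  regulation strength, recording the percent change of the forward and
  backward transition actions between two named attractors and the
  sensitivity score (backward change minus forward change).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .attractors import StableState, find_stable_states
from .drl import ProjectionBasis, compute_basis, project_points
from .grn_model import NetworkModel
from .map_solver import TransitionPath, minimize_action

__all__ = [
    "PerturbationEnsemble",
    "SensitivityRecord",
    "RobustPathsResult",
    "perturb_and_collect",
    "robust_paths",
    "global_sensitivity",
    "nonzero_links",
]

logger = logging.getLogger(__name__)


def nonzero_links(model: NetworkModel) -> list[tuple[str, int, int]]:
    """The perturbable parameters: nonzero entries of A and B.

    Returns (matrix, source index, target index) triples, activations
    first, in row-major order.
    """
    links = [("A", j, i) for j, i in np.argwhere(model.A > 0)]
    links += [("B", j, i) for j, i in np.argwhere(model.B > 0)]
    return [(m, int(j), int(i)) for m, j, i in links]


def _scaled_model(model: NetworkModel, factors: dict[tuple[str, int, int], float]) -> NetworkModel:
    A = model.A.copy()
    B = model.B.copy()
    for (mat, j, i), f in factors.items():
        (A if mat == "A" else B)[j, i] *= f
    return NetworkModel(
        node_names=list(model.node_names),
        A=A,
        B=B,
        S=model.S,
        n=model.n,
        k=model.k,
        g0=model.g0,
    )


@dataclass
class PerturbationEnsemble:
    n_sets: int
    scale_range: tuple[float, float]
    seed: int
    set_ids: np.ndarray  # (n_states,)
    states: np.ndarray  # (n_states, N)
    cluster_labels: np.ndarray  # (n_states,)
    n_failed_sets: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.max())


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd


def cluster_states(states: np.ndarray, n_clusters: int) -> np.ndarray:
    """Average-linkage Euclidean clustering of z-scored state vectors."""
    Z = linkage(_zscore_columns(np.asarray(states, float)), method="average")
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def perturb_and_collect(
    model: NetworkModel,
    scale_range: tuple[float, float] = (0.75, 1.25),
    n_sets: int = 1000,
    seed: int = 0,
    n_clusters: int | None = None,
    n_starts: int = 200,
) -> PerturbationEnsemble:
    """Pool stable states across randomly perturbed parameter sets and cluster.

    Every nonzero regulation strength is scaled by an independent uniform
    factor within ``range`` per set.  Sets with no stable state are logged
    and skipped.  ``n_clusters`` defaults to the default model's stable
    state count.
    """
    lo, hi = scale_range
    if not (0 < lo <= hi < 2):
        raise ValueError("range must satisfy 0 < lo <= hi < 2")
    if n_sets < 10:
        raise ValueError("n_sets must be at least 10")
    rng = np.random.default_rng(seed)
    links = nonzero_links(model)
    if n_clusters is None:
        n_clusters = len(find_stable_states(model, n_starts=max(n_starts, 100), seed=seed))

    rows, ids = [], []
    failed = 0
    for set_id in range(n_sets):
        factors = {l: rng.uniform(lo, hi) for l in links}
        pert = _scaled_model(model, factors)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                states = find_stable_states(
                    pert, n_starts=max(n_starts, 100), seed=seed + set_id + 1
                )
        except RuntimeError as exc:
            logger.warning("parameter set %d skipped: %s", set_id, exc)
            failed += 1
            continue
        for s in states:
            rows.append(s.x_star)
            ids.append(set_id)
    X = np.array(rows)
    labels = cluster_states(X, n_clusters)
    return PerturbationEnsemble(
        n_sets=n_sets,
        scale_range=(lo, hi),
        seed=seed,
        set_ids=np.array(ids),
        states=X,
        cluster_labels=labels,
        n_failed_sets=failed,
    )


@dataclass
class RobustPathsResult:
    ensemble: PerturbationEnsemble
    basis: ProjectionBasis
    projected_states: np.ndarray  # (n_states, 2)
    paths: list[TransitionPath]
    projected_paths: list[np.ndarray]  # each (K, 2)
    path_set_ids: list[int]


def robust_paths(
    model: NetworkModel,
    from_ref: np.ndarray,
    to_ref: np.ndarray,
    scale_range: tuple[float, float] = (0.95, 1.05),
    n_sets: int = 100,
    T: float = 40.0,
    K: int = 61,
    seed: int = 0,
    n_starts: int = 200,
) -> RobustPathsResult:
    """Minimum action paths under parameter perturbation, in pooled-PC view.

    For each sampled set the attractors nearest (relative L2) to the two
    reference points are taken as endpoints; per-set failures are logged,
    not fatal.  States and paths are projected onto the top two principal
    components of the pooled state matrix.
    """
    ens = perturb_and_collect(
        model, scale_range=scale_range, n_sets=n_sets, seed=seed, n_clusters=2,
        n_starts=n_starts
    )
    rng = np.random.default_rng(seed)
    links = nonzero_links(model)
    # replay the same factor stream to rebuild each perturbed model
    lo, hi = scale_range
    paths, path_ids = [], []
    for set_id in range(n_sets):
        factors = {l: rng.uniform(lo, hi) for l in links}
        pert = _scaled_model(model, factors)
        rows = ens.states[ens.set_ids == set_id]
        if rows.shape[0] < 2:
            logger.warning("set %d has fewer than two attractors; skipped", set_id)
            continue
        a = rows[np.argmin(np.linalg.norm(rows - from_ref, axis=1))]
        b = rows[np.argmin(np.linalg.norm(rows - to_ref, axis=1))]
        if np.allclose(a, b):
            logger.warning("set %d: endpoints merged; skipped", set_id)
            continue
        p = minimize_action(pert, a, b, T=T, K=K, seed=seed + set_id, n_restarts=1)
        paths.append(p)
        path_ids.append(set_id)
    centered = ens.states - ens.states.mean(axis=0)
    basis = compute_basis(centered.T @ centered / max(len(ens.states) - 1, 1))
    proj_states = project_points(ens.states - ens.states.mean(axis=0), basis, 2)
    mean = ens.states.mean(axis=0)
    proj_paths = [project_points(p.points - mean, basis, 2) for p in paths]
    return RobustPathsResult(
        ensemble=ens,
        basis=basis,
        projected_states=proj_states,
        paths=paths,
        projected_paths=proj_paths,
        path_set_ids=path_ids,
    )


@dataclass
class SensitivityRecord:
    link: str  # e.g. "A:HIF1->HIF1"
    direction: str  # "+10%" or "-10%"
    dS_forward_pct: float  # percent change of S(from -> to)
    dS_backward_pct: float  # percent change of S(to -> from)
    score: float  # dS_backward_pct - dS_forward_pct
    flagged: str = ""  # "phase change" when an endpoint is lost


def _match_endpoint(
    model: NetworkModel, ref: np.ndarray
) -> np.ndarray | None:
    """Newton-polish the reference attractor under perturbed parameters."""
    from scipy.optimize import root

    sol = root(model.force, ref, jac=model.jacobian, method="hybr")
    x = np.maximum(sol.x, 0.0)
    if not sol.success or np.max(np.abs(model.force(x))) > 1e-8:
        return None
    if np.max(np.linalg.eigvals(model.jacobian(x)).real) >= -1e-9:
        return None
    if np.linalg.norm(x - ref) > 0.5 * max(np.linalg.norm(ref), 1.0):
        return None  # converged to a different attractor: treat as lost
    return x


def global_sensitivity(
    model: NetworkModel,
    from_point: np.ndarray,
    to_point: np.ndarray,
    delta: float = 0.10,
    T: float = 40.0,
    K: int = 61,
    seed: int = 0,
    directions: tuple[str, ...] = ("+", "-"),
) -> list[SensitivityRecord]:
    """One-at-a-time +/-delta perturbation of every regulation strength.

    For each nonzero A/B entry the model is rebuilt with that one strength
    scaled by 1+delta (and 1-delta), the two endpoint attractors are
    re-located by polishing the defaults, and both transition actions are
    recomputed at fixed T and K.  Records where an endpoint disappears are
    flagged "phase change" and carry NaN changes.  Results are sorted by
    descending |score| within each direction.
    """
    if not (0 < delta < 0.5):
        raise ValueError("delta must lie in (0, 0.5)")
    base_fwd = minimize_action(model, from_point, to_point, T=T, K=K, seed=seed).action
    base_bwd = minimize_action(model, to_point, from_point, T=T, K=K, seed=seed).action
    records: list[SensitivityRecord] = []
    names = model.node_names
    for mat, j, i in nonzero_links(model):
        link = f"{mat}:{names[j]}->{names[i]}"
        for sgn in directions:
            factor = 1.0 + delta if sgn == "+" else 1.0 - delta
            pert = _scaled_model(model, {(mat, j, i): factor})
            a = _match_endpoint(pert, from_point)
            b = _match_endpoint(pert, to_point)
            tag = f"{sgn}{delta:.0%}"
            if a is None or b is None:
                records.append(
                    SensitivityRecord(link, tag, np.nan, np.nan, np.nan, "phase change")
                )
                continue
            s_fwd = minimize_action(pert, a, b, T=T, K=K, seed=seed).action
            s_bwd = minimize_action(pert, b, a, T=T, K=K, seed=seed).action
            d_fwd = 100.0 * (s_fwd - base_fwd) / base_fwd
            d_bwd = 100.0 * (s_bwd - base_bwd) / base_bwd
            records.append(SensitivityRecord(link, tag, d_fwd, d_bwd, d_bwd - d_fwd))
    records.sort(
        key=lambda r: (r.direction, -(abs(r.score) if np.isfinite(r.score) else -1.0))
    )
    return records
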