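"""Hill-kinetics gene regulatory network models.

A network of N components is specified by an activation-strength matrix A
and an inhibition-strength matrix B (entry ``[j, i]`` is the strength of
the regulation of component j on component i), a sigmoid threshold S, a
Hill coefficient n, a first-order degradation rate k and an optional basal
synthesis rate g0.  The deterministic drift of component i is

    f_i(x) = sum_j A[j,i] * x_j^n / (S[j,i]^n + x_j^n)
           + sum_j B[j,i] * S[j,i]^n / (S[j,i]^n + x_j^n)
           - k_i * x_i + g0_i

so an "inhibition" is a synthesis term that is large while the inhibitor
is low.  Stochastic dynamics add independent Gaussian white noise of
intensity 2*d per component (a Langevin equation with constant, homogeneous
diffusion coefficient d).

Component levels are concentrations: Hill terms are evaluated on
``max(x, 0)`` and the stochastic integrator clamps states at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "NetworkModel",
    "SimulationConfig",
    "CustomDrift",
    "load_network",
    "load_config",
    "force",
    "jacobian",
    "simulate_langevin",
    "simulate_deterministic",
]


@dataclass
class NetworkModel:
    """A Hill-kinetics regulatory network defining a deterministic drift.

    Parameters
    ----------
    node_names
        Identifiers of the N components.
    A, B
        N x N activation / inhibition strength matrices, ``A[j, i]`` acting
        from j onto i.  Entries are non-negative and a given ordered pair
        may carry at most one of the two signs.
    S
        Hill threshold, scalar or N x N matrix (``S[j, i]`` for the j->i
        regulation).
    n
        Hill coefficient (>= 1).
    k
        Degradation rate, scalar or length-N.
    g0
        Basal synthesis rate, scalar or length-N (default 0).
    """

    node_names: list[str]
    A: np.ndarray
    B: np.ndarray
    S: float | np.ndarray = 0.5
    n: float = 4
    k: float | np.ndarray = 1.0
    g0: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        N = len(self.node_names)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != (N, N) or self.B.shape != (N, N):
            raise ValueError(
                f"A and B must be {N}x{N} to match the {N} node names; "
                f"got {self.A.shape} and {self.B.shape}"
            )
        if np.any(self.A < 0) or np.any(self.B < 0):
            raise ValueError("regulation strengths must be non-negative")
        if np.any((self.A > 0) & (self.B > 0)):
            j, i = np.argwhere((self.A > 0) & (self.B > 0))[0]
            raise ValueError(
                f"link {self.node_names[j]}->{self.node_names[i]} is both "
                "an activation and an inhibition"
            )
        self.S = np.broadcast_to(np.asarray(self.S, dtype=float), (N, N)).copy()
        if np.any(self.S <= 0):
            raise ValueError("Hill thresholds must be positive")
        if self.n < 1:
            raise ValueError("Hill coefficient must be >= 1")
        self.k = np.broadcast_to(np.asarray(self.k, dtype=float), (N,)).copy()
        if np.any(self.k <= 0):
            raise ValueError("degradation rates must be positive")
        self.g0 = np.broadcast_to(np.asarray(self.g0, dtype=float), (N,)).copy()
        if np.any(self.g0 < 0):
            raise ValueError("basal synthesis rates must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def force(self, x: np.ndarray) -> np.ndarray:
        return force(self, x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return jacobian(self, x)

    def state_upper_bound(self, margin: float = 0.2) -> np.ndarray:
        """Per-node upper bound on any steady state.

        Every Hill term is at most 1, so x_i* <= (incoming strengths +
        g0_i) / k_i; a multiplicative margin gives a safe sampling box.
        """
        total_in = self.A.sum(axis=0) + self.B.sum(axis=0)
        return (1.0 + margin) * (total_in + self.g0) / self.k

    def relabelled(self, perm: Sequence[int]) -> "NetworkModel":
        """The same network with nodes re-ordered by ``perm``."""
        p = np.asarray(perm)
        return NetworkModel(
            node_names=[self.node_names[i] for i in p],
            A=self.A[np.ix_(p, p)],
            B=self.B[np.ix_(p, p)],
            S=self.S[np.ix_(p, p)],
            n=self.n,
            k=self.k[p],
            g0=self.g0[p],
        )


@dataclass
class CustomDrift:
    """An arbitrary drift field with an analytic Jacobian.

    Used for non-network dynamical systems (e.g. gradient systems serving
    as analytic references for path computations).  Exposes the same
    ``force``/``jacobian``/``n_nodes`` surface as :class:`NetworkModel`.
    """

    force_fn: Callable[[np.ndarray], np.ndarray]
    jacobian_fn: Callable[[np.ndarray], np.ndarray]
    n_nodes: int
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_names:
            self.node_names = [f"x{i+1}" for i in range(self.n_nodes)]

    def force(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.force_fn(np.asarray(x, dtype=float)), dtype=float)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self.jacobian_fn(np.asarray(x, dtype=float)), dtype=float)


@dataclass
class SimulationConfig:
    """Settings for stochastic (Langevin) simulation.

    d is the constant diffusion coefficient: each component receives
    independent Gaussian increments of variance 2*d*dt per step.
    """

    d: float
    dt: float = 0.01
    t_end: float = 100.0
    seed: int = 0
    n_trajectories: int = 1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("diffusion coefficient d must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_end <= self.dt:
            raise ValueError("t_end must exceed dt")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


def _hill_terms(model: NetworkModel, x: np.ndarray):
    """Activation and inhibition Hill factors for every (source, target) pair.

    Returns (act, inh) of shape (..., N, N) where ``act[..., j, i]`` is the
    activation factor of source j acting on target i.
    """
    xc = np.maximum(x, 0.0)
    n = model.n
    Sn = model.S**n  # (N, N)
    xn = xc[..., :, None] ** n  # source level broadcast over targets
    act = xn / (Sn + xn)
    inh = Sn / (Sn + xn)
    return act, inh


def force(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Deterministic drift f(x).  Supports batched states (..., N)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_nodes:
        raise ValueError(
            f"state has {x.shape[-1]} components, model has {model.n_nodes}"
        )
    act, inh = _hill_terms(model, x)
    synth = np.einsum("ji,...ji->...i", model.A, act) + np.einsum(
        "ji,...ji->...i", model.B, inh
    )
    return synth - model.k * x + model.g0


def jacobian(model: NetworkModel, x: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the drift at a single state x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_nodes,):
        raise ValueError("jacobian expects a single state vector")
    xc = np.maximum(x, 0.0)
    n = model.n
    Sn = model.S**n
    xn = xc[:, None] ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        xnm1 = np.where(xc[:, None] > 0, xc[:, None] ** (n - 1), 0.0)
    dact = n * Sn * xnm1 / (Sn + xn) ** 2  # d/dx_j of act[j, i]
    # J[i, j] = d f_i / d x_j: activation raises, inhibition lowers
    J = (model.A * dact - model.B * dact).T
    J[np.diag_indices_from(J)] -= model.k
    return J


def simulate_deterministic(
    model,
    x0: np.ndarray,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 200,
):
    """Integrate dx/dt = f(x) with an adaptive stiff-capable solver (LSODA).

    Returns (times, states) with ``states`` of shape (n_points, N).
    """
    from scipy.integrate import solve_ivp

    x0 = np.asarray(x0, dtype=float)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, x: model.force(x),
        (0.0, t_end),
        x0,
        method="LSODA",
        jac=lambda t, x: model.jacobian(x),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"deterministic integration failed: {sol.message}")
    return sol.t, sol.y.T


def simulate_langevin(
    model,
    sim: SimulationConfig,
    x0: np.ndarray,
    record_every: int = 1,
    clamp: bool = True,
) -> np.ndarray:
    """Euler-Maruyama trajectories of the Langevin dynamics.

    Per step each component receives an independent Gaussian increment of
    variance ``2 * d * dt``; states are clamped at zero (concentrations).

    Parameters
    ----------
    x0
        Initial state, shape (N,) or (n_trajectories, N).
    record_every
        Keep every ``record_every``-th step (the initial state is always
        recorded).

    Returns
    -------
    ndarray of shape (n_recorded, n_trajectories, N).
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    if x0.shape[0] == 1 and sim.n_trajectories > 1:
        x0 = np.repeat(x0, sim.n_trajectories, axis=0)
    if x0.shape[0] != sim.n_trajectories:
        raise ValueError("x0 rows must match n_trajectories")
    rng = np.random.default_rng(sim.seed)
    n_steps = int(round(sim.t_end / sim.dt))
    sigma = np.sqrt(2.0 * sim.d * sim.dt)
    x = x0.copy()
    out = [x.copy()]
    # divergence guard: drift steps should stay well below the state scale
    scale = max(1.0, float(np.max(np.abs(x0))))
    for step in range(1, n_steps + 1):
        f = model.force(x)
        x = x + f * sim.dt + sigma * rng.standard_normal(x.shape)
        if clamp:
            np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6 * scale:
            raise RuntimeError(
                f"Langevin simulation diverged at step {step} "
                f"(t={step * sim.dt:.3g}); dt={sim.dt} is likely too large"
            )
        if step % record_every == 0:
            out.append(x.copy())
    return np.array(out)


# ---------------------------------------------------------------------------
# edge-list I/O


_SIGNS = {"activate", "inhibit"}


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON parameter mapping (keys S, n, k, g0, d, a, b...)."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}


def load_network(
    path: str | Path,
    config: dict | str | Path | None = None,
    node_names: Sequence[str] | None = None,
) -> NetworkModel:
    """Build a :class:`NetworkModel` from a TSV edge list.

    The file needs columns ``source``, ``target``, ``sign`` (``activate`` or
    ``inhibit``) and ``strength``; a blank strength falls back to the config
    default ``a`` (activations) or ``b`` (inhibitions).  ``config`` supplies
    the kinetic parameters {S, n, k, g0} and the defaults {a, b}; it may be
    a mapping or the path of a YAML/JSON file.

    Node order is first-appearance order in the file unless ``node_names``
    pins it explicitly (which also allows isolated nodes).
    """
    if config is None:
        config = {}
    elif not isinstance(config, dict):
        config = load_config(config)
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    required = {"source", "target", "sign"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"edge list {path} must have columns source/target/sign; "
            f"found {list(df.columns)}"
        )
    if "strength" not in df.columns:
        df["strength"] = np.nan

    if node_names is None:
        seen: dict[str, None] = {}
        for name in pd.concat([df["source"], df["target"]]):
            seen.setdefault(name, None)
        node_names = list(seen)
    else:
        node_names = list(node_names)
        unknown = set(df["source"]) | set(df["target"]) - set(node_names)
        unknown -= set(node_names)
        if unknown:
            raise ValueError(f"edge list references unknown nodes: {sorted(unknown)}")
    index = {name: i for i, name in enumerate(node_names)}
    N = len(node_names)
    A = np.zeros((N, N))
    B = np.zeros((N, N))

    dup = df.duplicated(subset=["source", "target"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["source", "target"]].drop_duplicates().values.tolist()
        raise ValueError(f"duplicate edges for ordered pairs: {pairs}")

    for row in df.itertuples(index=False):
        sign = str(row.sign).strip().lower()
        if sign not in _SIGNS:
            raise ValueError(f"unknown sign {row.sign!r}; expected activate/inhibit")
        strength = row.strength
        if pd.isna(strength):
            key = "a" if sign == "activate" else "b"
            if key not in config:
                raise ValueError(
                    f"edge {row.source}->{row.target} has no strength and the "
                    f"config lacks a default {key!r}"
                )
            strength = config[key]
        strength = float(strength)
        if strength < 0:
            raise ValueError(f"negative strength on edge {row.source}->{row.target}")
        j, i = index[row.source], index[row.target]
        (A if sign == "activate" else B)[j, i] = strength

    return NetworkModel(
        node_names=node_names,
        A=A,
        B=B,
        S=config.get("S", 0.5),
        n=config.get("n", 4),
        k=config.get("k", 1.0),
        g0=config.get("g0", 0.0),
    )


def write_network(model: NetworkModel, path: str | Path) -> None:
    """Write the model's edge list as the canonical TSV format."""
    rows = []
    for j in range(model.n_nodes):
        for i in range(model.n_nodes):
            if model.A[j, i] > 0:
                rows.append(
                    (model.node_names[j], model.node_names[i], "activate", model.A[j, i])
                )
            if model.B[j, i] > 0:
                rows.append(
                    (model.node_names[j], model.node_names[i], "inhibit", model.B[j, i])
                )
    pd.DataFrame(rows, columns=["source", "target", "sign", "strength"]).to_csv(
        path, sep="\t", index=False
    )
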