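"""Benchmark comparisons between the mixture landscape and simulation.

The reference landscape is obtained by long Euler-Maruyama simulation of
the two-gene switch and binning the retained samples on the same grid as
the mixture landscape (probability-mass convention on both sides).  The
sweep over the cross-inhibition strength b yields, per b, the mean
relative deviation between the two landscapes and the per-basin barrier
heights of both, from which a barrier-series Pearson correlation is
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractors import find_stable_states
from .fixtures import MISA_D, fixture_misa
from .grn_model import SimulationConfig, simulate_langevin
from .landscape_metrics import (
    barrier_series_correlation,
    compare_landscapes,
    find_saddle,
    histogram_landscape,
    mixture_mass_grid,
)
from .tme import build_mixture

__all__ = ["SweepComparison", "misa_sweep_comparison"]

U_CAP = 50.0


@dataclass
class SweepComparison:
    b_values: tuple[float, ...]
    errors: list[float] = field(default_factory=list)  # per-b mean ratio
    bh_mixture: list[float] = field(default_factory=list)
    bh_simulation: list[float] = field(default_factory=list)

    @property
    def max_error(self) -> float:
        return max(self.errors)

    @property
    def barrier_correlation(self) -> float:
        return barrier_series_correlation(self.bh_mixture, self.bh_simulation)


def _basin_cells(U: np.ndarray, mus, edges) -> list[tuple[int, int]]:
    """Grid cell of the deepest U value near each component mean."""
    cells = []
    res = U.shape[0]
    for mu in mus:
        i = int(np.clip(np.searchsorted(edges[0], mu[0]) - 1, 0, res - 1))
        j = int(np.clip(np.searchsorted(edges[1], mu[1]) - 1, 0, res - 1))
        # refine to the local minimum within a small window
        w = 5
        sl = (slice(max(i - w, 0), min(i + w + 1, res)),
              slice(max(j - w, 0), min(j + w + 1, res)))
        local = np.unravel_index(np.argmin(U[sl]), U[sl].shape)
        cells.append((local[0] + sl[0].start, local[1] + sl[1].start))
    return cells


def misa_sweep_comparison(
    b_values=(0.4, 0.5, 0.6, 0.7),
    d: float = MISA_D,
    seed: int = 0,
    resolution: int = 80,
    n_walkers: int = 500,
    n_records: int = 8000,
    dt: float = 0.01,
    burn_time: float = 200.0,
    record_every: int = 5,
    n_starts: int = 600,
) -> SweepComparison:
    """Mixture-vs-simulation landscapes for the switch across a b sweep.

    Per b: build the two-component mixture at diffusion d, evaluate its
    mass landscape on a grid covering the attractors, run ``n_walkers``
    Langevin walkers long enough to retain ``n_walkers * n_records``
    samples (default 4e6), and compare.  Barrier heights for both
    landscapes come from the union-find minimax saddle between the two
    basin cells.
    """
    out = SweepComparison(b_values=tuple(b_values))
    for idx, b in enumerate(b_values):
        model = fixture_misa(b=b)
        states = find_stable_states(model, n_starts=n_starts, seed=seed + idx)
        if len(states) != 2:
            raise RuntimeError(f"switch not bistable at b={b}")
        mix = build_mixture(model, states, d)
        hi = max(s.x_star.max() for s in states) + 0.35
        edges = [np.linspace(0.0, hi, resolution + 1)] * 2
        U_mix = mixture_mass_grid(mix, edges, u_cap=U_CAP)

        record_time = n_records * record_every * dt
        sim = SimulationConfig(
            d=d,
            dt=dt,
            t_end=burn_time + record_time,
            seed=seed + 100 + idx,
            n_trajectories=n_walkers,
        )
        rng = np.random.default_rng(seed + 200 + idx)
        x0 = rng.uniform(0.0, hi, size=(n_walkers, 2))
        traj = simulate_langevin(model, sim, x0, record_every=record_every)
        n_burn_records = int(round(burn_time / (dt * record_every)))
        samples = traj[n_burn_records + 1 :].reshape(-1, 2)
        U_sim = histogram_landscape(samples, edges, u_cap=U_CAP)

        out.errors.append(compare_landscapes(U_mix, U_sim, u_cap=U_CAP).error)

        mus = [s.x_star for s in states]
        for U in (U_mix, U_sim):
            ca, cb = _basin_cells(U, mus, edges)
            sad = find_saddle(U, ca, cb, u_cap=U_CAP)
            bhs = [abs(sad.level - U[ca]), abs(sad.level - U[cb])]
            if U is U_mix:
                out.bh_mixture.extend(bhs)
            else:
                out.bh_simulation.extend(bhs)
    return out
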