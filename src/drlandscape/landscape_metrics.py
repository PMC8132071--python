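"""Quantifying gridded landscapes.

Saddles between basins are located by sorted-cell union-find flooding:
cells enter in order of increasing potential and the saddle level between
two minima is the lowest level at which their sublevel components merge
(the minimax level over all grid paths, with full 8-neighbor connectivity
in 2D and 2-neighbor in 1D).  Barrier height is BH = |U_saddle -
U_stable| per basin; the signed difference of two basin potentials is the
relative barrier height.

Reference landscapes come from long stochastic simulations: U = -ln of
the normalized histogram of retained samples.  Comparisons between two
landscapes on a shared grid use the mean relative deviation
mean(|U_a - U_b| / U_b) over cells valid (below the cap) in both, the
per-cell ratio summed and divided by the number of cells so the result
reads as a percentage; the raw (unnormalized) sum is also reported.
Comparisons require a shared normalization convention, so grids built for
comparison use probability mass per cell (density times cell volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drl import DEFAULT_U_CAP, ReducedLandscape

__all__ = [
    "BarrierReport",
    "LandscapeComparison",
    "find_saddle",
    "barrier_report",
    "histogram_landscape",
    "mixture_mass_grid",
    "compare_landscapes",
    "barrier_series_correlation",
]


@dataclass
class SaddleResult:
    cell: tuple[int, ...]
    level: float


@dataclass
class BarrierReport:
    """Per-basin barriers and signed basin-pair differences."""

    minima: list[tuple[int, ...]]
    u_minima: list[float]
    saddle: SaddleResult
    barrier_heights: list[float]  # BH = |U_saddle - U_stable| per basin

    def relative_barrier(self, a: int, b: int) -> float:
        """RBH between basins a and b: U_a - U_b (antisymmetric)."""
        return self.u_minima[a] - self.u_minima[b]


@dataclass
class LandscapeComparison:
    error: float  # mean of |U_a - U_b| / U_b over jointly valid cells
    error_sum: float  # the same sum without dividing by the cell count
    n_cells: int
    correlation: float | None = None


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.full(n, -1, dtype=np.int64)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj

    def active(self, i: int) -> bool:
        return self.parent[i] >= 0

    def activate(self, i: int) -> None:
        self.parent[i] = i


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    return [
        off
        for off in np.ndindex(*(3,) * ndim)
        if any(o != 1 for o in off)
    ]


def find_saddle(
    landscape: ReducedLandscape | np.ndarray,
    basin_a: tuple[int, ...],
    basin_b: tuple[int, ...],
    u_cap: float | None = None,
) -> SaddleResult:
    """Minimax saddle level between two basins of a gridded potential.

    Cells are flooded in order of increasing U; the first cell whose
    insertion connects the components containing the two basin minima is
    the saddle.  Raises if the basins only merge at or above the cap.
    """
    U = landscape.U if isinstance(landscape, ReducedLandscape) else np.asarray(landscape)
    if u_cap is None:
        u_cap = (
            landscape.u_cap if isinstance(landscape, ReducedLandscape) else DEFAULT_U_CAP
        )
    shape = U.shape
    basin_a, basin_b = tuple(basin_a), tuple(basin_b)
    ia = int(np.ravel_multi_index(basin_a, shape))
    ib = int(np.ravel_multi_index(basin_b, shape))
    if ia == ib:
        raise ValueError("the two basins coincide")
    flat = U.ravel()
    order = np.argsort(flat, kind="stable")
    uf = _UnionFind(flat.size)
    offsets = _neighbor_offsets(U.ndim)
    strides = np.array(
        [int(np.prod(shape[d + 1 :], dtype=int)) for d in range(U.ndim)]
    )
    for idx in order:
        level = flat[idx]
        if level >= u_cap:
            break
        uf.activate(int(idx))
        cell = np.unravel_index(idx, shape)
        for off in offsets:
            nb = tuple(c + o - 1 for c, o in zip(cell, off))
            if any(v < 0 or v >= s for v, s in zip(nb, shape)):
                continue
            j = int(np.dot(nb, strides))
            if uf.active(j):
                uf.union(int(idx), j)
        if uf.active(ia) and uf.active(ib) and uf.find(ia) == uf.find(ib):
            return SaddleResult(cell=tuple(int(c) for c in cell), level=float(level))
    raise ValueError("basins remain separated below the potential cap")


def barrier_report(
    landscape: ReducedLandscape,
    basin_a: tuple[int, ...] | None = None,
    basin_b: tuple[int, ...] | None = None,
) -> BarrierReport:
    """Barrier heights for a pair of basins (default: the two deepest minima)."""
    minima = landscape.minima
    if basin_a is None or basin_b is None:
        if len(minima) < 2:
            raise ValueError("landscape has fewer than two local minima")
        ranked = sorted(minima, key=lambda c: landscape.U[c])
        basin_a, basin_b = ranked[0], ranked[1]
    sad = find_saddle(landscape, basin_a, basin_b)
    u_min = [float(landscape.U[basin_a]), float(landscape.U[basin_b])]
    bh = [abs(sad.level - u) for u in u_min]
    return BarrierReport(
        minima=[basin_a, basin_b],
        u_minima=u_min,
        saddle=sad,
        barrier_heights=bh,
    )


def histogram_landscape(
    samples: np.ndarray,
    grid_edges: list[np.ndarray],
    u_cap: float = DEFAULT_U_CAP,
    min_samples: int = 100_000,
) -> np.ndarray:
    """U = -ln of the normalized sample histogram on the given grid.

    ``samples`` are retained states of shape (n, C); bins are defined by
    ``grid_edges`` (one edge vector per dimension).  Empty bins are capped
    at ``u_cap``.  The histogram is normalized to total probability mass
    one, so the result is directly comparable to :func:`mixture_mass_grid`.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < min_samples:
        raise ValueError(
            f"{samples.shape[0]} samples; at least {min_samples} required for "
            "a usable histogram landscape"
        )
    if samples.shape[1] != len(grid_edges):
        raise ValueError("sample dimension does not match the grid")
    H, _ = np.histogramdd(samples, bins=grid_edges)
    P = H / H.sum()
    floor = np.exp(-u_cap)
    return np.where(P > floor, -np.log(np.maximum(P, floor)), u_cap)


def mixture_mass_grid(
    mix,
    grid_edges: list[np.ndarray],
    u_cap: float = DEFAULT_U_CAP,
) -> np.ndarray:
    """Mixture landscape in the mass-per-cell convention of a histogram.

    Evaluates the mixture density at cell centers, multiplies by the cell
    volume and takes -ln, matching the normalization of
    :func:`histogram_landscape` on the same edges.
    """
    centers = [0.5 * (e[:-1] + e[1:]) for e in grid_edges]
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    vol = float(np.prod([e[1] - e[0] for e in grid_edges]))
    P = mix.pdf(pts).reshape(mesh[0].shape) * vol
    floor = np.exp(-u_cap)
    return np.where(P > floor, -np.log(np.maximum(P, floor)), u_cap)


def compare_landscapes(
    U_a: np.ndarray,
    U_b: np.ndarray,
    u_cap: float = DEFAULT_U_CAP,
) -> LandscapeComparison:
    """Mean relative deviation of U_a from reference U_b over jointly valid cells.

    Cells at or above the cap in either grid carry no density estimate and
    are excluded.  ``error`` is the mean per-cell ratio |dU|/U_b (a
    fraction; multiply by 100 for percent), ``error_sum`` the raw sum.
    """
    U_a, U_b = np.asarray(U_a), np.asarray(U_b)
    if U_a.shape != U_b.shape:
        raise ValueError(f"grid shapes differ: {U_a.shape} vs {U_b.shape}")
    valid = (U_a < u_cap) & (U_b < u_cap) & (np.abs(U_b) > 0)
    if not valid.any():
        raise ValueError("no jointly valid cells below the cap")
    ratios = np.abs(U_a[valid] - U_b[valid]) / np.abs(U_b[valid])
    return LandscapeComparison(
        error=float(ratios.mean()),
        error_sum=float(ratios.sum()),
        n_cells=int(valid.sum()),
    )


def barrier_series_correlation(
    series_a: np.ndarray, series_b: np.ndarray
) -> float:
    """Pearson correlation of two barrier-height series (e.g. across a sweep)."""
    from scipy.stats import pearsonr

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must share a length of at least 2")
    return float(pearsonr(a, b).statistic)
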