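"""Readers and writers for the tool's tabular output formats.

All outputs are plain text: TSV with headers for tables and paths,
delimited grids with a JSON sidecar for landscapes, JSON for mixtures
and manifests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attractors import StableState
from .drl import ProjectionBasis, ReducedLandscape
from .map_solver import TransitionPath

__all__ = [
    "write_states_tsv",
    "read_states_tsv",
    "write_landscape",
    "read_landscape",
    "write_path_tsv",
    "read_path_tsv",
]


def write_states_tsv(
    states: list[StableState], node_names: list[str], path: str | Path
) -> None:
    """One row per stable state: label, weight, then node values."""
    rows = [
        {"label": s.label, "weight": s.weight}
        | {name: s.x_star[i] for i, name in enumerate(node_names)}
        for s in states
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_states_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_landscape(land: ReducedLandscape, stem: str | Path) -> tuple[Path, Path]:
    """Write the U grid as delimited text plus a JSON sidecar.

    The grid file holds the flattened U values with one leading coordinate
    column per retained dimension; the sidecar records the basis W,
    eigenvalues, contribution rates, cap and shift mode.
    """
    stem = Path(stem)
    grid_file = stem.with_suffix(".grid.tsv")
    sidecar = stem.with_suffix(".meta.json")
    mesh = np.meshgrid(*land.grid_axes, indexing="ij")
    cols = {f"pc{i+1}": m.ravel() for i, m in enumerate(mesh)}
    cols["U"] = land.U.ravel()
    pd.DataFrame(cols).to_csv(grid_file, sep="\t", index=False, float_format="%.10g")
    meta = {
        "C": land.C,
        "shape": list(land.U.shape),
        "u_cap": land.u_cap,
        "shifted": land.shifted,
        "minima": [list(m) for m in land.minima],
        "W": land.basis.W.tolist(),
        "lambdas": land.basis.lambdas.tolist(),
        "contribution_rates_pct": land.basis.contribution_rates.tolist(),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return grid_file, sidecar


def read_landscape(stem: str | Path) -> ReducedLandscape:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".meta.json").read_text())
    df = pd.read_csv(stem.with_suffix(".grid.tsv"), sep="\t")
    shape = tuple(meta["shape"])
    U = df["U"].to_numpy().reshape(shape)
    axes = []
    for i in range(meta["C"]):
        col = df[f"pc{i+1}"].to_numpy().reshape(shape)
        sl = tuple(0 if d != i else slice(None) for d in range(len(shape)))
        axes.append(col[sl])
    basis = ProjectionBasis(
        W=np.array(meta["W"]), lambdas=np.array(meta["lambdas"])
    )
    return ReducedLandscape(
        basis=basis,
        C=meta["C"],
        grid_axes=axes,
        U=U,
        P=np.exp(-np.where(U >= meta["u_cap"], np.inf, U)),
        minima=[tuple(m) for m in meta["minima"]],
        u_cap=meta["u_cap"],
        shifted=meta["shifted"],
    )


def write_path_tsv(path_obj: TransitionPath, node_names: list[str], path: str | Path) -> None:
    df = pd.DataFrame(path_obj.points, columns=node_names)
    df.insert(0, "time", path_obj.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_path_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
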