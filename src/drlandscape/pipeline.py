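"""End-to-end pipeline: attractors -> mixture -> reduced landscape (-> paths).

Every run writes a manifest (config echo, seeds, package version) next to
its outputs so any table can be reproduced exactly from the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .attractors import find_stable_states
from .drl import compute_basis, grid_landscape, project_density
from .grn_model import load_config, load_network
from .io import write_landscape, write_path_tsv, write_states_tsv
from .map_solver import minimize_action
from .tme import build_mixture

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    network: str
    config: str | dict | None = None
    d: float = 0.01
    seed: int = 0
    n_starts: int = 1000
    pcs: int = 2
    resolution: int = 200
    u_cap: float = 50.0
    compute_maps: bool = False
    map_T: float = 40.0
    map_K: int = 101
    out_dir: str = "drl_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = load_config(path)
        return cls(**payload)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run fixpoints -> mixture -> reduction -> landscape (-> paths).

    Returns a summary dict (also written as ``manifest.json``); stage
    failures raise with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "d": cfg.d,
        "network": str(cfg.network),
        "config": cfg.config if isinstance(cfg.config, (dict, type(None))) else str(cfg.config),
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrap

    model = stage("load")(lambda: load_network(cfg.network, cfg.config))
    states = stage("fixpoints")(
        lambda: find_stable_states(model, n_starts=cfg.n_starts, seed=cfg.seed)
    )
    write_states_tsv(states, model.node_names, out / "states.tsv")
    manifest["n_stable_states"] = len(states)
    manifest["weights"] = [s.weight for s in states]

    mix = stage("tme")(lambda: build_mixture(model, states, cfg.d))
    mix.to_json(out / "mixture.json")
    manifest["spread_diagnostic"] = mix.spread_diagnostic()

    basis = stage("basis")(lambda: compute_basis(mix))
    C = min(cfg.pcs, model.n_nodes, 3)
    manifest["contribution_rates_pct"] = basis.contribution_rates[: max(C, 2)].tolist()

    land = stage("landscape")(
        lambda: grid_landscape(
            project_density(mix, basis, C),
            resolution=cfg.resolution,
            u_cap=cfg.u_cap,
            basis=basis,
        )
    )
    write_landscape(land, out / "landscape")
    manifest["n_landscape_minima"] = len(land.minima)

    if cfg.compute_maps and len(states) >= 2:
        def maps():
            pairs = []
            for i, si in enumerate(states):
                for j, sj in enumerate(states):
                    if i == j:
                        continue
                    p = minimize_action(
                        model,
                        si.x_star,
                        sj.x_star,
                        T=cfg.map_T,
                        K=cfg.map_K,
                        seed=cfg.seed,
                        labels=(si.label, sj.label),
                    )
                    write_path_tsv(
                        p, model.node_names, out / f"map_{si.label}_to_{sj.label}.tsv"
                    )
                    pairs.append(
                        {
                            "from": si.label,
                            "to": sj.label,
                            "action": p.action,
                            "converged": p.converged,
                        }
                    )
            return pairs

        manifest["maps"] = stage("maps")(maps)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
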