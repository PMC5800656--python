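"""Reproducible experiment orchestration.

Each experiment kind mirrors one figure-class analysis: endemic-region
sweeps, pairwise invasibility plots, ESS scans over clustering, lattice
generation, and Monte-Carlo persistence / evolution runs.  A run takes
an :class:`ExperimentConfig`, writes its tabular outputs (CSV for
matrices and time series, JSON for scalar summaries) plus a manifest
recording the full configuration, package version and seed, and returns
the paths.  Reruns with an identical config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import EpidemicParams, Strain, basic_reproduction_number, is_endemic
from .invasion import StrainGrid, build_pip, find_local_ess, r0_maximizing_G
from .simulate import MCConfig, run_evolution, run_persistence, summarize_trajectory
from .structures import (
    SpatialMoments,
    generate_csr,
    generate_deterministic,
    generate_structure_mh,
    measure_moments,
    write_structure,
)

__all__ = ["ExperimentConfig", "run_experiment"]

_KINDS = (
    "generate_structure",
    "endemic_region",
    "pip",
    "ess_scan",
    "mc_persistence",
    "mc_evolution",
)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    Unused fields for a given ``kind`` are ignored but recorded in the
    manifest, so a config document fully determines its outputs.
    """

    kind: str
    seed: int = 0
    # epidemic parameters
    beta_G: float = 10.0
    beta_L: float = 10.0
    alpha: float = 1.0
    tradeoff_exponent: float = 1.0
    # spatial structure (abstract moments and/or concrete lattice)
    x_C: float = 0.5
    p_CC: float = 0.25
    dims: tuple[int, int] = (100, 100)
    pattern: str | None = None  # e.g. "stripes:1"; None -> swap generator
    # strain grid
    n_strains: int = 101
    # sweep specifications
    alpha_values: list[float] = field(default_factory=list)
    G_values: list[float] = field(default_factory=list)
    clustering_values: list[float] = field(default_factory=list)
    # Monte-Carlo settings
    strain_G: float = 1.0
    t_end: float = 500.0
    reps: int = 20
    mutation_rate: float = 0.01
    initial_G: float = 0.5
    dt: float | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; one of {_KINDS}")

    def params(self) -> EpidemicParams:
        return EpidemicParams(self.beta_G, self.beta_L, self.alpha)

    def moments(self) -> SpatialMoments:
        return SpatialMoments(self.x_C, self.p_CC)

    def grid(self) -> StrainGrid:
        return StrainGrid(self.n_strains, tradeoff_exponent=self.tradeoff_exponent)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _structure_from_config(config: ExperimentConfig, seed):
    if config.pattern is not None:
        return generate_deterministic(config.pattern, config.dims)
    if abs(config.p_CC - config.x_C**2) < 1e-12:
        return generate_csr(config.x_C, config.dims, seed)
    return generate_structure_mh(config.x_C, config.p_CC, config.dims, seed)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute one experiment and write its artifacts under ``out_dir``.

    Returns a mapping from artifact name to path; a ``manifest.json``
    with the config, package version and seed is always written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: dict = {}

    if config.kind == "generate_structure":
        structure = _structure_from_config(config, config.seed)
        path = out / "structure.txt"
        write_structure(structure, path)
        artifacts["structure"] = path
        mom = measure_moments(structure)
        summary = {
            "x_C": mom.x_C,
            "p_CC": mom.p_CC,
            "clustering": mom.clustering,
        }

    elif config.kind == "endemic_region":
        params0 = config.params()
        moments = config.moments()
        alphas = config.alpha_values or [config.alpha]
        Gs = config.G_values or list(np.linspace(0, 1, config.n_strains))
        rows = []
        for a in alphas:
            params = EpidemicParams(config.beta_G, config.beta_L, a)
            for G in Gs:
                strain = Strain(G, config.tradeoff_exponent)
                endemic, margin = is_endemic(strain, params, moments)
                rows.append(
                    {
                        "alpha": a,
                        "G": G,
                        "endemic": endemic,
                        "margin": margin,
                        "R0": basic_reproduction_number(strain, params, moments),
                    }
                )
        df = pd.DataFrame(rows)
        path = out / "endemic_region.csv"
        _atomic_write(path, df.to_csv(index=False))
        artifacts["endemic_region"] = path
        summary = {"n_endemic": int(df["endemic"].sum()), "n_total": len(df)}

    elif config.kind == "pip":
        pip = build_pip(config.grid(), config.params(), config.moments())
        df = pd.DataFrame(
            pip.invade, index=pip.grid.values, columns=pip.grid.values
        )
        path = out / "pip.csv"
        _atomic_write(path, df.to_csv(index_label="resident_G"))
        artifacts["pip"] = path
        summary = {
            "singular": [dataclasses.asdict(s) for s in pip.singular],
            "ess_values": pip.ess_values,
        }

    elif config.kind == "ess_scan":
        rows = []
        for c in config.clustering_values or [1.0]:
            moments = SpatialMoments.from_clustering(config.x_C, c)
            ess = find_local_ess(config.grid(), config.params(), moments)
            r0max = r0_maximizing_G(config.params(), moments, config.grid())
            rows.append(
                {
                    "x_C": config.x_C,
                    "p_CC": moments.p_CC,
                    "clustering": c,
                    "ess_G": ess[0].G if ess else float("nan"),
                    "n_ess": len(ess),
                    "r0_max_G": r0max.G,
                }
            )
        df = pd.DataFrame(rows)
        path = out / "ess_scan.csv"
        _atomic_write(path, df.to_csv(index=False))
        artifacts["ess_scan"] = path
        summary = {"n_points": len(df)}

    elif config.kind == "mc_persistence":
        structure = _structure_from_config(config, config.seed)
        mc = MCConfig(dt=config.dt, seed=config.seed)
        res = run_persistence(
            structure,
            config.strain_G,
            config.params(),
            t_end=config.t_end,
            reps=config.reps,
            config=mc,
            tradeoff_exponent=config.tradeoff_exponent,
        )
        summary = {
            "survival_fraction": res.survival_fraction,
            "extinction_times": res.extinction_times,
        }

    elif config.kind == "mc_evolution":
        structure = _structure_from_config(config, config.seed)
        mc = MCConfig(dt=config.dt, mutation_rate=config.mutation_rate, seed=config.seed)
        traj = run_evolution(
            structure,
            config.grid(),
            config.params(),
            t_end=config.t_end,
            config=mc,
            initial_G=config.initial_G,
        )
        df = pd.DataFrame(
            {
                "t": traj.times,
                "mean_G": traj.mean_G,
                "infected_density": traj.infected_density,
            }
        )
        path = out / "mc_evolution.csv"
        _atomic_write(path, df.to_csv(index=False))
        artifacts["trajectory"] = path
        mean, sd = summarize_trajectory(traj)
        summary = {
            "mean_G_longrun": mean,
            "sd_G_longrun": sd,
            "extinction_time": traj.extinction_time,
        }

    summary_path = out / "summary.json"
    _atomic_write(summary_path, json.dumps(summary, indent=2, default=float))
    artifacts["summary"] = summary_path

    manifest = {
        "package": "pairsis",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    _atomic_write(manifest_path, json.dumps(manifest, indent=2, default=float))
    artifacts["manifest"] = manifest_path
    return artifacts
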