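"""Serialization: YAML configs, TSV tables with metadata, JSON results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .meanfield_linear import MeanFieldSolution
from .model import FitnessSpec, ModelParams
from .simulate import SimulationConfig, TrajectoryRecord

__all__ = [
    "params_to_dict", "params_from_dict",
    "config_to_dict", "config_from_dict",
    "load_yaml_config", "dump_yaml_config",
    "solution_to_dict", "write_json", "write_tsv",
    "write_trajectory",
]


def params_to_dict(p: ModelParams) -> dict:
    return {
        "Ne": p.Ne, "u": p.u, "v": p.v, "g": p.g,
        "fitness": {"kind": p.fitness.kind, "parameter": p.fitness.parameter},
        "a": p.a,
    }


def params_from_dict(d: dict) -> ModelParams:
    fit = d.get("fitness", {})
    spec = FitnessSpec(kind=fit.get("kind", "power"),
                       parameter=float(fit.get("parameter", 1e-2)))
    return ModelParams(Ne=int(d["Ne"]), u=float(d["u"]), v=float(d["v"]),
                       g=float(d["g"]), fitness=spec,
                       a=None if d.get("a") is None else float(d["a"]))


def config_to_dict(c: SimulationConfig) -> dict:
    return {
        "params": params_to_dict(c.params), "seed": c.seed,
        "record_stride": c.record_stride,
        "max_generations": c.max_generations,
        "burnin_multiplier": c.burnin_multiplier,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    return SimulationConfig(
        params=params_from_dict(d["params"]),
        seed=int(d.get("seed", 0)),
        record_stride=int(d.get("record_stride", 1)),
        max_generations=int(d.get("max_generations", 5_000_000)),
        burnin_multiplier=float(d.get("burnin_multiplier", 50.0)),
    )


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml_config(d: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def solution_to_dict(sol: MeanFieldSolution) -> dict:
    d = dataclasses.asdict(sol)
    d["diagnostics"] = {k: (v if isinstance(v, (int, float, str, bool)) else repr(v))
                        for k, v in d["diagnostics"].items()}
    return d


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata lines before the header."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_trajectory(traj: TrajectoryRecord, outdir) -> dict:
    """Write trajectory.tsv, summaries.tsv and config.json; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"burnin": traj.burnin, "n_samples": traj.n_samples,
            "seed": traj.config.seed}
    paths = {
        "trajectory": outdir / "trajectory.tsv",
        "summaries": outdir / "summaries.tsv",
        "config": outdir / "config.json",
    }
    write_tsv(traj.allele_table(), paths["trajectory"], meta)
    write_tsv(traj.summaries, paths["summaries"], meta)
    write_json(config_to_dict(traj.config), paths["config"])
    return paths
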