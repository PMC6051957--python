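"""Experiment configuration and result serialization.

Configs are YAML; unknown keys are rejected so typos fail before any
simulation starts.  Results are written as CSV (grids, ensembles) and
JSON (summaries) with the config hash and seeds embedded, so every
output is reproducible from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import NetworkParams, default_params, load_params, params_to_dict

_TOP_KEYS = {"params_file", "experiment", "weights", "protocol", "grid",
             "noise", "perturbation", "seed", "duration", "solver", "outdir"}
_WEIGHT_KEYS = {"w_ampa", "w_nmda", "w_inh"}
_PROTOCOL_KEYS = {"A", "d", "t1", "delta"}
_GRID_KEYS = {"axis1", "range1", "axis2", "range2", "n1", "n2", "duration"}
_NOISE_KEYS = {"phi", "dt"}
_PERT_KEYS = {"t_star", "sigma"}
_SOLVER_KEYS = {"rtol", "atol", "method"}


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    experiment: str = "simulate"
    params_file: str | None = None
    weights: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    perturbation: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    duration: float = 3000.0
    outdir: str = "results"

    # ------------------------------------------------------------------
    def network_params(self) -> NetworkParams:
        p = load_params(self.params_file) if self.params_file else default_params()
        if self.weights:
            p = p.with_weights(**self.weights)
        return p

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment, "params_file": self.params_file,
            "weights": self.weights, "protocol": self.protocol,
            "grid": self.grid, "noise": self.noise,
            "perturbation": self.perturbation, "solver": self.solver,
            "seed": self.seed, "duration": self.duration,
            "outdir": self.outdir,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_keys(name: str, given: dict, allowed: set) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {name}: {sorted(unknown)}")


def config_from_dict(tree: dict) -> ExperimentConfig:
    if not isinstance(tree, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("config", tree, _TOP_KEYS)
    for section, allowed in (("weights", _WEIGHT_KEYS),
                             ("protocol", _PROTOCOL_KEYS),
                             ("grid", _GRID_KEYS), ("noise", _NOISE_KEYS),
                             ("perturbation", _PERT_KEYS),
                             ("solver", _SOLVER_KEYS)):
        if section in tree and tree[section] is not None:
            _check_keys(section, tree[section], allowed)
    cfg = ExperimentConfig(
        experiment=tree.get("experiment", "simulate"),
        params_file=tree.get("params_file"),
        weights=dict(tree.get("weights") or {}),
        protocol=dict(tree.get("protocol") or {}),
        grid=dict(tree.get("grid") or {}),
        noise=dict(tree.get("noise") or {}),
        perturbation=dict(tree.get("perturbation") or {}),
        solver=dict(tree.get("solver") or {}),
        seed=int(tree.get("seed", 0)),
        duration=float(tree.get("duration", 3000.0)),
        outdir=str(tree.get("outdir", "results")),
    )
    for w, v in cfg.weights.items():
        if v < 0:
            raise ConfigError(f"{w} must be >= 0")
    if cfg.protocol:
        if cfg.protocol.get("d", 0.0) < 0 or cfg.protocol.get("A", 0.0) < 0:
            raise ConfigError("protocol A and d must be >= 0")
    if cfg.noise:
        if cfg.noise.get("dt", 0.01) <= 0:
            raise ConfigError("noise dt must be > 0")
        if cfg.noise.get("phi", 0.0) < 0:
            raise ConfigError("noise phi must be >= 0")
    if cfg.params_file and not Path(cfg.params_file).exists():
        raise ConfigError(f"params_file does not exist: {cfg.params_file}")
    # validate the parameter tree itself (negative taus etc.)
    cfg.network_params().validate()
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load and fully validate an experiment config; rejects unknown keys."""
    with open(path) as fh:
        tree = yaml.safe_load(fh)
    return config_from_dict(tree or {})


# ----------------------------------------------------------------------
# results


def write_results(results: dict, outdir, cfg: ExperimentConfig | None = None,
                  params: NetworkParams | None = None) -> list:
    """Write a result bundle deterministically.

    DataFrames become CSV, mappings/lists become JSON; a ``meta.json``
    records the config (with hash), seed, and parameter echo.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = outdir / f"{name}.csv"
            obj.to_csv(path, index=False)
        else:
            path = outdir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        written.append(path)
    meta = {}
    if cfg is not None:
        meta["config"] = cfg.to_dict()
        meta["config_hash"] = cfg.digest()
        meta["seed"] = cfg.seed
    if params is not None:
        meta["network_params"] = params_to_dict(params)
    path = outdir / "meta.json"
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=float)
    written.append(path)
    return written
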