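"""YAML-configured experiment pipeline with a reproducibility manifest.

A run is a YAML file with a master ``seed``, an ``out_dir``, and an ordered
list of ``stages`` (generate, load, balance, build, attack, tune).  Stages
communicate through an in-memory cohort (group label -> dataset); every
artifact is written as CSV/JSON under ``out_dir`` and the manifest records
the config snapshot, the per-stage derived seeds (children of the master
seed keyed by stage position) and a SHA-256 checksum of every output file,
so a rerun with the same config is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import __version__
from ._seeds import child_seed
from .balance import adasyn_oversample, undersample_groups
from .construction import conventional_mbn, ms_network
from .datasets import SUVRDataset, read_suvr_table, write_network, write_suvr_table
from .stability import AttackConfig, run_attack_experiment
from .synthetic import CohortSpec, generate_cohort
from .tuning import tune_n

__all__ = ["ConfigError", "PipelineError", "RunManifest", "run_pipeline"]

log = logging.getLogger("mbnet")

KNOWN_STAGES = ("generate", "load", "balance", "build", "attack", "tune")


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


class PipelineError(RuntimeError):
    """A stage failed after the pipeline started."""


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    master_seed: int
    version: str
    stage_seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "master_seed": self.master_seed,
                "package_version": self.version,
                "stage_seeds": self.stage_seeds,
                "outputs": self.outputs,
                "failure": self.failure,
            },
            indent=2,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(params: dict, stage: str, *keys: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise ConfigError(f"stage {stage!r} missing required params: {missing}")


def _validate(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config root must be a mapping")
    for key in ("seed", "out_dir", "stages"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")
    if not isinstance(config["stages"], list) or not config["stages"]:
        raise ConfigError("stages must be a non-empty list")
    for i, stage in enumerate(config["stages"]):
        if not isinstance(stage, dict) or "stage" not in stage:
            raise ConfigError(f"stages[{i}] must be a mapping with a 'stage' key")
        name = stage["stage"]
        if name not in KNOWN_STAGES:
            raise ConfigError(
                f"stages[{i}]: unknown stage {name!r}; choose from {KNOWN_STAGES}"
            )
        params = stage.get("params", {})
        if not isinstance(params, dict):
            raise ConfigError(f"stages[{i}].params must be a mapping")
        if name == "load":
            _require(params, name, "files")
        if name == "build":
            _require(params, name, "group")
        if name == "attack":
            _require(params, name, "target", "donors")


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute the stages of a YAML run config in order; returns (and
    writes) the manifest.  Schema violations raise :class:`ConfigError`
    before any stage executes; a stage failure writes a partial manifest
    with a failure record and raises :class:`PipelineError`."""
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    _validate(config)
    seed = int(config["seed"])
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, master_seed=seed, version=__version__)
    manifest_path = out_dir / "manifest.json"
    cohort: dict[str, SUVRDataset] = {}

    def record(path: Path) -> None:
        manifest.outputs[str(path)] = _sha256(path)

    try:
        for i, stage in enumerate(config["stages"]):
            name = stage["stage"]
            params = dict(stage.get("params", {}))
            stage_seed = child_seed(seed, "stage", i)
            manifest.stage_seeds[f"{i}:{name}"] = stage_seed
            t0 = time.time()
            if name == "generate":
                spec_params = dict(params)
                spec_params.setdefault("seed", stage_seed)
                if "block_sizes" in spec_params:
                    spec_params["block_sizes"] = tuple(spec_params["block_sizes"])
                spec = CohortSpec(**spec_params)
                cohort = generate_cohort(spec)
                for g, ds in cohort.items():
                    path = out_dir / f"cohort_{g}.csv"
                    write_suvr_table(ds, path)
                    record(path)
            elif name == "load":
                covs = params.get("covariate_columns", [])
                for g, path in params["files"].items():
                    cohort[g] = read_suvr_table(path, group=g, covariate_columns=covs)
            elif name == "balance":
                strategy = params.get("strategy", "undersample")
                rng = np.random.default_rng(stage_seed)
                if strategy == "undersample":
                    cohort = undersample_groups(cohort, rng)
                elif strategy == "adasyn":
                    cohort = adasyn_oversample(
                        cohort, k_neighbors=int(params.get("k_neighbors", 5)), rng=rng
                    )
                else:
                    raise PipelineError(f"unknown balance strategy {strategy!r}")
                for g, ds in cohort.items():
                    path = out_dir / f"balanced_{g}.csv"
                    write_suvr_table(ds, path)
                    record(path)
            elif name == "build":
                group = params["group"]
                if group not in cohort:
                    raise PipelineError(f"group {group!r} not in cohort")
                alpha = float(params.get("alpha", 0.0001))
                method = params.get("method", "ms_bootstrap")
                if method == "conventional":
                    net = conventional_mbn(cohort[group], alpha)
                    meta = {"method": method, "alpha": alpha, "seed": stage_seed}
                else:
                    result = ms_network(
                        cohort[group],
                        n=int(params.get("n", 500)),
                        alpha=alpha,
                        criterion=params.get("criterion", "mean"),
                        mode="subsample" if method == "ms_subsample" else "bootstrap",
                        fraction=float(params.get("fraction", 0.8)),
                        seed=stage_seed,
                        apply_pmap=bool(params.get("apply_pmap", True)),
                    )
                    net = result.network
                    meta = {
                        "method": method,
                        "alpha": alpha,
                        "theta": 1 - alpha,
                        "criterion": result.criterion,
                        "n": len(result.ensemble),
                        "representative_index": result.representative_index,
                        "seed": stage_seed,
                    }
                path = out_dir / f"network_{group}.csv"
                write_network(net, path, metadata=meta)
                record(path)
                for suffix in (".pvalues.csv", ".meta.json"):
                    record(out_dir / f"network_{group}{suffix}")
            elif name == "attack":
                cfg = AttackConfig(
                    p_o=float(params.get("po", 2.0)),
                    q_attacks=int(params.get("q", 256)),
                    method=params.get("method", "ms_bootstrap"),
                    ns=params.get("ns"),
                    seed=stage_seed,
                )
                report = run_attack_experiment(
                    cohort,
                    target=params["target"],
                    donors=list(params["donors"]),
                    config=cfg,
                    alpha=float(params.get("alpha", 0.01)),
                    n_samples=int(params.get("n", 500)),
                    criterion=params.get("criterion", "mean"),
                    apply_pmap=bool(params.get("apply_pmap", True)),
                )
                path = out_dir / f"attack_{params['target']}_{cfg.method}.csv"
                report.to_csv(path)
                record(path)
            elif name == "tune":
                group = params.get("group")
                if group not in cohort:
                    raise PipelineError(f"group {group!r} not in cohort")
                grid = params.get("grid")
                if isinstance(grid, str):
                    start, stop, gstep = (int(x) for x in grid.split(":"))
                    grid = list(range(start, stop + 1, gstep))
                result = tune_n(
                    cohort[group],
                    k_grid=grid,
                    alpha=float(params.get("alpha", 0.0001)),
                    criterion=params.get("criterion", "mean"),
                    seed=stage_seed,
                    step=int(params.get("step", 100)),
                )
                path = out_dir / f"tune_{group}.csv"
                result.trace.to_csv(path, index=False)
                record(path)
                (out_dir / f"tune_{group}_selected.json").write_text(
                    json.dumps({"selected_n": result.selected_n})
                )
                record(out_dir / f"tune_{group}_selected.json")
            log.info(
                "stage %d %s done in %.2fs (seed %d)",
                i,
                name,
                time.time() - t0,
                stage_seed,
            )
    except (ConfigError,):
        raise
    except Exception as exc:
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest_path.write_text(manifest.to_json())
        raise PipelineError(str(exc)) from exc
    manifest_path.write_text(manifest.to_json())
    return manifest
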