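"""Run configuration, serialization and output writing.

Every run directory receives the resolved configuration (YAML) next to its
TSV/JSON outputs, so a run is reconstructible -- bit for bit, given the same
package version -- from the emitted config copy alone.  Tables are TSV to
avoid locale and quoting ambiguity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .experiments import EquilibriumResult, SubstitutionResult, SweepExperimentResult
from .model import ConfigurationError, SeedBankParams
from .theory import RegimeReport

__all__ = ["RunConfig", "parse_config", "write_outputs", "EXPERIMENTS"]

EXPERIMENTS = ("sweep", "equilibrium", "substitution", "theory")

_PARAM_FIELDS = {f.name for f in dataclasses.fields(SeedBankParams)}


@dataclass
class RunConfig:
    """Fully serializable description of one run."""

    experiment: str
    params: SeedBankParams
    reps: int = 1
    horizon: int = 10_000
    base_seed: int = 0
    output_dir: Optional[str] = None
    record_every: Optional[int] = None
    tolerance: float = 0.10
    window: Optional[int] = None
    sample_size: int = 30
    residences: Optional[List[float]] = None
    vary: str = "bank_size"
    min_fixations: Optional[int] = None
    max_attempts: Optional[int] = None
    generations_per_day: Optional[float] = None
    export_fasta: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}")
        if self.reps < 0:
            raise ConfigurationError("reps must be non-negative")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be a positive integer")
        if self.experiment == "sweep" and self.params.s == 0:
            raise ConfigurationError(
                "sweep requires s > 0 (violated invariant: beneficial allele needs "
                "a fitness advantage; use equilibrium/substitution for neutral runs)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        raw_params = dict(d.pop("params", {}))
        unknown = set(raw_params) - _PARAM_FIELDS
        if unknown:
            raise ConfigurationError(f"unknown model parameters: {sorted(unknown)}")
        params = SeedBankParams(**raw_params)
        known = {f.name for f in dataclasses.fields(cls)} - {"params"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(params=params, **d)


def parse_config(source: Union[str, Path, dict, None] = None,
                 overrides: Optional[dict] = None) -> RunConfig:
    """Build a validated RunConfig from a YAML/JSON file and/or override values.

    ``overrides`` (e.g. CLI flags) take precedence over file values; model
    parameters live under the ``params`` key in both.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, dict):
            data = {k: (dict(v) if isinstance(v, dict) else v) for k, v in source.items()}
        else:
            path = Path(source)
            if not path.exists():
                raise ConfigurationError(f"config file not found: {path}")
            text = path.read_text()
            data = (json.loads(text) if path.suffix.lower() == ".json"
                    else yaml.safe_load(text)) or {}
    if overrides:
        params_over = overrides.pop("params", None) or {}
        params_over = {k: v for k, v in params_over.items() if v is not None}
        data.setdefault("params", {})
        data["params"].update(params_over)
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)


def _ensure_outdir(config: RunConfig) -> Path:
    if config.output_dir is None:
        raise ConfigurationError("an output directory is required to write outputs")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")  # fail fast before any simulation output is produced
    probe.unlink()
    return out


def check_writable(config: RunConfig) -> Path:
    """Validate the output path before a simulation starts (fail fast)."""
    return _ensure_outdir(config)


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("seedbank")
    except Exception:  # pragma: no cover
        return "unknown"


def _summary_header(config: RunConfig) -> dict:
    return {
        "experiment": config.experiment,
        "params": dataclasses.asdict(config.params),
        "base_seed": config.base_seed,
        "software_version": _version(),
    }


def write_outputs(result, config: RunConfig) -> Path:
    """Write an experiment's tables, JSON summary and resolved config."""
    out = _ensure_outdir(config)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    summary = _summary_header(config)

    if isinstance(result, SweepExperimentResult):
        rows = []
        for r in result.results:
            if r.trajectory is not None:
                for gen, fa, fd in r.trajectory:
                    rows.append((r.replicate_id, int(gen), fa, fd))
        pd.DataFrame(rows, columns=["replicate", "generation", "active_freq", "dormant_freq"]
                     ).to_csv(out / "trajectory.tsv", sep="\t", index=False)
        summary.update({
            "n_attempts": result.n_attempts,
            "n_fixed": result.n_fixed,
            "n_lost": result.n_lost,
            "mean_t_fix_total": result.mean_t_fix_total,
            "mean_t_quasi_fix_active": result.mean_t_quasi_fix_active,
            "replicates": [
                {"replicate": r.replicate_id, "fixed": r.fixed,
                 "t_quasi_fix_active": r.t_quasi_fix_active,
                 "t_fix_total": r.t_fix_total} for r in result.results],
        })
        if result.n_attempts == 0:
            summary["note"] = "zero replicates requested; headers-only trajectory table"
    elif isinstance(result, EquilibriumResult):
        pd.DataFrame(result.pi_series, columns=["generation", "mean_pi"]
                     ).to_csv(out / "pi_series.tsv", sep="\t", index=False)
        summary.update({
            "t_equilibrium": result.t_equilibrium,
            "target_pi": result.target_pi,
            "tolerance": result.tolerance,
            "window": result.window,
            "final_mean_pi": float(result.pi_series[-1, 1]) if len(result.pi_series) else None,
        })
    elif isinstance(result, list) and all(isinstance(r, SubstitutionResult) for r in result):
        pd.DataFrame(
            [(r.mean_residence, r.mean_jc69_distance, r.se, r.n_sampled, r.n_saturated,
              r.M, r.c) for r in result],
            columns=["mean_residence", "mean_jc69", "se", "n_sampled", "n_saturated",
                     "M", "c"]).to_csv(out / "substitution.tsv", sep="\t", index=False)
        summary["grid_points"] = len(result)
        summary["n_saturated_total"] = int(sum(r.n_saturated for r in result))
    elif isinstance(result, RegimeReport):
        summary.update(dataclasses.asdict(result))
    else:  # pragma: no cover
        raise TypeError(f"unknown result type {type(result)!r}")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))
    return out


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)!r}")
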