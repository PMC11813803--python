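"""Config loading, CSV/JSON writers and run manifests shared by the CLI."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meanfield import DensityGrid, LocalizationVerdict, TailLaw
from .simulate import EnsembleSeries

__all__ = [
    "ConfigError",
    "load_config",
    "require_keys",
    "write_snapshots_csv",
    "write_events_csv",
    "write_variance_csv",
    "write_density_csv",
    "read_density_csv",
    "tail_law_to_json",
    "verdict_to_json",
    "RunManifest",
]


class ConfigError(ValueError):
    """A configuration file is missing or malformed."""


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def require_keys(cfg: dict, keys) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise ConfigError(f"missing required config key(s): {', '.join(missing)}")


def write_snapshots_csv(series: EnsembleSeries, path) -> None:
    n_t, n_p = series.snapshots.shape
    frame = pd.DataFrame(
        {
            "time": np.repeat(series.sample_times, n_p),
            "particle_id": np.tile(np.arange(n_p), n_t),
            "position": series.snapshots.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def write_events_csv(series: EnsembleSeries, path) -> None:
    pd.DataFrame(series.events).to_csv(path, index=False)


def write_variance_csv(times, variance, path, time_col: str = "time",
                       var_col: str = "variance") -> None:
    pd.DataFrame({time_col: times, var_col: variance}).to_csv(path, index=False)


def write_density_csv(grid: DensityGrid, path) -> None:
    pd.DataFrame({"chi": grid.chi, "density": grid.density}).to_csv(path, index=False)


def read_density_csv(path, time: float = 0.0) -> DensityGrid:
    frame = pd.read_csv(path)
    return DensityGrid(chi=frame["chi"].to_numpy(),
                       density=frame["density"].to_numpy(), time=time)


def tail_law_to_json(law: TailLaw, path) -> None:
    payload = {
        "form": law.form,
        "alpha": law.alpha,
        "rho": law.rho,
        "sqrt_rho": law.sqrt_rho,
        "rate_or_exponent": law.rate_or_exponent,
        "normalizable": law.normalizable,
        "chi_ref": law.chi_ref,
        "p_ref": law.p_ref,
        "valid_for": "asymptotic |chi| -> inf",
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def verdict_to_json(verdict: LocalizationVerdict, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(verdict), indent=2) + "\n"
    )


class RunManifest:
    """Collects parameters, derived quantities and produced files of one run
    and serializes them to a round-trippable JSON document."""

    def __init__(self, command: str, config: dict, seed) -> None:
        self._t0 = time.perf_counter()
        self.payload: dict = {
            "command": command,
            "config": _plain(config),
            "seed": seed,
            "derived": {},
            "files": [],
        }

    def add_derived(self, **quantities) -> None:
        self.payload["derived"].update(_plain(quantities))

    def add_file(self, path) -> None:
        self.payload["files"].append(Path(path).name)

    def write(self, path) -> None:
        self.payload["wall_time_s"] = round(time.perf_counter() - self._t0, 3)
        Path(path).write_text(json.dumps(self.payload, indent=2, sort_keys=True) + "\n")


def _plain(obj):
    """Recursively convert numpy scalars/arrays for lossless JSON round-trips."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
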