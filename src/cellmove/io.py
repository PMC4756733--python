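"""Coordinate tables, configuration files and run manifests.

Coordinates travel as plain CSV with unit-suffixed headers (``x_um, y_um``,
optionally ``time_h`` and ``replicate``). Configurations are flat YAML with
``model``, ``numerics``, ``pcf`` and ``run`` sections; the named presets
``fig2``, ``fig3`` and ``fig4`` ship the three parameter sets used in the
numerical studies (weak/strong directional bias at high density in a small
square domain, neighbour-dependent motility in the same geometry, and the
fibroblast-scale strip-domain set with cell-diameter interaction ranges).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ModelParams
from .errors import ConfigError
from .ibm import CellConfiguration, Domain
from .moments import MomentParams

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "load_config",
    "dump_config",
    "load_preset",
    "preset_path",
    "write_manifest",
]

_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_NUMERICS_KEYS = {f.name for f in dataclasses.fields(MomentParams)}
_PCF_KEYS = {"delta_r", "r_max", "periodic"}
_RUN_KEYS = {"t_end", "output_times", "replicates"}


def read_coordinates(path, x_col: str = "x_um", y_col: str = "y_um",
                     domain: Domain | None = None, periodic: bool = False,
                     time: float = 0.0) -> CellConfiguration:
    """Read a coordinate table (µm) into a configuration.

    ``x_col``/``y_col`` allow a custom column mapping for third-party tables.
    If ``domain`` is given, out-of-domain points raise an error in periodic
    mode and a warning otherwise; without a domain, a non-periodic bounding
    box is inferred from the data extent.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ConfigError(f"{path}: no data rows")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing required column {col!r}")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ConfigError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise ConfigError(f"{path}: missing value in column {col!r} at data row {row}")
    pts = df[[x_col, y_col]].to_numpy(dtype=float)
    if domain is None:
        domain = Domain(float(pts[:, 0].max()) or 1.0, float(pts[:, 1].max()) or 1.0,
                        periodic=False)
    else:
        outside = ((pts[:, 0] < 0) | (pts[:, 0] >= domain.Lx)
                   | (pts[:, 1] < 0) | (pts[:, 1] >= domain.Ly))
        if outside.any():
            msg = f"{int(outside.sum())} points fall outside the declared domain"
            if periodic or domain.periodic:
                raise ConfigError(msg + " (fatal in periodic mode)")
            warnings.warn(msg, stacklevel=2)
    return CellConfiguration(pts, time, domain)


def write_coordinates(config: CellConfiguration, path, replicate: int | None = None) -> None:
    """Write a configuration as CSV (columns x_um, y_um, time_h[, replicate])."""
    df = pd.DataFrame({"x_um": config.positions[:, 0], "y_um": config.positions[:, 1]})
    df["time_h"] = config.time
    if replicate is not None:
        df["replicate"] = replicate
    df.to_csv(path, index=False)


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")


def _parse(doc: dict):
    if not isinstance(doc, dict) or "model" not in doc:
        raise ConfigError("config must be a mapping with a required 'model' section")
    _check_keys(doc, {"model", "numerics", "pcf", "run"}, "top level")
    _check_keys(doc["model"], _MODEL_KEYS, "model")
    missing = _MODEL_KEYS - set(doc["model"])
    if missing:
        raise ConfigError(f"missing model parameters: {sorted(missing)}")
    try:
        model = ModelParams(**doc["model"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid model parameters: {exc}") from exc
    numerics = None
    if "numerics" in doc:
        _check_keys(doc["numerics"], _NUMERICS_KEYS, "numerics")
        try:
            numerics = MomentParams(**doc["numerics"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid numerics parameters: {exc}") from exc
    options: dict = {}
    if "pcf" in doc:
        _check_keys(doc["pcf"], _PCF_KEYS, "pcf")
        options.update(doc["pcf"])
    if "run" in doc:
        _check_keys(doc["run"], _RUN_KEYS, "run")
        options.update(doc["run"])
    return model, numerics, options


def load_config(path):
    """Parse and validate a YAML config; returns (ModelParams, MomentParams|None, options)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise ConfigError(f"{path}: empty config (model parameters are required)")
    return _parse(doc)


def dump_config(model: ModelParams, numerics: MomentParams | None, options: dict, path) -> None:
    """Write a config document that load_config parses back identically."""
    doc: dict = {"model": dataclasses.asdict(model)}
    if numerics is not None:
        doc["numerics"] = {k: v for k, v in dataclasses.asdict(numerics).items()
                           if v is not None}
    pcf = {k: v for k, v in options.items() if k in _PCF_KEYS}
    run = {k: v for k, v in options.items() if k in _RUN_KEYS}
    if pcf:
        doc["pcf"] = pcf
    if run:
        doc["run"] = run
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def preset_path(name: str) -> Path:
    p = importlib.resources.files("cellmove") / "presets" / f"{name}.yaml"
    if not p.is_file():
        raise ConfigError(f"unknown preset {name!r}")
    return Path(str(p))


def load_preset(name: str):
    """Load a shipped preset ('fig2', 'fig3' or 'fig4')."""
    return load_config(preset_path(name))


def write_manifest(out_dir, command: str, seed=None, **extra) -> Path:
    """Drop a JSON manifest (command, parameters, seed, version) next to outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"command": command, "seed": seed, "cellmove_version": __version__}
    for k, v in extra.items():
        if dataclasses.is_dataclass(v):
            v = dataclasses.asdict(v)
        payload[k] = v
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
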