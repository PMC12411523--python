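"""TIFF/CSV/YAML plumbing, configuration files and run manifests.

Images are exchanged as single- or multi-page grayscale TIFF (one page per
channel); masks as 8-bit TIFF with 0 = background and 255 = foreground.
The physical pixel pitch always comes from configuration, never from TIFF
metadata (metadata dialects vary too much between acquisition systems).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import tifffile
import yaml

from . import __version__
from .postprocess import AnalysisConfig
from .simulate import SimulationConfig

FLOAT_FORMAT = "%.6g"  # fixed CSV float formatting for diff-stable outputs


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


def read_image(path: Union[str, Path]) -> List[np.ndarray]:
    """Read a TIFF into a list of 2-D channel arrays.

    Accepts a single page, a multi-page stack, or a 3-D array whose
    smallest axis (<= 4) indexes channels.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        return [np.asarray(data)]
    if data.ndim == 3:
        axis = int(np.argmin(data.shape))
        if data.shape[axis] > 4:
            raise ValueError(f"cannot identify channel axis of shape {data.shape}")
        return [np.take(data, i, axis=axis) for i in range(data.shape[axis])]
    raise ValueError(f"unsupported TIFF dimensionality: {data.ndim}")


def write_image(path: Union[str, Path], channels: List[np.ndarray]) -> None:
    """Write channels as a multi-page float32 TIFF."""
    stack = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
    tifffile.imwrite(str(path), stack)


def read_mask(path: Union[str, Path]) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def write_mask(path: Union[str, Path], mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def write_zones(path: Union[str, Path], zones: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(zones, dtype=np.uint8))


_ANALYSIS_FIELDS = {f.name for f in dataclasses.fields(AnalysisConfig)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def _load_yaml(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a key-value mapping")
    return data


def _coerce_tuples(data: dict) -> dict:
    out = dict(data)
    for key in ("angle_range_deg", "freq_range_nm"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def load_analysis_config(path: Union[str, Path]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; unknown keys are rejected
    and missing keys take the reference defaults."""
    data = _coerce_tuples(_load_yaml(path))
    unknown = set(data) - _ANALYSIS_FIELDS
    if unknown:
        raise ConfigError(f"unknown analysis config keys: {sorted(unknown)}")
    try:
        return AnalysisConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    data = _load_yaml(path)
    unknown = set(data) - _SIM_FIELDS
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    try:
        return SimulationConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: Union[str, Path],
    config: object,
    inputs: Optional[dict] = None,
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> dict:
    """Write a JSON run manifest sufficient to reproduce the run exactly."""
    manifest = {
        "tool": "ringcorr",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
        "inputs": {
            name: file_sha256(p) for name, p in (inputs or {}).items()
        },
        "seed": seed,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def write_csv(df, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
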