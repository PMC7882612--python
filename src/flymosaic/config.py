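"""Run configuration: YAML-backed settings shared by the pipeline stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import yaml

from .errors import InputError
from .spectra import DEFAULT_LAMBDA_MAX, WavelengthGrid
from .vision import DEFAULT_THRESHOLDS


def _default_config() -> Dict[str, Any]:
    return {
        "seed": 0,
        "grid": {"start_nm": 300.0, "stop_nm": 700.0, "step_nm": 1.0},
        "illuminant": "d65",
        "photon_units": True,
        "receptors": {"source": "nomogram", "lambda_max": dict(DEFAULT_LAMBDA_MAX)},
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "transform": "hyperbolic",
        "one_sided_welch": False,
        "vision": {"n_images": 5, "n_regions": 5, "spectra": None, "manifest": None},
        "mosaic": {"surveys": None, "site_colors": None, "landscape": {}},
        "choice": {"trials": None, "sim": {}, "jackknife": "one-step"},
    }


def _deep_update(base: Dict[str, Any], extra: Mapping[str, Any]) -> Dict[str, Any]:
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


@dataclass
class RunConfig:
    """Validated pipeline settings with provenance support."""

    data: Dict[str, Any] = field(default_factory=_default_config)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        seed = self.data["seed"]
        if not isinstance(seed, int):
            raise InputError(f"seed must be an integer, got {seed!r}")
        return seed

    @property
    def grid(self) -> WavelengthGrid:
        g = self.data["grid"]
        return WavelengthGrid(float(g["start_nm"]), float(g["stop_nm"]), float(g["step_nm"]))

    def config_hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> Dict[str, Any]:
        from . import __version__

        return {
            "package": "flymosaic",
            "version": __version__,
            "seed": self.seed,
            "config_hash": self.config_hash(),
        }


def load_config(path: Optional[str | Path] = None, seed: Optional[int] = None) -> RunConfig:
    """Load a YAML config over the defaults; ``seed`` overrides the file."""
    data = _default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise InputError(f"config file {path} must contain a YAML mapping")
        _deep_update(data, loaded)
    if seed is not None:
        data["seed"] = int(seed)
    return RunConfig(data)
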