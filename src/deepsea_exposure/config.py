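"""Run configuration, schema validation and the reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .grid import ValidationError

SCHEMA_VERSION = 1

#: all tunable keys with their defaults, grouped by stage
DEFAULTS: dict = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "grid": {"nlat": 24, "nlon": 24,
             "lat_range": [-12.0, 11.0], "lon_range": [-150.0, -127.0]},
    "years": {"start": 1951, "end": 2100},
    "simulate": {
        "trend_magnitude": 0.05,     # driver units per year, harmful direction
        "baseline_sd": 1.0,          # stationary AR(1) SD, driver units
        "ar1_phi": 0.3,
        "scenarios": {"rcp85": 1.0, "rcp26": 0.4},  # trend scale per scenario
    },
    "hazard": {
        "baseline_window": [1951, 2000],
        "windows": [[2041, 2060], [2081, 2100]],
        "clamp_beneficial": True,
    },
    "toe": {"k": 1.0, "rule": "sustained", "horizon": 2100, "two_sided": False},
    "connectivity": {
        "flow_kind": "double_gyre",
        "amplitude_ms": 0.2,
        "n_sites": 6,
        "particles_per_release": 10,
        "n_releases": 12,
        "duration_days": 180.0,
        "dt_hours": 6.0,
        "diffusivity_m2s": 50.0,
        "capture_radius_km": 50.0,
        "future_amplitude_scale": 1.5,
    },
    "refugia": {"n_species": 6, "n_calibration": 200, "mode": "present_and_future"},
}


def show_defaults() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=False)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            val = user[key]
            if isinstance(default, dict):
                if not isinstance(val, dict):
                    raise ValidationError(f"config key {here!r} must be a mapping")
                out[key] = _merge(default, val, here)
            else:
                out[key] = val
        else:
            out[key] = default
    unknown = set(user) - set(defaults)
    if unknown:
        name = f"{path}.{sorted(unknown)[0]}" if path else sorted(unknown)[0]
        raise ValidationError(f"unknown config key {name!r}")
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML config, filling defaults.

    Unknown keys raise a :class:`ValidationError` naming the offending key.
    """
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError("config file must contain a mapping")
    cfg = _merge(DEFAULTS, user)
    for key, val in (overrides or {}).items():
        if val is not None:
            cfg[key] = val
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {cfg['schema_version']}")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every stage's outputs.

    The embedded resolved config can be replayed: running the same
    subcommand with it (and the same seed) reproduces deterministic outputs
    bit-for-bit.
    """

    subcommand: str
    config: dict
    config_hash: str
    seed: int
    inputs: dict = field(default_factory=dict)      # path -> digest
    outputs: list = field(default_factory=list)
    software_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, subcommand: str, cfg: dict, inputs: dict | None = None):
        from . import __version__

        return cls(subcommand=subcommand, config=cfg, config_hash=config_hash(cfg),
                   seed=int(cfg.get("seed", 0)), inputs=inputs or {},
                   software_version=__version__,
                   timestamp=datetime.now(timezone.utc).isoformat())

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / f"manifest_{self.subcommand}.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path
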