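"""YAML experiment configuration.

A single structured key-value file controls every module default; every
run echoes the fully resolved configuration (all defaults filled in)
next to its outputs, so a run directory is self-describing and
re-runnable.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["DEFAULTS", "load_config", "resolve_config", "dump_config"]

DEFAULTS: dict = {
    "seed": None,  # mandatory for simulation
    "phantom": {
        "kind": "bead_field+vessel_tree",
        "shape": [48, 48, 48],
        "margin": 14,
        "n_beads": 6,
    },
    "psf": {
        "sigma_lateral": 1.0,
        "sigma_transverse": 1.0,
        "sigma_scan": 3.0,
    },
    "acquisition": {
        "angle_step": 30.0,   # degrees; a full turn -> n_views = 360/step
        "angles": None,       # explicit list overrides angle_step
        "voxel_pitch": [1.0, 1.0, 1.0],
        "interp_order": 3,
    },
    "shifts": {
        "max_abs": 4,
        "fractional": False,
    },
    "noise": {
        "kind": "none",
        "gaussian_sigma": 0.0,
        "photon_scale": 100.0,
        "background_level": 0.0,
    },
    "solver": {
        "scheme": "ss",
        "n_iter": 5000,
        "checkpoint_every": 100,
        "mode": "circular",
        "tol": None,
        "init": "reference",
    },
    "preprocess": {
        "background": True,
        "dark_region_size": 8,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValidationError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def resolve_config(user: dict | None) -> dict:
    """Merge a user configuration over the defaults.

    Unknown keys raise a :class:`ValidationError` naming every offender's
    full path.
    """
    return _merge(DEFAULTS, user or {})


def load_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"configuration root must be a mapping: {path}")
    return resolve_config(raw)


def dump_config(cfg: dict, path) -> None:
    """Write the fully resolved configuration next to run outputs."""
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def angles_from_config(cfg: dict):
    acq = cfg["acquisition"]
    if acq.get("angles"):
        return [float(a) for a in acq["angles"]]
    step = float(acq["angle_step"])
    if step <= 0 or 360.0 % step != 0:
        raise ValidationError("angle_step must positively divide 360")
    return [float(a) for a in
            [step * i for i in range(int(round(360.0 / step)))]]
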