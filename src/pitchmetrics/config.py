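"""Analysis configuration: YAML file merged over package defaults."""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .kinematics import PaceScheme
from .positional import PitchModel
from .synchrony import ApEnParams

DEFAULTS: dict = {
    "pitch": {"length": 105.0, "width": 68.0},
    "rate": 10.0,
    "pace": {
        "thresholds": [0.2, 2.1, 3.8, 6.1],
        "labels": ["Standing", "Walking", "Jogging", "Running", "Sprinting"],
    },
    "apen": {"m": 2, "r": 0.2, "r_mode": "sd"},
    "smoothing_window_s": 0.5,
    "heatmap_bin_m": 1.0,
    "max_gap_s": 0.5,
    "strict_bounds": False,
}


def load_config(path: str | Path | None = None) -> dict:
    """Package defaults, overridden by an optional YAML config file."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    try:
        user = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigError(f"config {path} must be a mapping")
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            unknown = set(value) - set(cfg[key])
            if unknown:
                raise ConfigError(f"unknown config keys {sorted(unknown)} under {key!r}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def pitch_from_config(cfg: dict) -> PitchModel:
    try:
        return PitchModel(
            length=float(cfg["pitch"]["length"]), width=float(cfg["pitch"]["width"])
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid pitch dimensions: {exc}") from exc


def pace_scheme_from_config(cfg: dict) -> PaceScheme:
    try:
        return PaceScheme(
            thresholds=tuple(float(t) for t in cfg["pace"]["thresholds"]),
            labels=tuple(str(s) for s in cfg["pace"]["labels"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid pace scheme: {exc}") from exc


def apen_params_from_config(cfg: dict) -> ApEnParams:
    try:
        return ApEnParams(
            m=int(cfg["apen"]["m"]),
            r=float(cfg["apen"]["r"]),
            r_mode=str(cfg["apen"]["r_mode"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid ApEn parameters: {exc}") from exc
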