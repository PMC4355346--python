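"""Layered run configuration: defaults < TOML file < explicit overrides.

Every tunable of the pipeline lives under a dotted ``section.key`` name.
Unknown keys and out-of-range values are rejected with a
:class:`~retveseg.errors.ConfigError` naming the offender, so a typo in a
config file can never silently fall back to a default.
"""

from __future__ import annotations

import copy
import tomllib
from pathlib import Path

from .errors import ConfigError

DEFAULTS: dict = {
    "diffusion": {"psi": 0.125, "kappa": 30.0, "iterations": 15},
    "threshold": {"t0": 15.0, "tol": 0.5},
    "mask": {
        "green_threshold": 10,   # grey levels, or "auto" for iterative estimation
        "open_radius": 1,
        "dilate_radius": 15,
        "erode_radius": 10,
        "fill_holes": True,
        "source": "computed",    # "computed" | "provided" (dataset FOV files)
    },
    "od": {"channel": "red", "fill": "zero"},
    "vessel": {"line_length": 10, "source": "od_eliminated"},
    "postprocess": {
        "s_size": 15,            # disc radius of the top-hat structuring element
        "min_component": 50,     # components smaller than this are noise
        "connectivity": 8,
        "eq10": "tophat",        # "tophat" | "literal" (plain erosion, for audit)
    },
    "evaluation": {"fov_only": True},
}


def _is_pos_int(v) -> bool:
    return isinstance(v, int) and not isinstance(v, bool) and v >= 1


def _is_number(v) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


_VALIDATORS = {
    ("diffusion", "psi"): (lambda v: _is_number(v) and 0 < v <= 1, "a number in (0, 1]"),
    ("diffusion", "kappa"): (lambda v: _is_number(v) and v > 0, "a positive number"),
    ("diffusion", "iterations"): (_is_pos_int, "a positive integer"),
    ("threshold", "t0"): (_is_number, "a number"),
    ("threshold", "tol"): (lambda v: _is_number(v) and v > 0, "a positive number"),
    ("mask", "green_threshold"): (
        lambda v: v == "auto" or (_is_number(v) and v >= 0),
        'a non-negative number or "auto"',
    ),
    ("mask", "open_radius"): (_is_pos_int, "a positive integer"),
    ("mask", "dilate_radius"): (_is_pos_int, "a positive integer"),
    ("mask", "erode_radius"): (_is_pos_int, "a positive integer"),
    ("mask", "fill_holes"): (lambda v: isinstance(v, bool), "a boolean"),
    ("mask", "source"): (lambda v: v in ("computed", "provided"), '"computed" or "provided"'),
    ("od", "channel"): (lambda v: v in ("red", "green"), '"red" or "green"'),
    ("od", "fill"): (lambda v: v in ("zero", "mean"), '"zero" or "mean"'),
    ("vessel", "line_length"): (_is_pos_int, "a positive integer"),
    ("vessel", "source"): (
        lambda v: v in ("od_eliminated", "green"),
        '"od_eliminated" or "green"',
    ),
    ("postprocess", "s_size"): (_is_pos_int, "a positive integer"),
    ("postprocess", "min_component"): (_is_pos_int, "a positive integer"),
    ("postprocess", "connectivity"): (lambda v: v in (4, 8), "4 or 8"),
    ("postprocess", "eq10"): (lambda v: v in ("tophat", "literal"), '"tophat" or "literal"'),
    ("evaluation", "fov_only"): (lambda v: isinstance(v, bool), "a boolean"),
}


def _coerce(text: str):
    """Best-effort typing of a command-line override value."""
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def validate_config(cfg: dict) -> None:
    """Reject unknown keys and out-of-range values."""
    for section, keys in cfg.items():
        if section not in DEFAULTS:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(keys, dict):
            raise ConfigError(f"section {section!r} must be a table of keys")
        for key, value in keys.items():
            if key not in DEFAULTS[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            ok, expected = _VALIDATORS[(section, key)]
            if not ok(value):
                raise ConfigError(f"config key {section}.{key} must be {expected}, got {value!r}")


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Resolve the full configuration.

    ``path`` is an optional TOML file; ``overrides`` maps dotted
    ``"section.key"`` strings to values (strings are coerced to
    bool/int/float where possible, convenient for CLI ``--set`` flags).
    The result always contains every key, fully validated.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(Path(path), "rb") as fh:
            try:
                loaded = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        validate_config(loaded)
        for section, keys in loaded.items():
            cfg[section].update(keys)
    if overrides:
        for dotted, value in overrides.items():
            if "." not in dotted:
                raise ConfigError(f"override {dotted!r} is not of the form section.key")
            section, key = dotted.split(".", 1)
            if isinstance(value, str):
                value = _coerce(value)
            validate_config({section: {key: value}})
            cfg[section][key] = value
    validate_config(cfg)
    return cfg


def resolve_config(cfg: dict | None) -> dict:
    """Merge a possibly partial config dict onto the defaults and validate."""
    if cfg is None:
        return copy.deepcopy(DEFAULTS)
    validate_config(cfg)
    out = copy.deepcopy(DEFAULTS)
    for section, keys in cfg.items():
        out[section].update(keys)
    return out
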