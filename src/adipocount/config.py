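"""Pipeline configuration: nested key-value parameters with validation.

Configs are plain nested dicts, loadable from YAML.  Unknown keys are
rejected and values are checked against the owning parameter's type and
range, so typos fail fast instead of silently running with defaults.
"""

from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "validate_config"]


class ConfigError(ValueError):
    """Invalid configuration: lists every offending key."""


def _positive(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool) and x > 0


def _non_negative(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool) and x >= 0


def _non_negative_int(x) -> bool:
    return isinstance(x, int) and not isinstance(x, bool) and x >= 0


def _is_bool(x) -> bool:
    return isinstance(x, bool)


def _canny_threshold(x) -> bool:
    return x == "auto" or (_non_negative(x))


# (default, validator, description)
_SCHEMA: dict[str, dict[str, tuple[Any, Any, str]]] = {
    "preprocessing": {
        "g1_sigma": (0.5, _positive, "narrow Gaussian sigma (px)"),
        "g1_size": (3, lambda x: _non_negative_int(x) and x >= 1, "narrow Gaussian window size (px)"),
        "g2_sigma": (30.0, _positive, "wide Gaussian sigma (px)"),
        "g2_size": (60, lambda x: _non_negative_int(x) and x >= 1, "wide Gaussian window size (px)"),
        "illumination_correction": (True, _is_bool, "apply DoG illumination correction before thresholding"),
    },
    "segmentation": {
        "canny_low": ("auto", _canny_threshold, "Canny low hysteresis threshold or 'auto'"),
        "canny_high": ("auto", _canny_threshold, "Canny high hysteresis threshold or 'auto'"),
        "canny_sigma": (1.0, _positive, "Canny Gaussian pre-smoothing sigma (px)"),
    },
    "reseg": {
        "enabled": (True, _is_bool, "run the watershed re-segmentation stage"),
        "area_threshold": (64, _non_negative_int, "minimum membrane component area kept (px)"),
        "open_radius": (1, _non_negative_int, "opening disk radius (px)"),
        "close_radius": (1, _non_negative_int, "closing disk radius (px)"),
        "dilate_radius": (1, _non_negative_int, "dilation disk radius (px)"),
        "max_length": (50.0, _positive, "watershed line length threshold L_T (px)"),
        "max_area_ratio": (3.0, lambda x: _positive(x) and x > 1, "basin area ratio threshold R_a"),
        "h_maxima": (1.0, _non_negative, "regional-maxima merge depth h (distance units)"),
    },
    "count": {
        "min_cell_area": (30, _non_negative_int, "minimum labeled cell area kept (px)"),
        "exclude_border": (False, _is_bool, "drop cells touching the image border"),
        "connectivity": (4, lambda x: x in (4, 8), "interior labeling connectivity"),
        "microns_per_pixel": (None, lambda x: x is None or _positive(x), "physical calibration passthrough"),
    },
    "eval": {
        "iou_threshold": (0.5, lambda x: _positive(x) and x <= 1, "label matching IoU threshold"),
    },
    "synth": {
        "height": (256, lambda x: _non_negative_int(x) and x >= 16, "image height (px)"),
        "width": (256, lambda x: _non_negative_int(x) and x >= 16, "image width (px)"),
        "n_cells": (35, lambda x: _non_negative_int(x) and x >= 1, "number of cells"),
        "min_spacing": (24.0, _positive, "minimum seed spacing (px)"),
        "membrane_width": (3, lambda x: _non_negative_int(x) and x >= 1, "drawn membrane width (px)"),
        "membrane_intensity": (70.0, _non_negative, "mean membrane gray level"),
        "background_intensity": (215.0, _non_negative, "mean background gray level"),
        "noise_sigma": (5.0, _non_negative, "per-pixel Gaussian noise sigma"),
        "gap_fraction": (0.05, lambda x: _non_negative(x) and x < 1, "fraction of membrane skeleton erased"),
        "gap_run_length": (12.0, _positive, "mean erased-run length (px)"),
        "n_debris": (6, _non_negative_int, "debris fragment count"),
        "debris_size": (12, lambda x: _non_negative_int(x) and x >= 1, "debris fragment area (px)"),
        "vignette_strength": (0.15, lambda x: _non_negative(x) and x < 1, "corner darkening factor"),
    },
}


def default_config() -> dict:
    """Full config with every parameter at its default."""
    return {
        section: {key: copy.deepcopy(spec[0]) for key, spec in keys.items()}
        for section, keys in _SCHEMA.items()
    }


def validate_config(cfg: Mapping) -> None:
    """Raise :class:`ConfigError` listing every unknown or invalid key."""
    problems = []
    for section, keys in cfg.items():
        if section not in _SCHEMA:
            problems.append(f"unknown section '{section}'")
            continue
        if not isinstance(keys, Mapping):
            problems.append(f"section '{section}' must be a mapping")
            continue
        for key, value in keys.items():
            if key not in _SCHEMA[section]:
                problems.append(f"unknown key '{section}.{key}'")
                continue
            _, check, desc = _SCHEMA[section][key]
            if not check(value):
                problems.append(
                    f"invalid value for '{section}.{key}' ({desc}): {value!r}"
                )
    if problems:
        raise ConfigError("; ".join(problems))


def load_config(
    path: str | None = None, overrides: Mapping | None = None
) -> dict:
    """Merge defaults <- YAML file <- overrides, validating each layer."""
    cfg = default_config()
    for layer in (_read_yaml(path) if path else None, overrides):
        if not layer:
            continue
        validate_config(layer)
        for section, keys in layer.items():
            cfg[section].update(keys)
    return cfg


def _read_yaml(path: str) -> Mapping:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data
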