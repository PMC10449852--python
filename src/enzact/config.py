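"""Build landscapes and assay conditions from JSON/YAML config files.

Recognised keys (exact names, all optional unless noted): ``dG1`` (required
for a landscape), ``dGT`` (required), ``alpha1``, ``alpha2``, ``k1_0``,
``k2_0``, ``temperature``, ``S`` (required for a condition), ``P``, ``ET``,
``gamma``, ``mechanism``.  Energies in kJ/mol, concentrations in uM,
temperature in K.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .thermo import AssayCondition, ThermoLandscape

__all__ = ["read_config", "landscape_from_dict", "condition_from_dict"]

_LANDSCAPE_KEYS = ("dG1", "dGT", "alpha1", "alpha2", "k1_0", "k2_0", "temperature")
_CONDITION_KEYS = ("S", "P", "ET", "gamma", "mechanism")


def read_config(path) -> dict:
    """Parse a JSON or YAML parameter file into a flat dict."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping of parameter names")
    unknown = set(data) - set(_LANDSCAPE_KEYS) - set(_CONDITION_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def landscape_from_dict(data: dict, **overrides) -> ThermoLandscape:
    """ThermoLandscape from config values; keyword overrides win."""
    kwargs = {k: data[k] for k in _LANDSCAPE_KEYS if k in data}
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    missing = {"dG1", "dGT"} - set(kwargs)
    if missing:
        raise ValueError(f"landscape parameters missing: {sorted(missing)}")
    return ThermoLandscape(**kwargs)


def condition_from_dict(data: dict, **overrides) -> AssayCondition:
    """AssayCondition from config values; keyword overrides win."""
    kwargs = {k: data[k] for k in _CONDITION_KEYS if k in data}
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    if "S" not in kwargs:
        raise ValueError("condition parameter 'S' missing")
    return AssayCondition(**kwargs)
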