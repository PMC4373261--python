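"""YAML configuration loading and validation.

Schema (all keys optional; defaults fill in):

.. code-block:: yaml

    network:
      n_ec: 800
      n_dg: 4000
      r: 0.1
      n_bins: 500
      bin_ms: 10.0
      pattern_size: 20
      n_patterns: 40
      alpha: null          # or a positive number
      seed: 0
    cell:
      v_rest: -75.0
      v_threshold: -45.0
      tau_m: 10.0
      spikes_to_threshold: 10
      refractory_bins: 0
    encoding:
      S: 100
      theta: 2
      inhibition_mode: scaled   # scaled | subtractive | scaled-const
    sweep:
      r_values: [...]
      p_values: [...]
      alpha_values: [...]      # entries may be null for "no inhibition"
      trials: 20
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .network import GranuleCellParams, NetworkConfig

__all__ = ["ConfigError", "validate_config", "load_config", "normalized_config"]


class ConfigError(ValueError):
    """A configuration file failed validation; ``errors`` lists violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


_SECTIONS = ("network", "cell", "encoding", "sweep")

_ENCODING_DEFAULTS = {"S": 100, "theta": 2, "inhibition_mode": "scaled"}
_SWEEP_DEFAULTS: dict[str, Any] = {
    "r_values": None, "p_values": None, "alpha_values": None, "trials": 20,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a YAML config file into a raw dictionary (no validation)."""
    path = Path(path)
    with path.open() as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError([f"{path}: YAML parse error: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return raw


def validate_config(path: str | Path) -> dict[str, Any]:
    """Validate a YAML config file; return the normalized configuration.

    The result has keys ``network`` (a :class:`NetworkConfig`), ``cell``
    (a :class:`GranuleCellParams`, also embedded in the network config),
    ``encoding`` and ``sweep`` (plain dictionaries with defaults filled).
    Raises :class:`ConfigError` naming every violation.
    """
    return normalized_config(load_config(path))


def normalized_config(raw: dict[str, Any]) -> dict[str, Any]:
    """Validate an already-parsed configuration dictionary."""
    errors = [f"unknown section {key!r}" for key in raw if key not in _SECTIONS]

    cell_fields = {f.name for f in dataclasses.fields(GranuleCellParams)}
    cell_raw = raw.get("cell") or {}
    errors += [f"cell: unknown field {k!r}" for k in cell_raw if k not in cell_fields]
    net_fields = {f.name for f in dataclasses.fields(NetworkConfig)} - {"cell"}
    net_raw = raw.get("network") or {}
    errors += [f"network: unknown field {k!r}" for k in net_raw if k not in net_fields]

    cell = None
    if not errors:
        try:
            cell = GranuleCellParams(**cell_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"cell: {exc}")
    network = None
    if cell is not None:
        try:
            network = NetworkConfig(cell=cell, **net_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"network: {exc}")

    encoding = {**_ENCODING_DEFAULTS, **(raw.get("encoding") or {})}
    for key in encoding:
        if key not in _ENCODING_DEFAULTS:
            errors.append(f"encoding: unknown field {key!r}")
    if encoding["inhibition_mode"] not in ("scaled", "subtractive", "scaled-const"):
        errors.append(
            "encoding: inhibition_mode must be one of scaled, subtractive, scaled-const"
        )

    sweep = {**_SWEEP_DEFAULTS, **(raw.get("sweep") or {})}
    for key in sweep:
        if key not in _SWEEP_DEFAULTS:
            errors.append(f"sweep: unknown field {key!r}")
    if not (isinstance(sweep["trials"], int) and sweep["trials"] >= 1):
        errors.append("sweep: trials must be an integer >= 1")
    for key in ("r_values", "p_values"):
        vals = sweep[key]
        if vals is not None:
            if not isinstance(vals, (list, tuple)) or not vals:
                errors.append(f"sweep: {key} must be a non-empty list")
            elif any(not (0 <= v <= 1) for v in vals):
                errors.append(f"sweep: {key} entries must be in [0, 1]")
    alphas = sweep["alpha_values"]
    if alphas is not None:
        if not isinstance(alphas, (list, tuple)) or not alphas:
            errors.append("sweep: alpha_values must be a non-empty list")
        elif any(a is not None and a <= 0 for a in alphas):
            errors.append("sweep: alpha_values entries must be positive or null")

    if errors:
        raise ConfigError(errors)
    return {"network": network, "cell": cell, "encoding": encoding, "sweep": sweep}
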