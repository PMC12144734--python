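"""Configuration surface: flat key-value files and the run manifest.

Config files are flat YAML mappings keyed by the tool's parameter names.
The dotted spellings used in the design table (``s.dist``, ``censoring.prob``,
``lossfu.dist``, ``one.sided.alpha``) are accepted verbatim, alongside
underscore and dash aliases.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .design import DesignConfig

__all__ = ["parse_config", "config_to_dict", "write_manifest", "SIZE_KEYS"]

# canonical key -> DesignConfig field
_KEY_MAP = {
    "n": "n", "r": "r", "m1": "m1", "m2": "m2", "shape": "shape", "k": "k",
    "f1": "f1", "m0": "m0", "f2": "f2", "margin": "margin",
    "ps": "ps", "rs": "rs", "rhos": "rhos",
    "s.dist": "s_dist", "entry": "entry",
    "censoring.prob": "censoring_prob", "lossfu.dist": "lossfu_dist",
    "Ta": "ta", "Te": "te", "tau": "tau",
    "one.sided.alpha": "one_sided_alpha", "TXswitch": "tx_switch",
    "af": "af", "n_simulations": "n_simulations", "seed": "seed",
}
SIZE_KEYS = ("nL", "nU", "B", "epwr")

_INT_FIELDS = {"n", "n_simulations", "seed"}
_FLOAT_FIELDS = {
    "r", "m1", "m2", "shape", "k", "f1", "m0", "f2", "margin", "ps", "rs",
    "rhos", "ta", "te", "tau", "one_sided_alpha", "af",
}


def _canonical(key: str) -> str:
    """Map aliased spellings (dashes/underscores, case) to the canonical key."""
    for canon in _KEY_MAP:
        variants = {canon, canon.replace(".", "_"), canon.replace(".", "-")}
        if key in variants or key.lower() in {v.lower() for v in variants}:
            return canon
    if key in SIZE_KEYS:
        return key
    raise KeyError(
        f"unknown design parameter {key!r}; expected one of "
        f"{sorted(_KEY_MAP) + list(SIZE_KEYS)}"
    )


def _coerce(field: str, value: Any) -> Any:
    if value is None:
        return None
    if field == "s_dist":
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        return str(value)
    if field == "censoring_prob":
        if isinstance(value, str) and value != "AC.only":
            try:
                return float(value)
            except ValueError as err:
                raise ValueError(
                    f"censoring.prob must be a probability or 'AC.only', got {value!r}"
                ) from err
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        return value
    if field in _INT_FIELDS:
        return int(value)
    if field in _FLOAT_FIELDS:
        return float(value)
    return str(value)


def parse_config(
    source: str | Path | Mapping[str, Any] | None = None,
    **overrides: Any,
) -> tuple[DesignConfig, dict[str, Any]]:
    """Build a DesignConfig from a config file/mapping plus explicit overrides.

    Returns ``(config, size_params)`` where ``size_params`` collects the
    sample-size-search keys (nL, nU, B, epwr) if present.  Explicit overrides
    win over file values.
    """
    raw: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, Mapping):
            items = dict(source)
        else:
            text = Path(source).read_text()
            items = yaml.safe_load(text) or {}
            if not isinstance(items, dict):
                raise ValueError(f"config file {source} must be a flat mapping")
        for key, value in items.items():
            raw[_canonical(str(key))] = value
    for key, value in overrides.items():
        if value is None:
            continue
        raw[_canonical(str(key))] = value

    size_params = {k: raw.pop(k) for k in list(raw) if k in SIZE_KEYS}
    if "nL" in size_params:
        size_params["nL"] = int(size_params["nL"])
    if "nU" in size_params:
        size_params["nU"] = int(size_params["nU"])
    if "B" in size_params:
        size_params["B"] = int(size_params["B"])
    if "epwr" in size_params:
        size_params["epwr"] = float(size_params["epwr"])

    kwargs = {}
    for key, value in raw.items():
        field = _KEY_MAP[key]
        kwargs[field] = _coerce(field, value)
    if "n" not in kwargs and size_params:
        kwargs["n"] = size_params.get("nL", 2)  # placeholder for size mode
    try:
        config = DesignConfig(**kwargs)
    except TypeError as err:
        raise ValueError(f"incomplete design configuration: {err}") from err
    return config, size_params


def config_to_dict(config: DesignConfig) -> dict[str, Any]:
    """Serialize a DesignConfig under the canonical (dotted) key names."""
    inverse = {v: k for k, v in _KEY_MAP.items()}
    out = {}
    for f in dataclasses.fields(config):
        out[inverse[f.name]] = getattr(config, f.name)
    return out


def write_manifest(
    path: str | Path,
    config: DesignConfig,
    solver_info: Mapping[str, Any],
    results: Mapping[str, Any],
) -> None:
    """Write the reproducibility manifest (config echo + solver outputs + results)."""
    from . import __version__

    payload = {
        "tool": "niswitch",
        "version": __version__,
        "config": config_to_dict(config),
        "solved": dict(solver_info),
        "results": dict(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj: Any) -> Any:
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
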