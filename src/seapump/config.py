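"""YAML run configuration with an ``extends`` mechanism.

A config file maps directly onto :class:`~seapump.integrate.RunConfig`;
nested sections (``calendar``, ``attenuation``, ``ecosystem``, ``forcing``)
map onto the corresponding parameter dataclasses.  A file may name a parent
through ``extends: <relative path>``; child keys override parent keys with
a per-section deep merge, so a variant is typically a three-line file.

The attenuation section additionally understands ``delta_b_frac`` (amplitude
as a fraction of ``b_ref``) as an alternative to the absolute ``delta_b``.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .attenuation import LambdaSeasonal, SeasonalAttenuation
from .ecosystem import EcosystemParams
from .forcing_synth import ForcingParams
from .integrate import RunConfig
from .model_core import Calendar

__all__ = ["load_config", "config_to_dict"]

_SECTIONS = {
    "calendar": Calendar,
    "ecosystem": EcosystemParams,
    "forcing": ForcingParams,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def _load_raw(path: Path, _seen=None) -> dict:
    path = path.resolve()
    _seen = _seen or set()
    if path in _seen:
        raise ValueError(f"circular 'extends' chain at {path}")
    _seen.add(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    parent_ref = raw.pop("extends", None)
    if parent_ref:
        parent = _load_raw((path.parent / parent_ref), _seen)
        raw = _deep_merge(parent, raw)
    return raw


def _build_attenuation(section: dict) -> SeasonalAttenuation:
    section = dict(section)
    ls = section.pop("lambda_seasonal", None)
    frac = section.pop("delta_b_frac", None)
    if frac is not None:
        # frac wins over an inherited absolute delta_b (extends-merge case)
        section["delta_b"] = frac * section.get("b_ref", 1.388)
    if ls is not None:
        section["lambda_seasonal"] = LambdaSeasonal(**ls)
    return SeasonalAttenuation(**section)


def load_config(path) -> RunConfig:
    raw = _load_raw(Path(path))
    kwargs = dict(raw)
    for name, cls in _SECTIONS.items():
        if name in kwargs:
            kwargs[name] = cls(**kwargs[name])
    if "attenuation" in kwargs:
        kwargs["attenuation"] = _build_attenuation(kwargs["attenuation"])
    if "interfaces" in kwargs and kwargs["interfaces"] is not None:
        kwargs["interfaces"] = tuple(kwargs["interfaces"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid config key ({exc})") from exc


def config_to_dict(config: RunConfig) -> dict:
    from dataclasses import asdict
    return asdict(config)
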