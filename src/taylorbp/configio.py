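"""YAML round-trip for the package's configuration dataclasses.

One file can carry any subset of the three sections::

    simulation:   # SimConfig fields (sessions as [[kind, dur_s, sbp], ...])
    model:        # ModelConfig fields
    training:     # TrainConfig fields
"""

from __future__ import annotations

import dataclasses

import yaml

from .network import ModelConfig
from .simulate import SimConfig
from .training import TrainConfig

__all__ = ["load_configs", "save_configs"]

_SECTIONS = {"simulation": SimConfig, "model": ModelConfig,
             "training": TrainConfig}


def _build(cls, payload: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    if cls is SimConfig and "sessions" in payload:
        payload = dict(payload,
                       sessions=tuple(tuple(s) for s in payload["sessions"]))
    return cls(**payload)


def load_configs(path) -> dict:
    """Read a YAML file into a dict of config objects keyed by section."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        out[section] = _build(_SECTIONS[section], payload or {})
    return out


def save_configs(path, **configs) -> None:
    """Write config objects (``simulation=``, ``model=``, ``training=``)."""
    doc = {}
    for section, obj in configs.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        d = dataclasses.asdict(obj)
        if isinstance(obj, SimConfig):
            d["sessions"] = [list(s) for s in obj.sessions]
        doc[section] = d
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
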