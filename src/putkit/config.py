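"""YAML configuration loading and run-directory snapshots."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .bubble import MediumProperties, SolverOptions
from .pa_source import OpticalPulse, VesselAbsorber
from .threshold import DriveProtocol

__all__ = [
    "load_yaml",
    "medium_from_dict",
    "vessel_from_dict",
    "pulse_from_dict",
    "protocol_from_dict",
    "snapshot",
]

_MEDIUM_KEYS = {f.name for f in dataclasses.fields(MediumProperties)}
_VESSEL_KEYS = {f.name for f in dataclasses.fields(VesselAbsorber)}
_PULSE_KEYS = {f.name for f in dataclasses.fields(OpticalPulse)}


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _filtered(d: dict, keys: set) -> dict:
    unknown = set(d) - keys
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)} (allowed: {sorted(keys)})")
    return d


def medium_from_dict(d: dict | None) -> MediumProperties:
    return MediumProperties(**_filtered(d or {}, _MEDIUM_KEYS))


def vessel_from_dict(d: dict | None) -> VesselAbsorber:
    return VesselAbsorber(**_filtered(d or {}, _VESSEL_KEYS))


def pulse_from_dict(d: dict | None) -> OpticalPulse:
    return OpticalPulse(**_filtered(d or {}, _PULSE_KEYS))


def protocol_from_dict(d: dict | None) -> DriveProtocol:
    d = dict(d or {})
    vessel = vessel_from_dict(d.pop("vessel", None))
    pulse = pulse_from_dict(d.pop("optical_pulse", None))
    return DriveProtocol(vessel=vessel, pulse=pulse, **d)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        try:
            return super().default(o)
        except TypeError:
            return str(o)


def snapshot(config: object, out_dir: str | Path, name: str = "config_snapshot.json") -> Path:
    """Serialize a run configuration into its output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    path.write_text(json.dumps(config, indent=2, cls=_Encoder))
    return path
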