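"""YAML configuration for the study pipeline.

The configuration overlays the reference-child defaults: any field left out
keeps its default, so a minimal config is an empty file.  Structure::

    patient:
      hr: 100
      control: {CO_target: 2.1, MAP_target: 61.0}
      oxygen: {S_pv: 0.98, VO2_total: 102.0}
      walls:
        LV: {V_w: 35.0, sigma_act: 250.0}
      nodes:
        AoP: {V_0: 25.0, C: 0.30}
      septum: {S_c: 0.2}
      pulmonary: {q_ref: 2.1, dp_ref: 9.0}
      r_upper: 55.0
    protocol:
      mpap_levels: [50, 55, 60, 65, 70, 75, 80]
      diameters_mm: [0, 1, ..., 16]
      reference_mpap: 15.0
      exercise_reference: {co_factor: 3.0, hr_factor: 2.0}
      exercise_compensated: {co_factor: 2.0, hr_factor: 1.8}
    output_dir: results
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .parameters import ExerciseSpec, ParameterSet, default_parameter_set
from .protocol import DIAMETERS_MM, MPAP_LEVELS


@dataclass
class ProtocolConfig:
    mpap_levels: tuple = MPAP_LEVELS
    diameters_mm: tuple = DIAMETERS_MM
    reference_mpap: float = 15.0
    exercise_reference: ExerciseSpec = field(
        default_factory=lambda: ExerciseSpec(3.0, 2.0))
    exercise_compensated: ExerciseSpec = field(
        default_factory=lambda: ExerciseSpec(2.0, 1.8))


@dataclass
class StudyConfig:
    patient: ParameterSet
    protocol: ProtocolConfig
    output_dir: Path
    raw_text: str = ""


def _apply(obj, mapping: dict) -> None:
    for key, value in mapping.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config field {key!r} on {type(obj).__name__}")
        current = getattr(obj, key)
        if isinstance(value, dict):
            if isinstance(current, dict):
                for sub, submap in value.items():
                    if sub not in current:
                        raise KeyError(f"unknown entry {sub!r} in {key}")
                    _apply(current[sub], submap)
            else:
                _apply(current, value)
        else:
            setattr(obj, key, type(current)(value) if current is not None else value)


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a study configuration; ``None`` gives the built-in defaults."""
    patient = default_parameter_set()
    protocol = ProtocolConfig()
    outdir = Path("results")
    text = ""
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if "patient" in data:
            _apply(patient, data["patient"])
        if "protocol" in data:
            proto = dict(data["protocol"])
            for name in ("exercise_reference", "exercise_compensated"):
                if name in proto:
                    _apply(getattr(protocol, name), proto.pop(name))
            for name in ("mpap_levels", "diameters_mm"):
                if name in proto:
                    setattr(protocol, name, tuple(float(v) for v in proto.pop(name)))
            for key, value in proto.items():
                if not hasattr(protocol, key):
                    raise KeyError(f"unknown protocol field {key!r}")
                setattr(protocol, key, value)
        if "output_dir" in data:
            outdir = Path(data["output_dir"])
    patient.validate()
    return StudyConfig(patient=patient, protocol=protocol, output_dir=outdir,
                       raw_text=text)
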