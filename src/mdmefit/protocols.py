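"""Acquisition protocol definitions for the MDME saturation-recovery sequence.

An MDME (multi-dynamic multi-echo) acquisition interleaves slice-selective
saturation pulses with fast-spin-echo readouts so that every slice is imaged
at two echo times and four saturation-to-acquisition delays, giving eight
images per slice from which T1, T2, proton density and B1 can be fitted.

This module defines the :class:`AcquisitionProtocol` record (timing, matrix,
acceleration, geometry), validation of its physical constraints, YAML
(de)serialization, and the twelve shipped presets organised as three
parameter families — echo train length (``ETL``), acquisition matrix
(``Matrix``) and parallel-imaging acceleration (``Phase``) — of four
protocols each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "AcquisitionProtocol",
    "ProtocolFamily",
    "DEFAULT_DELAY_FRACTIONS",
    "default_delay_times",
    "load_presets",
    "get_protocol",
    "validate_protocol",
    "voxel_volume_mm3",
    "protocol_to_yaml",
    "protocol_from_yaml",
]

#: Saturation-to-acquisition delays as fractions of TR.  The vendor sequence
#: allows delays to be chosen freely; these fractions span the early, middle
#: and late part of the T1 recovery curve while keeping every delay < TR.
DEFAULT_DELAY_FRACTIONS = (0.07, 0.26, 0.52, 0.87)


def default_delay_times(tr_ms: float) -> tuple[float, ...]:
    """Default 4-delay set for a given repetition time (ms)."""
    return tuple(round(f * tr_ms, 6) for f in DEFAULT_DELAY_FRACTIONS)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One MDME scan-parameter set.

    All times are milliseconds, angles degrees, bandwidth kHz and geometry
    millimetres; conversion to radians happens only inside the signal model.
    """

    name: str
    te1_ms: float
    te2_ms: float
    tr_ms: float
    delay_times_ms: tuple[float, float, float, float]
    etl: int
    matrix_freq: int
    matrix_phase: int
    accel_factor: float = 1.0
    bandwidth_khz: float = 25.0
    fov_mm: float = 240.0
    slice_thickness_mm: float = 4.0
    gap_mm: float = 1.0
    flip_excitation_deg: float = 90.0
    flip_saturation_deg: float = 120.0
    family: str | None = None
    scan_time_s: float | None = None  # metadata only, never computed

    def __post_init__(self) -> None:
        object.__setattr__(self, "delay_times_ms", tuple(float(t) for t in self.delay_times_ms))

    @property
    def echo_times_ms(self) -> tuple[float, float]:
        return (self.te1_ms, self.te2_ms)

    @property
    def pixel_size_mm(self) -> tuple[float, float]:
        return (self.fov_mm / self.matrix_freq, self.fov_mm / self.matrix_phase)


@dataclass(frozen=True)
class ProtocolFamily:
    """A named group of four protocols varying one scan parameter."""

    family: str
    members: tuple[AcquisitionProtocol, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ValueError(
                f"family {self.family!r} must have exactly 4 members, got {len(self.members)}"
            )

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> AcquisitionProtocol:
        return self.members[i]


def validate_protocol(p: AcquisitionProtocol) -> list[str]:
    """Check a protocol against its physical invariants.

    Returns a list of human-readable violation messages; an empty list means
    the protocol is valid.  Nothing is raised so callers can report all
    problems at once.
    """
    v: list[str] = []
    if not (0 < p.te1_ms < p.te2_ms):
        v.append(f"echo times must satisfy 0 < TE1 < TE2 (got {p.te1_ms}, {p.te2_ms})")
    if not (p.te2_ms < p.tr_ms):
        v.append(f"TE2 must be below TR (got TE2={p.te2_ms}, TR={p.tr_ms})")
    delays = p.delay_times_ms
    if len(delays) != 4:
        v.append(f"exactly 4 delay times required (got {len(delays)})")
    else:
        if any(not (0 < d < p.tr_ms) for d in delays):
            v.append(f"each delay time must lie in (0, TR) (got {delays}, TR={p.tr_ms})")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            v.append(f"delay times must be strictly increasing (got {delays})")
    if p.accel_factor < 1.0:
        v.append(f"acceleration factor must be >= 1.0 (got {p.accel_factor})")
    if p.matrix_freq < 8 or p.matrix_phase < 8:
        v.append(f"matrix dimensions must be >= 8 (got {p.matrix_freq}x{p.matrix_phase})")
    if p.etl < 1:
        v.append(f"echo train length must be a positive integer (got {p.etl})")
    for attr in ("tr_ms", "bandwidth_khz", "fov_mm", "slice_thickness_mm"):
        if getattr(p, attr) <= 0:
            v.append(f"{attr} must be positive (got {getattr(p, attr)})")
    if p.gap_mm < 0:
        v.append(f"interslice gap must be non-negative (got {p.gap_mm})")
    if not (0 < p.flip_excitation_deg <= 180 and 0 < p.flip_saturation_deg <= 180):
        v.append("flip angles must lie in (0, 180] degrees")
    return v


def voxel_volume_mm3(p: AcquisitionProtocol) -> float:
    """Nominal acquired voxel volume (mm^3) from FOV, matrix and thickness."""
    if p.matrix_freq <= 0 or p.matrix_phase <= 0:
        raise ValueError("matrix dimensions must be positive")
    dx = p.fov_mm / p.matrix_freq
    dy = p.fov_mm / p.matrix_phase
    return dx * dy * p.slice_thickness_mm


# ---------------------------------------------------------------------------
# serialization

def protocol_to_yaml(p: AcquisitionProtocol) -> str:
    """Serialize one protocol to a YAML document."""
    d = asdict(p)
    d["delay_times_ms"] = list(p.delay_times_ms)
    return yaml.safe_dump(d, sort_keys=False)


def protocol_from_yaml(text_or_mapping) -> AcquisitionProtocol:
    """Parse a protocol from a YAML document string or an already-loaded dict."""
    d = text_or_mapping
    if isinstance(d, str):
        d = yaml.safe_load(d)
    if not isinstance(d, dict):
        raise TypeError("expected a YAML mapping describing a protocol")
    d = dict(d)
    d["delay_times_ms"] = tuple(d["delay_times_ms"])
    return AcquisitionProtocol(**d)


# ---------------------------------------------------------------------------
# presets

_FAMILY_ORDER = ("ETL", "Matrix", "Phase")


def _read_preset_docs() -> list[dict]:
    text = resources.files("mdmefit.data").joinpath("protocols.yaml").read_text()
    return [doc for doc in yaml.safe_load_all(text) if doc]


def load_presets() -> list[ProtocolFamily]:
    """Load the twelve shipped protocol presets as three families.

    The families vary echo train length (ETL1-4), acquisition matrix
    (Matrix1-4) and parallel-imaging acceleration (Phase1-4); shared geometry
    is a 240 mm square FOV, 4 mm slices with a 1 mm gap, 90 deg excitation
    and 120 deg saturation flip angles.
    """
    protos = [protocol_from_yaml(doc) for doc in _read_preset_docs()]
    families = []
    for fam in _FAMILY_ORDER:
        members = tuple(p for p in protos if p.family == fam)
        families.append(ProtocolFamily(family=fam, members=members))
    return families


def get_protocol(name: str) -> AcquisitionProtocol:
    """Look up a preset protocol by name (e.g. ``"ETL1"``, ``"Phase4"``)."""
    for fam in load_presets():
        for p in fam:
            if p.name == name:
                return p
    raise KeyError(f"no preset protocol named {name!r}")
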