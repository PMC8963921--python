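"""Four-link sagittal body model: segment anthropometry and joint damping.

The chain is grounded at the ankle and runs shank -> thigh -> pelvis -> HAT
(head + arms + trunk), connected by the ankle, knee, hip and lumbar joints.
Segment properties default to height/mass-scaled fractions loaded from the
bundled ``defaults/body.yaml`` table and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

SEGMENTS = ("shank", "thigh", "pelvis", "hat")
JOINTS = ("ankle", "knee", "hip", "lumbar")

GRAVITY = 9.81  # m/s^2

#: lumbar viscous dead zone half-width [rad]
LUMBAR_DEAD_ZONE = 0.0314


@dataclass(frozen=True)
class Segment:
    """Rigid segment: geometry and inertia about its own centre of mass."""

    length: float        # m
    mass: float          # kg
    com: float           # distance of COM from the proximal joint, m
    inertia: float       # about COM, kg*m^2

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.mass > 0 and self.inertia > 0):
            raise ValidationError("segment length, mass and inertia must be positive")
        if not 0 < self.com <= self.length:
            raise ValidationError("segment COM must lie within the segment")


@dataclass(frozen=True)
class BodyModel:
    """Anthropometry plus joint viscous coefficients for the four-link chain.

    ``viscous`` holds ``(d_ankle, d_knee, d_hip)`` in N*m*s/rad;
    ``lumbar_extension``/``lumbar_flexion`` are the angular-stiffness-like
    lumbar coefficients in N*m/rad applied outside the dead zone.
    """

    segments: tuple[Segment, Segment, Segment, Segment]
    height: float
    mass: float
    viscous: tuple[float, float, float] = (0.5, 0.5, 0.5)
    lumbar_extension: float = 10.0
    lumbar_flexion: float = 10.0
    hip_contact_fraction: float = 0.5

    def __post_init__(self) -> None:
        if len(self.segments) != 4:
            raise ValidationError("exactly four segments required")
        if self.height <= 0 or self.mass <= 0:
            raise ValidationError("subject height and mass must be positive")
        if sum(s.mass for s in self.segments) > self.mass + 1e-9:
            raise ValidationError("segment masses exceed subject mass")
        if any(d < 0 for d in self.viscous) or self.lumbar_extension < 0 or self.lumbar_flexion < 0:
            raise ValidationError("viscous coefficients must be non-negative")
        if not 0 <= self.hip_contact_fraction <= 1:
            raise ValidationError("hip_contact_fraction must lie in [0, 1]")

    # -- array views used by the dynamics code -------------------------------
    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments])

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.segments])

    @property
    def coms(self) -> np.ndarray:
        return np.array([s.com for s in self.segments])

    @property
    def inertias(self) -> np.ndarray:
        return np.array([s.inertia for s in self.segments])

    @classmethod
    def from_anthropometry(
        cls,
        height: float,
        mass: float,
        table: dict | None = None,
        **overrides,
    ) -> "BodyModel":
        """Build a model by scaling a fraction table by subject height/mass.

        ``table`` defaults to the bundled YAML; pass a dict of the same shape
        to override.  Extra keyword arguments override top-level fields
        (``viscous``, ``lumbar_extension`` ...).
        """
        if table is None:
            table = _load_default_table()
        segs = []
        for name in SEGMENTS:
            row = table["segments"][name]
            length = row["length_fraction"] * height
            seg_mass = row["mass_fraction"] * mass
            com = row["com_fraction"] * length
            rog = row["gyration_fraction"] * length
            segs.append(Segment(length=length, mass=seg_mass, com=com,
                                inertia=seg_mass * rog ** 2))
        visc = table.get("viscous", {})
        kwargs = dict(
            viscous=(visc.get("ankle", 0.5), visc.get("knee", 0.5), visc.get("hip", 0.5)),
            lumbar_extension=visc.get("lumbar_extension", 10.0),
            lumbar_flexion=visc.get("lumbar_flexion", 10.0),
            hip_contact_fraction=table.get("hip_contact_fraction", 0.5),
        )
        kwargs.update(overrides)
        return cls(segments=tuple(segs), height=height, mass=mass, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, height: float, mass: float, **overrides) -> "BodyModel":
        with open(path) as fh:
            table = yaml.safe_load(fh)
        return cls.from_anthropometry(height, mass, table=table, **overrides)

    def with_zero_damping(self) -> "BodyModel":
        """Copy of this model with all viscous coefficients set to zero."""
        return BodyModel(
            segments=self.segments, height=self.height, mass=self.mass,
            viscous=(0.0, 0.0, 0.0), lumbar_extension=0.0, lumbar_flexion=0.0,
            hip_contact_fraction=self.hip_contact_fraction,
        )


def _load_default_table() -> dict:
    with resources.files("stsnorm.defaults").joinpath("body.yaml").open() as fh:
        return yaml.safe_load(fh)
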