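"""Geometry of the hydroxyapatite calibration phantom.

A cylindrical water-equivalent resin body (6.5 cm length and diameter)
holding four parallel cylindrical inserts of uniform HA concentration at
100, 200, 400 and 800 mg/cm3. The phantom axis is the scanner z axis;
insert positions are given in the phantom's own frame (origin on the body
axis at mid-length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["InsertSpec", "PhantomSpec", "default_phantom", "INSERT_DENSITIES"]

INSERT_DENSITIES = (100.0, 200.0, 400.0, 800.0)


@dataclass(frozen=True)
class InsertSpec:
    """One cylindrical HA insert, axis parallel to the phantom axis."""

    density_mg_cm3: float
    center_xy_mm: tuple[float, float]  # offset from the phantom axis
    radius_mm: float = 7.5
    length_mm: float = 60.0

    def __post_init__(self):
        if self.density_mg_cm3 <= 0:
            raise ValueError("insert density must be strictly positive")
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("insert radius and length must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical calibration phantom with four HA inserts."""

    length_mm: float = 65.0
    diameter_mm: float = 65.0
    inserts: tuple[InsertSpec, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.inserts:
            # four quadrants, comfortably inside the body
            offs = [(-16.0, -16.0), (16.0, -16.0), (-16.0, 16.0), (16.0, 16.0)]
            inserts = tuple(
                InsertSpec(d, o) for d, o in zip(INSERT_DENSITIES, offs)
            )
            object.__setattr__(self, "inserts", inserts)
        densities = [ins.density_mg_cm3 for ins in self.inserts]
        if len(set(densities)) != len(densities):
            raise ValueError("insert densities must be distinct")
        r_body = self.diameter_mm / 2.0
        for ins in self.inserts:
            cx, cy = ins.center_xy_mm
            if np.hypot(cx, cy) + ins.radius_mm > r_body:
                raise ValueError(
                    f"insert at {ins.center_xy_mm} does not fit inside the body"
                )
            if ins.length_mm > self.length_mm:
                raise ValueError("insert longer than the phantom body")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def insert_by_density(self, density: float) -> InsertSpec:
        for ins in self.inserts:
            if ins.density_mg_cm3 == density:
                return ins
        raise KeyError(f"no insert with density {density}")


def default_phantom() -> PhantomSpec:
    """The standard four-insert phantom used throughout the package."""
    return PhantomSpec()
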