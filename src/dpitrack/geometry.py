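"""Parameterized internal geometry of a capsule-based dry powder inhaler.

The true internal geometry of an RS01-type device (capsule seat, swirl chamber contours,
grid lattice) is proprietary; only bounding dimensions are measurable from a
disassembled device.  The stand-in used here is two coaxial cylinders — a wide
swirl/capsule chamber and a narrow mouthpiece — joined at a thin perforated
grid plane.  This preserves the three deposition regions relevant to powder
fate accounting (chamber, grid, mouthpiece) while keeping every wall query
analytic.

Conventions
-----------
* z axis along the device axis, origin at the chamber floor, SI units (m)
  internally; configuration files use mm.
* chamber occupies z in [0, grid_z); the grid is a zero-thickness perforated
  plane at z = grid_z; the mouthpiece occupies z in (grid_z, total_height].
* region boundaries are half-open so every axial position maps to exactly one
  region; the grid plane itself classifies as "grid".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import OutOfDomainError, ValidationError

CHAMBER = "chamber"
GRID = "grid"
MOUTHPIECE = "mouthpiece"

#: axial half-width (m) within which a point counts as lying on the grid plane
GRID_PLANE_TOL = 1.0e-12


@dataclass(frozen=True)
class InhalerGeometry:
    """Bounding-dimension model of the inhaler internals.

    Defaults are the measured external dimensions of the device at 60 L/min
    operation: 47.5 mm total height, 28.0 mm maximal width (14.0 mm chamber
    radius), 10.0 mm outlet diameter, 1.5 mm x 6.0 mm tangential inlet, and a
    powder release surface 12 mm above the chamber floor.  The chamber/grid
    split at 25 mm is a free parameter (not published); the grid porosity
    (open-area fraction) defaults to 0.6.
    """

    chamber_radius: float = 14.0e-3
    grid_z: float = 25.0e-3
    total_height: float = 47.5e-3
    outlet_diameter: float = 10.0e-3
    inlet_width: float = 1.5e-3
    inlet_height: float = 6.0e-3
    injection_z: float = 12.0e-3
    grid_porosity: float = 0.6

    def __post_init__(self) -> None:
        positive = (
            "chamber_radius",
            "grid_z",
            "total_height",
            "outlet_diameter",
            "inlet_width",
            "inlet_height",
            "injection_z",
        )
        for name in positive:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(f"geometry field {name!r} must be positive, got {value!r}")
        if not self.grid_z < self.total_height:
            raise ValidationError(
                f"grid_z ({self.grid_z}) must lie strictly below total_height ({self.total_height})"
            )
        if self.outlet_diameter / 2.0 > self.chamber_radius:
            raise ValidationError("mouthpiece_radius cannot exceed chamber_radius")
        if not self.injection_z < self.grid_z:
            raise ValidationError(
                f"injection_z ({self.injection_z}) must lie inside the chamber (< grid_z)"
            )
        if not 0.0 <= self.grid_porosity <= 1.0:
            raise ValidationError(f"grid_porosity must be in [0, 1], got {self.grid_porosity}")

    @property
    def mouthpiece_radius(self) -> float:
        return self.outlet_diameter / 2.0

    @property
    def chamber_height(self) -> float:
        return self.grid_z

    @property
    def mouthpiece_length(self) -> float:
        return self.total_height - self.grid_z

    @property
    def max_width(self) -> float:
        return 2.0 * self.chamber_radius

    def radius_at(self, z: float) -> float:
        """Wall radius of the region containing axial position ``z``."""
        if z < self.grid_z:
            return self.chamber_radius
        if abs(z - self.grid_z) <= GRID_PLANE_TOL:
            return self.chamber_radius
        return self.mouthpiece_radius


#: geometry fields interpreted as lengths in mm when read from a config file
_MM_FIELDS = (
    "chamber_radius",
    "grid_z",
    "total_height",
    "outlet_diameter",
    "inlet_width",
    "inlet_height",
    "injection_z",
)


def build_geometry(config: dict | None = None) -> InhalerGeometry:
    """Build an :class:`InhalerGeometry` from a config-style parameter set.

    ``config`` keys mirror the dataclass fields; length values are in mm
    (the configuration-file convention) and are converted to m internally.
    ``grid_porosity`` is dimensionless.  Unknown keys are rejected.
    """
    config = dict(config or {})
    kwargs: dict[str, float] = {}
    for key in list(config):
        value = config.pop(key)
        if key in _MM_FIELDS:
            kwargs[key] = float(value) * 1.0e-3
        elif key == "grid_porosity":
            kwargs[key] = float(value)
        else:
            raise ValidationError(f"unknown geometry parameter {key!r}")
    return InhalerGeometry(**kwargs)


def _radial(position: np.ndarray) -> float:
    return math.hypot(float(position[0]), float(position[1]))


def _check_in_domain(geometry: InhalerGeometry, position: np.ndarray) -> tuple[float, float]:
    z = float(position[2])
    r = _radial(position)
    if z < -GRID_PLANE_TOL or z > geometry.total_height + GRID_PLANE_TOL:
        raise OutOfDomainError(f"axial position z={z} outside [0, {geometry.total_height}]")
    wall_r = geometry.radius_at(z)
    if r > wall_r * (1.0 + 1e-12) + GRID_PLANE_TOL:
        raise OutOfDomainError(f"radius r={r} exceeds wall radius {wall_r} at z={z}")
    return r, z


def region_of(geometry: InhalerGeometry, position) -> str:
    """Classify a position into the chamber, grid, or mouthpiece region.

    The grid plane (z == grid_z, to within 1e-12 m) belongs to the grid
    region; below is chamber, above is mouthpiece.
    """
    position = np.asarray(position, dtype=float)
    _, z = _check_in_domain(geometry, position)
    if abs(z - geometry.grid_z) <= GRID_PLANE_TOL:
        return GRID
    if z < geometry.grid_z:
        return CHAMBER
    return MOUTHPIECE


def wall_query(geometry: InhalerGeometry, position) -> tuple[float, np.ndarray, str]:
    """Distance to the nearest lateral wall, its inward unit normal, region.

    The query considers the cylindrical side wall of the region containing
    the point (the impact surface relevant to the sticking criterion); the
    grid plane and floor are handled as crossing events by the tracker.  On
    the axis the nearest-wall direction is degenerate and the +x wall point
    is chosen by convention.
    """
    position = np.asarray(position, dtype=float)
    r, z = _check_in_domain(geometry, position)
    region = region_of(geometry, position)
    wall_r = geometry.chamber_radius if region in (CHAMBER, GRID) else geometry.mouthpiece_radius
    if r < 1e-15:
        normal = np.array([-1.0, 0.0, 0.0])
    else:
        normal = np.array([-position[0] / r, -position[1] / r, 0.0])
    distance = max(wall_r - r, 0.0)
    return distance, normal, region
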