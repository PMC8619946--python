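"""Steady velocity-field providers for the inhaler interior.

The airflow through the device is treated as a steady incompressible field
supplied by a pluggable provider.  Three providers are available:

* :func:`analytic_swirl_field` — a closed-form stand-in for the converging
  swirling flow at the 60 L/min operating point.  The axial/radial part is
  built from an axisymmetric stream function, so continuity is satisfied
  exactly and the axial flux through every cross-section equals the
  prescribed volumetric flow Q.
* :func:`load_gridded_field` — nearest/trilinear interpolation of an
  externally computed field sampled on a structured point lattice (CSV).
* :func:`uniform_field` — a constant field, mainly a test fixture.

All providers are steady by construction: repeated queries at the same
position return bitwise-identical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import OutOfDomainError, ParseError, ValidationError
from .geometry import InhalerGeometry


class FlowField:
    """Base class: a steady velocity field u(x) with optional gradient.

    Subclasses implement :meth:`velocity`.  The velocity gradient defaults to
    central finite differences on the exact field (step 1e-7 m), which is
    accurate to ~1e-7 1/s for the smooth analytic fields used here; gridded
    fields override it with lattice differences.
    """

    #: volumetric flow metadata (m^3/s); None when not applicable
    volumetric_flow: float | None = None

    def velocity(self, position) -> np.ndarray:
        raise NotImplementedError

    def velocity_gradient(self, position, h: float = 1.0e-7) -> np.ndarray:
        """3x3 tensor G[i, j] = du_i/dx_j by central differences."""
        position = np.asarray(position, dtype=float)
        grad = np.empty((3, 3))
        for j in range(3):
            dp = np.zeros(3)
            dp[j] = h
            grad[:, j] = (self.velocity(position + dp) - self.velocity(position - dp)) / (2.0 * h)
        return grad


LPM_TO_M3S = 1.0e-3 / 60.0  # 1 L/min in m^3/s


def _smoothstep(s: float) -> float:
    return s * s * (3.0 - 2.0 * s)


def _smoothstep_deriv(s: float) -> float:
    return 6.0 * s * (1.0 - s)


@dataclass(frozen=True)
class AnalyticSwirlField(FlowField):
    """Closed-form converging swirl flow for the two-cylinder geometry.

    The through-flow is a Poiseuille-profile stream tube whose radius equals
    the chamber radius low in the chamber and contracts smoothly (cubic
    smoothstep) to the mouthpiece radius over the top ``convergence_fraction``
    of the chamber, then stays at the mouthpiece radius.  Outside the tube
    (the chamber shoulder below the grid annulus) the fluid is quiescent.
    Built from the stream function psi = (Q/2pi) * eta * (2 - eta) with
    eta = (r/R(z))^2, so the axial flux through any cross-section is exactly
    Q and the wall-normal velocity vanishes at every wall.

    A solid-body-rotation swirl u_theta = S * U_ch * (r/R_c) * (1 - z/grid_z)
    is superimposed in the chamber (S = swirl number, U_ch = chamber plug
    speed), decaying to zero at the grid plane, emulating the tangential-inlet
    swirl that carries powder toward the axis and out of the device.
    """

    geometry: InhalerGeometry
    Q: float
    swirl_number: float = 2.0
    convergence_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not (math.isfinite(self.Q) and self.Q > 0):
            raise ValidationError(f"volumetric flow Q must be positive, got {self.Q}")
        if not 0.0 < self.convergence_fraction < 1.0:
            raise ValidationError("convergence_fraction must be in (0, 1)")
        object.__setattr__(self, "volumetric_flow", self.Q)

    # -- geometry of the converging core ------------------------------------
    def _core_radius(self, z: float) -> tuple[float, float]:
        """Stream-tube radius R(z) and its derivative dR/dz."""
        g = self.geometry
        z0 = g.grid_z * (1.0 - self.convergence_fraction)
        if z <= z0:
            return g.chamber_radius, 0.0
        if z >= g.grid_z:
            return g.mouthpiece_radius, 0.0
        s = (z - z0) / (g.grid_z - z0)
        dr = g.mouthpiece_radius - g.chamber_radius
        radius = g.chamber_radius + dr * _smoothstep(s)
        slope = dr * _smoothstep_deriv(s) / (g.grid_z - z0)
        return radius, slope

    def velocity(self, position) -> np.ndarray:
        position = np.asarray(position, dtype=float)
        x, y, z = float(position[0]), float(position[1]), float(position[2])
        g = self.geometry
        r = math.hypot(x, y)
        core_r, core_slope = self._core_radius(z)

        u_z = 0.0
        u_r = 0.0
        if r < core_r:
            eta = (r / core_r) ** 2
            u_z = (2.0 * self.Q / (math.pi * core_r * core_r)) * (1.0 - eta)
            u_r = (2.0 * self.Q / math.pi) * (1.0 - eta) * r * core_slope / core_r**3

        u_t = 0.0
        if z < g.grid_z and self.swirl_number != 0.0:
            plug_speed = self.Q / (math.pi * g.chamber_radius**2)
            u_t = (
                self.swirl_number
                * plug_speed
                * (r / g.chamber_radius)
                * (1.0 - z / g.grid_z)
            )

        if r > 1e-15:
            cx, cy = x / r, y / r
        else:
            cx, cy = 1.0, 0.0
        return np.array([u_r * cx - u_t * cy, u_r * cy + u_t * cx, u_z])

    def mean_outlet_speed(self) -> float:
        """Cross-section-averaged axial speed at the outlet, Q / (pi r^2)."""
        return self.Q / (math.pi * self.geometry.mouthpiece_radius**2)

    def axial_flux(self, z: float, n_r: int = 2000) -> float:
        """Numerical quadrature of the axial flux through the plane at z."""
        wall_r = self.geometry.radius_at(z)
        radii = np.linspace(0.0, wall_r, n_r)
        u_z = np.array([self.velocity((rr, 0.0, z))[2] for rr in radii])
        return float(np.trapezoid(u_z * 2.0 * math.pi * radii, radii))


def analytic_swirl_field(
    geometry: InhalerGeometry,
    Q: float,
    swirl_number: float = 2.0,
    convergence_fraction: float = 0.4,
) -> AnalyticSwirlField:
    """Build the analytic stand-in field for volumetric flow ``Q`` (m^3/s)."""
    return AnalyticSwirlField(geometry, Q, swirl_number, convergence_fraction)


@dataclass(frozen=True)
class UniformField(FlowField):
    """Spatially constant velocity; gradient identically zero."""

    vector: tuple[float, float, float]

    def velocity(self, position) -> np.ndarray:  # noqa: ARG002 - uniform
        return np.array(self.vector, dtype=float)

    def velocity_gradient(self, position, h: float = 1.0e-7) -> np.ndarray:  # noqa: ARG002
        return np.zeros((3, 3))


def uniform_field(speed: float, direction) -> UniformField:
    """Constant field with magnitude ``speed`` along ``direction``.

    ``speed`` may be zero (quiescent air); the direction vector must be
    non-zero so the orientation is well defined.
    """
    direction = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(direction))
    if norm <= 0.0 or not math.isfinite(norm):
        raise ValidationError("direction vector must be non-zero")
    vec = direction / norm * float(speed)
    return UniformField(tuple(float(v) for v in vec))


class GriddedField(FlowField):
    """Velocity field interpolated from a structured point lattice."""

    def __init__(self, xs, ys, zs, u, v, w, method: str):
        self._axes = (np.asarray(xs, float), np.asarray(ys, float), np.asarray(zs, float))
        self._interp = [
            RegularGridInterpolator(self._axes, comp, method=method, bounds_error=True)
            for comp in (u, v, w)
        ]
        # component gradients tabulated on the lattice by central differences
        grads = []
        for comp in (u, v, w):
            g = np.gradient(comp, *self._axes, edge_order=1)
            grads.append(
                [
                    RegularGridInterpolator(self._axes, gj, method=method, bounds_error=True)
                    for gj in g
                ]
            )
        self._grad_interp = grads
        self.volumetric_flow = None

    def _query(self, interp, position):
        try:
            return float(interp(np.asarray(position, float))[0])
        except ValueError as exc:
            raise OutOfDomainError(f"query {position} outside the lattice hull") from exc

    def velocity(self, position) -> np.ndarray:
        return np.array([self._query(i, position) for i in self._interp])

    def velocity_gradient(self, position, h: float = 1.0e-7) -> np.ndarray:  # noqa: ARG002
        return np.array(
            [[self._query(self._grad_interp[i][j], position) for j in range(3)] for i in range(3)]
        )


def load_gridded_field(path, interpolation: str = "trilinear") -> GriddedField:
    """Load a steady field from a CSV with header ``x,y,z,u,v,w`` (SI units).

    Points must form a full structured lattice (every combination of the
    unique x, y, z values present exactly once, >= 2 values per axis).
    ``interpolation`` selects ``nearest`` or ``trilinear`` queries; queries
    outside the lattice hull raise :class:`OutOfDomainError`.
    """
    methods = {"nearest": "nearest", "trilinear": "linear"}
    if interpolation not in methods:
        raise ValidationError(
            f"interpolation must be one of {sorted(methods)}, got {interpolation!r}"
        )
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, OSError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot read gridded field {path}: {exc}") from exc
    required = ["x", "y", "z", "u", "v", "w"]
    if list(df.columns[: len(required)]) != required:
        raise ParseError(f"{path}: expected columns {required}, found {list(df.columns)}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: malformed or missing values at line {line}")

    xs = np.unique(df["x"].to_numpy())
    ys = np.unique(df["y"].to_numpy())
    zs = np.unique(df["z"].to_numpy())
    if min(len(xs), len(ys), len(zs)) < 2:
        raise ParseError(f"{path}: lattice needs at least 2 distinct values per axis")
    if len(df) != len(xs) * len(ys) * len(zs):
        raise ParseError(
            f"{path}: {len(df)} points do not form a {len(xs)}x{len(ys)}x{len(zs)} lattice"
        )
    df = df.sort_values(["x", "y", "z"], kind="mergesort")
    shape = (len(xs), len(ys), len(zs))
    expected = pd.MultiIndex.from_product([xs, ys, zs])
    actual = pd.MultiIndex.from_frame(df[["x", "y", "z"]])
    if not expected.equals(actual):
        raise ParseError(f"{path}: points are not a complete structured lattice")
    u = df["u"].to_numpy().reshape(shape)
    v = df["v"].to_numpy().reshape(shape)
    w = df["w"].to_numpy().reshape(shape)
    return GriddedField(xs, ys, zs, u, v, w, methods[interpolation])
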