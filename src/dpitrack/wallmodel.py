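"""Particle-wall interaction physics: capture-velocity sticking and
rolling/sliding detachment.

Sticking follows the capture-velocity criterion for impacting spheres: a
particle whose wall-normal impact speed v_n falls below a critical capture
velocity v_cr adheres; above it the particle rebounds with reduced normal
velocity.  The capture velocity is

    v_cr = (2 E / d_p)^(10/7)

with the El Batch parameter

    E = 0.51 * [5 pi^2 (k1 + k2) / (4 rho_p^(3/2))]^(2/5),
    k1 = (1 - v_s^2) / (pi E_s),   k2 = (1 - v_p^2) / (pi E_p),

where E_s, E_p are the Young's moduli and v_s, v_p the Poisson ratios of the
wall and particle materials.  v_cr decreases steeply with particle size:
small particles stick on almost any impact, large ones bounce.

A deposited particle is re-entrained when aerodynamic forces overcome
adhesion, either by rolling (moment balance about the contact rim)

    F_D (d_p/2 - b) + F_L a >= F_st a

or by sliding (force balance against static friction)

    F_D >= k_s F_st.

The adhesion force F_st, contact half-width a and normal flattening b follow
JKR adhesion mechanics from the tabulated work of adhesion; the drag on the
attached particle is Stokes drag with a near-wall correction factor f and
the lift is a Saffman-type shear lift (switchable off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

STICK = "stick"
BOUNCE = "bounce"

REMAINS_STUCK = "remains_stuck"
ROLLS = "rolls"
SLIDES = "slides"


@dataclass(frozen=True)
class MaterialParams:
    """Wall/particle mechanics and air constants.

    Defaults are the tabulated constants of the sticking model: polycarbonate
    device wall (E_s = 4.1 GPa, v_s = 0.35) against a lipid-matrix particle
    (E_p = 1 GPa, v_p = 0.40), work of adhesion W_A = 0.039 J/m^2, static
    friction k_s = 0.50, near-wall drag correction f = 1.70, Cunningham
    factor C_u = 1 (spheres), air viscosity 1.7894e-5 Pa s and density
    1.225 kg/m^3 at ambient conditions.  ``e_n`` (normal restitution of a
    rebounding particle) and ``lift_enabled`` are model parameters of this
    package, not tabulated constants.
    """

    E_s: float = 4.1e9  # Pa
    E_p: float = 1.0e9  # Pa
    v_s: float = 0.35
    v_p: float = 0.40
    W_A: float = 0.039  # J/m^2
    k_s: float = 0.50
    f: float = 1.70
    C_u: float = 1.0
    mu: float = 1.7894e-5  # Pa s
    rho_air: float = 1.225  # kg/m^3
    e_n: float = 0.8
    lift_enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.E_s, self.E_p) <= 0:
            raise ValidationError("Young's moduli must be positive")
        for name in ("v_s", "v_p"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ValidationError(f"Poisson ratio {name} must lie in [0, 0.5), got {v}")
        if self.W_A < 0:
            raise ValidationError("work of adhesion cannot be negative")
        if min(self.k_s, self.f, self.C_u, self.mu, self.rho_air) <= 0:
            raise ValidationError("k_s, f, C_u, mu, rho_air must be positive")
        if not 0.0 < self.e_n <= 1.0:
            raise ValidationError(f"normal restitution must lie in (0, 1], got {self.e_n}")

    def with_overrides(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ImpactEvent:
    """One particle-wall impact and its resolution."""

    particle_id: int
    position: tuple[float, float, float]
    region: str
    v_n: float  # normal impact speed, m/s
    v_cr: float  # capture velocity for this particle, m/s
    outcome: str  # STICK or BOUNCE

    def __post_init__(self) -> None:
        if self.v_n < 0:
            raise ValidationError("normal impact speed cannot be negative")
        expected = STICK if self.v_n <= self.v_cr else BOUNCE
        if self.outcome != expected:
            raise ValidationError(
                f"outcome {self.outcome!r} inconsistent with v_n={self.v_n}, v_cr={self.v_cr}"
            )


@dataclass(frozen=True)
class DetachmentForces:
    """Force system acting on a wall-attached particle (SI units)."""

    F_D: float  # drag, N
    F_L: float  # lift, N
    F_st: float  # adhesion, N
    a: float  # contact half-width along the surface, m
    b: float  # normal flattening of the particle, m


def _elastic_compliances(materials: MaterialParams) -> tuple[float, float]:
    k1 = (1.0 - materials.v_s**2) / (math.pi * materials.E_s)
    k2 = (1.0 - materials.v_p**2) / (math.pi * materials.E_p)
    return k1, k2


def el_batch_parameter(materials: MaterialParams, rho_p: float) -> float:
    """El Batch parameter E of the capture-velocity law.

    E = 0.51 * [5 pi^2 (k1 + k2) / (4 rho_p^(3/2))]^(2/5); depends on the
    elastic pairing and the particle density but not on particle size.
    """
    if rho_p <= 0:
        raise ValidationError(f"particle density must be positive, got {rho_p}")
    k1, k2 = _elastic_compliances(materials)
    return 0.51 * (5.0 * math.pi**2 * (k1 + k2) / (4.0 * rho_p**1.5)) ** 0.4


def capture_velocity(d_p: float, rho_p: float, materials: MaterialParams) -> float:
    """Capture velocity v_cr = (2E/d_p)^(10/7) (m/s); decreasing in d_p."""
    if d_p <= 0:
        raise ValidationError(f"particle diameter must be positive, got {d_p}")
    E = el_batch_parameter(materials, rho_p)
    return (2.0 * E / d_p) ** (10.0 / 7.0)


def impact_outcome(
    v_impact,
    wall_normal,
    v_cr: float,
    e_n: float,
    particle_id: int = -1,
    position=(0.0, 0.0, 0.0),
    region: str = "",
) -> tuple[ImpactEvent, np.ndarray]:
    """Resolve an impact: stick (v_n <= v_cr) or bounce (v_n > v_cr).

    ``wall_normal`` must be the inward (into-fluid) unit normal.  On a stick
    the returned velocity is zero; on a bounce the normal component is
    reversed and scaled by the restitution ``e_n`` while the tangential
    component is preserved.  The equality tie-break deposits the particle
    (sticking is the conservative resolution of the published strict
    inequalities).
    """
    v_impact = np.asarray(v_impact, dtype=float)
    normal = np.asarray(wall_normal, dtype=float)
    if abs(float(np.linalg.norm(normal)) - 1.0) > 1e-9:
        raise ValidationError("wall normal must have unit length")
    v_normal_signed = float(np.dot(v_impact, normal))  # negative when incoming
    v_n = max(0.0, -v_normal_signed)
    if v_n <= v_cr:
        event = ImpactEvent(particle_id, tuple(position), region, v_n, v_cr, STICK)
        return event, np.zeros(3)
    v_out = v_impact - (1.0 + e_n) * v_normal_signed * normal
    event = ImpactEvent(particle_id, tuple(position), region, v_n, v_cr, BOUNCE)
    return event, v_out


def adhesion_force(d_p: float, W_A: float) -> float:
    """JKR pull-off adhesion force F_st = (3/4) pi W_A d_p (N)."""
    if d_p <= 0:
        raise ValidationError(f"particle diameter must be positive, got {d_p}")
    if W_A < 0:
        raise ValidationError("work of adhesion cannot be negative")
    return 0.75 * math.pi * W_A * d_p


def wall_drag_force(d_p: float, u_rel: float, materials: MaterialParams) -> float:
    """Near-wall drag F_D = 3 pi mu d_p u_rel f / C_u (N).

    ``u_rel`` is the magnitude of the fluid velocity relative to the attached
    particle, evaluated one particle radius from the wall; ``f`` is the
    near-wall correction to free-stream Stokes drag.
    """
    if d_p <= 0:
        raise ValidationError(f"particle diameter must be positive, got {d_p}")
    if u_rel < 0:
        raise ValidationError("relative speed cannot be negative")
    return 3.0 * math.pi * materials.mu * d_p * u_rel * materials.f / materials.C_u


def wall_lift_force(
    d_p: float, u_rel: float, shear_rate: float, materials: MaterialParams
) -> float:
    """Saffman-type shear lift F_L = 1.615 mu d_p^2 u_rel sqrt(rho G / mu) (N).

    G is the near-wall shear rate; returns 0 when lift is disabled in the
    material configuration or the shear vanishes.
    """
    if shear_rate < 0:
        raise ValidationError("shear rate cannot be negative")
    if u_rel < 0:
        raise ValidationError("relative speed cannot be negative")
    if not materials.lift_enabled:
        return 0.0
    return (
        1.615
        * materials.mu
        * d_p**2
        * u_rel
        * math.sqrt(materials.rho_air * shear_rate / materials.mu)
    )


def contact_geometry(d_p: float, materials: MaterialParams) -> tuple[float, float]:
    """JKR contact dimensions of an adhering sphere: (a, b) in m.

    a = [9 pi W_A (d_p/2)^2 / (2K)]^(1/3) with the composite stiffness
    K = (4/3) / [(1 - v_s^2)/E_s + (1 - v_p^2)/E_p]; the normal flattening
    is the chordal relation b = a^2 / d_p.  Degenerate contacts
    (b >= d_p/2, impossible for physical elastic inputs) are rejected.
    """
    if d_p <= 0:
        raise ValidationError(f"particle diameter must be positive, got {d_p}")
    compliance = (1.0 - materials.v_s**2) / materials.E_s + (
        1.0 - materials.v_p**2
    ) / materials.E_p
    K = (4.0 / 3.0) / compliance
    a = (9.0 * math.pi * materials.W_A * (d_p / 2.0) ** 2 / (2.0 * K)) ** (1.0 / 3.0)
    b = a * a / d_p
    if b >= d_p / 2.0:
        raise ValidationError(
            f"degenerate contact: flattening b={b} not below particle radius {d_p / 2.0}"
        )
    return a, b


def detachment_mode(forces: DetachmentForces, d_p: float, k_s: float) -> str:
    """Classify a stuck particle as remaining stuck, rolling, or sliding.

    Rolling: moment balance F_D (d_p/2 - b) + F_L a >= F_st a.
    Sliding: F_D >= k_s F_st.  When both inequalities hold the particle is
    reported as rolling, the more easily triggered mechanism for spheres.
    Both boundaries are inclusive (detachment at exact equality).
    """
    if d_p <= 0:
        raise ValidationError(f"particle diameter must be positive, got {d_p}")
    rolling = forces.F_D * (d_p / 2.0 - forces.b) + forces.F_L * forces.a >= forces.F_st * forces.a
    sliding = forces.F_D >= k_s * forces.F_st
    if rolling:
        return ROLLS
    if sliding:
        return SLIDES
    return REMAINS_STUCK


def evaluate_detachment(
    d_p: float,
    u_rel: float,
    shear_rate: float,
    materials: MaterialParams,
) -> tuple[str, DetachmentForces]:
    """Assemble the force system for a stuck particle and classify it.

    ``u_rel`` and ``shear_rate`` are the wall-tangential fluid speed and the
    shear rate evaluated one particle radius from the wall.
    """
    a, b = contact_geometry(d_p, materials)
    forces = DetachmentForces(
        F_D=wall_drag_force(d_p, u_rel, materials),
        F_L=wall_lift_force(d_p, u_rel, shear_rate, materials),
        F_st=adhesion_force(d_p, materials.W_A),
        a=a,
        b=b,
    )
    return detachment_mode(forces, d_p, materials.k_s), forces
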