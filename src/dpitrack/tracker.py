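"""Lagrangian tracking of powder particles through a steady flow field.

Each particle obeys Stokes-drag relaxation toward the local fluid velocity,

    dv/dt = (u - v) / tau  (+ g),    tau = rho_p d_p^2 C_u / (18 mu),

integrated with the exact exponential update over each step, which is
unconditionally stable even when dt >> tau (small particles simply follow
the fluid).  Wall impacts are located geometrically as the first boundary
crossing of each straight sub-step and resolved by the capture-velocity
criterion; particles that stick are immediately re-tested for rolling or
sliding detachment against the local near-wall flow (the field is steady,
so the detachment inequality never changes afterwards).

A particle's life ends in one of three ways, tallied exactly: it is emitted
through the outlet, it remains permanently stuck on a wall, or it is still
airborne when the simulated time budget runs out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wallmodel
from .errors import NumericalError, ValidationError
from .flowfield import FlowField
from .geometry import CHAMBER, GRID, MOUTHPIECE, InhalerGeometry
from .particles import (
    EMITTED,
    IN_FLIGHT,
    STUCK,
    TIMED_OUT,
    FormulationRecord,
    ParticleState,
    aerodynamic_diameter,
    fit_rosin_rammler,
    relaxation_time,
    sample_diameters,
)
from .wallmodel import REMAINS_STUCK, MaterialParams

GRAVITY = np.array([0.0, 0.0, -9.80665])

#: maximum particle displacement per step (m) — geometric CFL cap
CFL_DISPLACEMENT = 0.2e-3
#: lower bound on the step (s); below this the exponential update already
#: locks the particle to the fluid and smaller steps only add cost
DT_FLOOR = 1.0e-6
#: wall offset (m) applied when re-seeding a bounced/detached particle
WALL_EPS = 1.0e-9

NUMBER = "number"
MASS = "mass"


@dataclass(frozen=True)
class FateRecord:
    """Terminal bookkeeping for one tracked particle."""

    particle_id: int
    d_g_um: float
    d_ae_um: float
    mass_kg: float
    n_impacts: int
    stuck_ever: bool
    n_detachments: int
    final_status: str
    final_region: str | None = None
    z_stick_m: float | None = None
    exit_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.final_status == STUCK and not self.stuck_ever:
            raise ValidationError("a permanently stuck particle must have stuck_ever set")
        if self.n_detachments > self.n_impacts:
            raise ValidationError("detachments cannot outnumber impacts")


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregate fate fractions under one weighting (percent of injected)."""

    weighting: str
    n_particles: int
    fraction_impacted: float
    fraction_stuck_ever: float
    fraction_permanently_stuck: float
    detached_to_stuck_ratio: float
    emitted_fraction: float
    fraction_timed_out: float
    region_fractions: dict[str, float]  # % of deposited weight by region

    def __post_init__(self) -> None:
        total = self.emitted_fraction + self.fraction_permanently_stuck + self.fraction_timed_out
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(f"fate fractions must sum to 100%, got {total}")


def step_particle(
    state: ParticleState,
    fluid_velocity: np.ndarray,
    dt: float,
    materials: MaterialParams,
    gravity_on: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one particle by ``dt`` through a locally frozen fluid velocity.

    Returns (new_position, new_velocity) from the closed-form solution of the
    linear relaxation equation:

        v(dt) = u* + (v0 - u*) exp(-dt/tau),
        x(dt) = x0 + u* dt + (v0 - u*) tau (1 - exp(-dt/tau)),

    where u* = u + g tau is the drift velocity (terminal-settling-shifted
    when gravity is on).  The state itself is not mutated.
    """
    if dt <= 0:
        raise ValidationError(f"time step must be positive, got {dt}")
    if state.status != IN_FLIGHT:
        raise ValidationError(f"cannot step a particle with status {state.status!r}")
    tau = relaxation_time(state.d_p, state.rho_p, materials.mu, materials.C_u)
    u_star = np.asarray(fluid_velocity, dtype=float)
    if gravity_on:
        u_star = u_star + GRAVITY * tau
    decay = math.exp(-dt / tau)
    slip = state.velocity - u_star
    new_v = u_star + slip * decay
    new_x = state.position + u_star * dt + slip * tau * (1.0 - decay)
    return new_x, new_v


@dataclass(frozen=True)
class Collision:
    """First boundary event along a straight sub-step."""

    kind: str  # "wall" or "emitted"
    s: float  # fraction of the segment travelled at the event
    point: np.ndarray
    normal: np.ndarray | None  # inward unit normal (wall events)
    region: str | None


def _radial_crossing(p0, d, radius) -> float | None:
    """Smallest s in (0, 1] with |p0_xy + s d_xy| = radius, else None."""
    a = d[0] * d[0] + d[1] * d[1]
    if a <= 0.0:
        return None
    b = 2.0 * (p0[0] * d[0] + p0[1] * d[1])
    c = p0[0] * p0[0] + p0[1] * p0[1] - radius * radius
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return None
    sq = math.sqrt(disc)
    for root in ((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)):
        if 1e-12 < root <= 1.0:
            return root
    return None


def detect_wall_collision(
    prev_position,
    new_position,
    geometry: InhalerGeometry,
    rng: np.random.Generator,
) -> Collision | None:
    """First boundary crossing along the segment prev -> new, if any.

    Candidate events: the cylindrical side wall of the current region, the
    chamber floor, the grid plane, and the outlet plane.  A grid-plane
    crossing inside the open area (r < mouthpiece radius) impacts the grid
    lattice with probability (1 - porosity), drawn from ``rng``; crossings
    over the annular shoulder always impact.  Passing through the grid hands
    the remaining sub-segment to the other region's wall checks.
    """
    p0 = np.asarray(prev_position, dtype=float)
    p1 = np.asarray(new_position, dtype=float)
    d = p1 - p0
    consumed = 0.0

    for _ in range(4):  # a straight segment can pass the grid plane at most once per region flip
        z0 = p0[2]
        in_chamber = z0 < geometry.grid_z
        side_radius = geometry.chamber_radius if in_chamber else geometry.mouthpiece_radius
        events: list[tuple[float, str]] = []

        s_side = _radial_crossing(p0, d, side_radius)
        if s_side is not None:
            events.append((s_side, "side"))
        if d[2] != 0.0:
            s_grid = (geometry.grid_z - z0) / d[2]
            if 1e-12 < s_grid <= 1.0:
                events.append((s_grid, "grid"))
            if in_chamber:
                s_floor = (0.0 - z0) / d[2]
                if 1e-12 < s_floor <= 1.0:
                    events.append((s_floor, "floor"))
            else:
                s_out = (geometry.total_height - z0) / d[2]
                if 1e-12 < s_out <= 1.0:
                    events.append((s_out, "outlet"))
        if not events:
            return None
        s_event, kind = min(events)
        point = p0 + s_event * d
        s_total = consumed + s_event * (1.0 - consumed)

        if kind == "side":
            r = math.hypot(point[0], point[1])
            normal = np.array([-point[0] / r, -point[1] / r, 0.0])
            region = CHAMBER if in_chamber else MOUTHPIECE
            return Collision("wall", s_total, point, normal, region)
        if kind == "floor":
            return Collision("wall", s_total, point, np.array([0.0, 0.0, 1.0]), CHAMBER)
        if kind == "outlet":
            return Collision("emitted", s_total, point, None, None)

        # grid-plane crossing
        point[2] = geometry.grid_z
        r = math.hypot(point[0], point[1])
        into_fluid = np.array([0.0, 0.0, -math.copysign(1.0, d[2])])
        if r >= geometry.mouthpiece_radius or rng.random() >= geometry.grid_porosity:
            return Collision("wall", s_total, point, into_fluid, GRID)
        # porous pass: continue with the remaining sub-segment on the far side
        p0 = point + np.array([0.0, 0.0, math.copysign(1e-12, d[2])])
        d = p1 - p0
        consumed = s_total
        if np.dot(d, d) == 0.0:
            return None
    return None


def _near_wall_conditions(
    field_: FlowField, hit_point: np.ndarray, normal: np.ndarray, d_p: float
) -> tuple[np.ndarray, float, float]:
    """Fluid state one particle radius off the wall: probe point, tangential
    speed, and shear rate |d u_t / d n|."""
    probe = hit_point + normal * (d_p / 2.0)
    u = field_.velocity(probe)
    u_tan = u - np.dot(u, normal) * normal
    grad = field_.velocity_gradient(probe)
    dudn = grad @ normal
    dudn_tan = dudn - np.dot(dudn, normal) * normal
    return probe, float(np.linalg.norm(u_tan)), float(np.linalg.norm(dudn_tan))


@dataclass
class _Track:
    """Per-particle mutable counters used during a run."""

    n_impacts: int = 0
    n_detachments: int = 0
    stuck_ever: bool = False


def run_simulation(
    formulation: FormulationRecord,
    geometry: InhalerGeometry,
    field_: FlowField,
    n_particles: int,
    seed,
    materials: MaterialParams | None = None,
    gravity_on: bool = False,
    max_time: float = 0.5,
    max_steps_per_particle: int = 400_000,
    collect_impacts: bool = False,
    cfl_displacement: float = CFL_DISPLACEMENT,
    dt_floor: float = DT_FLOOR,
) -> tuple[list[FateRecord], list[wallmodel.ImpactEvent]]:
    """Track ``n_particles`` of one formulation through the device.

    Particles are injected at z = injection_z, uniformly over the chamber
    cross-section, with initial velocity equal to the local fluid velocity
    and diameters drawn from the Rosin-Rammler law fitted to the
    formulation's volume quantiles.  Each particle is tracked until it is
    emitted through the outlet, permanently stuck, or ``max_time`` (s) of
    simulated steady flow has elapsed.  The run is deterministic for a fixed
    seed, and the three terminal fates always partition the injected count.

    Returns the fate records and (optionally) the logged impact events.
    """
    if n_particles < 1:
        raise ValidationError(f"need at least one particle, got {n_particles}")
    if seed is None:
        raise ValidationError("a seed is mandatory for simulation runs")
    materials = materials or MaterialParams()
    rng = np.random.default_rng(seed)

    rr = fit_rosin_rammler(formulation.d_v10, formulation.d_v50, formulation.d_v90)
    diameters_um = sample_diameters(rr, n_particles, rng)
    rho_p = formulation.density_kg_m3
    # uniform over the injection cross-section area
    inj_radius = geometry.chamber_radius
    radii = inj_radius * np.sqrt(rng.uniform(size=n_particles))
    angles = rng.uniform(0.0, 2.0 * math.pi, size=n_particles)

    records: list[FateRecord] = []
    impacts_log: list[wallmodel.ImpactEvent] = []

    for pid in range(n_particles):
        d_p = float(diameters_um[pid]) * 1e-6
        position = np.array(
            [
                radii[pid] * math.cos(angles[pid]),
                radii[pid] * math.sin(angles[pid]),
                geometry.injection_z,
            ]
        )
        state = ParticleState(
            id=pid,
            position=position,
            velocity=field_.velocity(position),
            d_p=d_p,
            rho_p=rho_p,
        )
        track = _Track()
        t = 0.0
        v_cr = wallmodel.capture_velocity(d_p, rho_p, materials)
        tau = relaxation_time(d_p, rho_p, materials.mu, materials.C_u)
        exit_time: float | None = None
        z_stick: float | None = None

        for _ in range(max_steps_per_particle):
            if t >= max_time:
                break
            u = field_.velocity(state.position)
            speed = max(float(np.linalg.norm(state.velocity)), float(np.linalg.norm(u)), 1e-12)
            dt = min(max(tau / 5.0, dt_floor), cfl_displacement / speed, max_time - t)
            new_x, new_v = step_particle(state, u, dt, materials, gravity_on)
            if not (np.all(np.isfinite(new_x)) and np.all(np.isfinite(new_v))):
                raise NumericalError(
                    f"particle {pid}: non-finite trajectory at t={t:.6g} s"
                )
            col = detect_wall_collision(state.position, new_x, geometry, rng)
            if col is None:
                state.position, state.velocity = new_x, new_v
                t += dt
                continue

            dt_hit = max(col.s * dt, 1e-15)
            _, v_hit = step_particle(state, u, dt_hit, materials, gravity_on)
            t += dt_hit
            if col.kind == "emitted":
                state.status = EMITTED
                exit_time = t
                break

            track.n_impacts += 1
            event, v_out = wallmodel.impact_outcome(
                v_hit,
                col.normal,
                v_cr,
                materials.e_n,
                particle_id=pid,
                position=tuple(col.point),
                region=col.region,
            )
            if collect_impacts:
                impacts_log.append(event)
            if event.outcome == wallmodel.STICK:
                track.stuck_ever = True
                _, u_rel, shear = _near_wall_conditions(field_, col.point, col.normal, d_p)
                mode, _ = wallmodel.evaluate_detachment(d_p, u_rel, shear, materials)
                if mode == REMAINS_STUCK:
                    state.status = STUCK
                    state.region = col.region
                    z_stick = float(col.point[2])
                    break
                track.n_detachments += 1
                state.position = col.point + col.normal * (d_p / 2.0)
                state.velocity = field_.velocity(state.position)
            else:
                state.position = col.point + col.normal * max(WALL_EPS, d_p / 2.0)
                state.velocity = v_out

        if state.status == IN_FLIGHT:
            state.status = TIMED_OUT

        records.append(
            FateRecord(
                particle_id=pid,
                d_g_um=float(diameters_um[pid]),
                d_ae_um=aerodynamic_diameter(float(diameters_um[pid]), formulation.true_density),
                mass_kg=state.mass,
                n_impacts=track.n_impacts,
                stuck_ever=track.stuck_ever,
                n_detachments=track.n_detachments,
                final_status=state.status,
                final_region=state.region,
                z_stick_m=z_stick,
                exit_time_s=exit_time,
            )
        )
    return records, impacts_log


def summarize_fates(records: list[FateRecord], weighting: str = MASS) -> SimulationSummary:
    """Aggregate fate records into percentages under one weighting.

    ``weighting="number"`` counts particles; ``weighting="mass"`` weights by
    physical particle mass.  The detached-to-stuck ratio is the (weighted)
    amount that stuck at some point but was re-entrained, divided by the
    amount permanently stuck (NaN when nothing is permanently stuck).
    """
    if not records:
        raise ValidationError("cannot summarize an empty set of fate records")
    if weighting not in (NUMBER, MASS):
        raise ValidationError(f"weighting must be 'number' or 'mass', got {weighting!r}")
    w = np.array([1.0 if weighting == NUMBER else r.mass_kg for r in records])
    total = float(w.sum())

    def frac(mask) -> float:
        return 100.0 * float(w[mask].sum()) / total

    impacted = np.array([r.n_impacts > 0 for r in records])
    stuck_ever = np.array([r.stuck_ever for r in records])
    stuck_final = np.array([r.final_status == STUCK for r in records])
    emitted = np.array([r.final_status == EMITTED for r in records])
    timed_out = np.array([r.final_status == TIMED_OUT for r in records])

    stuck_w = float(w[stuck_final].sum())
    detached_w = float(w[stuck_ever & ~stuck_final].sum())
    ratio = detached_w / stuck_w if stuck_w > 0 else float("nan")

    regions = {}
    for region in (CHAMBER, GRID, MOUTHPIECE):
        mask = np.array([r.final_status == STUCK and r.final_region == region for r in records])
        regions[region] = 100.0 * float(w[mask].sum()) / stuck_w if stuck_w > 0 else 0.0

    return SimulationSummary(
        weighting=weighting,
        n_particles=len(records),
        fraction_impacted=frac(impacted),
        fraction_stuck_ever=frac(stuck_ever),
        fraction_permanently_stuck=frac(stuck_final),
        detached_to_stuck_ratio=ratio,
        emitted_fraction=frac(emitted),
        fraction_timed_out=frac(timed_out),
        region_fractions=regions,
    )


def fates_to_dataframe(records: list[FateRecord]) -> pd.DataFrame:
    """Fate table with the documented CSV column layout."""
    return pd.DataFrame(
        {
            "particle_id": [r.particle_id for r in records],
            "d_g_um": [r.d_g_um for r in records],
            "d_ae_um": [r.d_ae_um for r in records],
            "mass_kg": [r.mass_kg for r in records],
            "n_impacts": [r.n_impacts for r in records],
            "stuck_ever": [r.stuck_ever for r in records],
            "n_detachments": [r.n_detachments for r in records],
            "final_status": [r.final_status for r in records],
            "final_region": [r.final_region for r in records],
            "z_stick_m": [r.z_stick_m for r in records],
            "exit_time_s": [r.exit_time_s for r in records],
        }
    )
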