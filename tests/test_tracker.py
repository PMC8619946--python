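import math
import statistics

import numpy as np
import pytest

from dpitrack.errors import ValidationError
from dpitrack.flowfield import uniform_field
from dpitrack.geometry import build_geometry
from dpitrack.fixtures import get_formulation
from dpitrack.particles import EMITTED, STUCK, TIMED_OUT, ParticleState
from dpitrack.tracker import (
    FateRecord,
    detect_wall_collision,
    fates_to_dataframe,
    run_simulation,
    step_particle,
    summarize_fates,
)
from dpitrack.wallmodel import MaterialParams


class TestStepParticle:
    def _state(self, velocity):
        return ParticleState(0, np.zeros(3), np.array(velocity, float), 5e-6, 1050.0)

    def test_particle_at_fluid_velocity_is_fixed_point(self, materials):
        u = np.array([0.3, -0.1, 1.0])
        _, v = step_particle(self._state(u), u, dt=1e-4, materials=materials)
        assert np.allclose(v, u, atol=1e-15)

    def test_large_step_relaxes_to_fluid_velocity(self, materials):
        u = np.array([0.0, 0.0, 2.0])
        _, v = step_particle(self._state([5.0, 0.0, 0.0]), u, dt=10.0, materials=materials)
        assert np.allclose(v, u, atol=1e-12)

    def test_one_relaxation_time_gives_exponential_fraction(self, materials):
        """After dt = tau, the velocity has closed 1 - 1/e of the gap."""
        tau = 1050.0 * (5e-6) ** 2 / (18 * materials.mu)
        _, v = step_particle(
            self._state([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]), tau, materials
        )
        assert v[2] == pytest.approx(1.0 - math.exp(-1.0), rel=1e-9)

    def test_rejects_non_flight_state(self, materials):
        state = self._state([0, 0, 0])
        state.status = STUCK
        with pytest.raises(ValidationError):
            step_particle(state, np.zeros(3), 1e-5, materials)

    def test_gravity_adds_terminal_settling(self, materials):
        state = self._state([0.0, 0.0, 0.0])
        tau = 1050.0 * (5e-6) ** 2 / (18 * materials.mu)
        _, v = step_particle(state, np.zeros(3), dt=1.0, materials=materials, gravity_on=True)
        assert v[2] == pytest.approx(-9.80665 * tau, rel=1e-6)


class TestDetectWallCollision:
    def test_interior_segment_has_no_event(self, geometry, rng):
        hit = detect_wall_collision((0, 0, 0.005), (0.001, 0.001, 0.006), geometry, rng)
        assert hit is None

    def test_radial_segment_hits_chamber_wall(self, geometry, rng):
        hit = detect_wall_collision((0, 0, 0.005), (0.02, 0, 0.005), geometry, rng)
        assert hit is not None and hit.kind == "wall"
        assert np.hypot(*hit.point[:2]) == pytest.approx(geometry.chamber_radius, abs=1e-9)
        assert np.allclose(hit.normal, [-1, 0, 0])
        assert hit.region == "chamber"

    def test_grid_porosity_one_never_impacts_open_area(self, rng):
        geom = build_geometry({"grid_porosity": 1.0})
        for _ in range(50):
            hit = detect_wall_collision(
                (0.001, 0, geom.grid_z - 1e-3), (0.001, 0, geom.grid_z + 1e-3), geom, rng
            )
            assert hit is None

    def test_grid_porosity_zero_always_impacts(self, rng):
        geom = build_geometry({"grid_porosity": 0.0})
        hit = detect_wall_collision(
            (0.001, 0, geom.grid_z - 1e-3), (0.001, 0, geom.grid_z + 1e-3), geom, rng
        )
        assert hit is not None and hit.region == "grid"
        assert np.allclose(hit.normal, [0, 0, -1])

    def test_grid_shoulder_is_solid(self, geometry, rng):
        """Crossing the grid plane outside the open bore always impacts."""
        r = (geometry.mouthpiece_radius + geometry.chamber_radius) / 2
        for _ in range(20):
            hit = detect_wall_collision(
                (r, 0, geometry.grid_z - 1e-3), (r, 0, geometry.grid_z + 1e-3), geometry, rng
            )
            assert hit is not None and hit.region == "grid"

    def test_outlet_crossing_is_emission(self, geometry, rng):
        hit = detect_wall_collision(
            (0.001, 0, geometry.total_height - 1e-4),
            (0.001, 0, geometry.total_height + 1e-4),
            geometry,
            rng,
        )
        assert hit is not None and hit.kind == "emitted"


def _straight_tube():
    """Degenerate device: constant-radius duct with a fully open grid."""
    return build_geometry(
        {"chamber_radius": 5.0, "outlet_diameter": 10.0, "grid_porosity": 1.0}
    )


class TestRunSimulation:
    def test_unobstructed_axial_flow_emits_everything(self):
        geom = _straight_tube()
        field = uniform_field(2.0, (0, 0, 1))
        records, _ = run_simulation(
            get_formulation("F1"), geom, field, 40, seed=1, max_time=0.2
        )
        assert all(r.final_status == EMITTED for r in records)
        summary = summarize_fates(records, "mass")
        assert summary.emitted_fraction == pytest.approx(100.0)
        assert summary.fraction_permanently_stuck == 0.0

    def test_quiescent_air_times_everything_out(self, geometry):
        field = uniform_field(0.0, (0, 0, 1))
        records, _ = run_simulation(
            get_formulation("F1"), geometry, field, 20, seed=2, max_time=0.02
        )
        assert all(r.final_status == TIMED_OUT for r in records)

    def test_fates_partition_injected_count(self, default_run):
        records, _ = default_run
        by_status = {
            status: sum(r.final_status == status for r in records)
            for status in (EMITTED, STUCK, TIMED_OUT)
        }
        assert sum(by_status.values()) == len(records) == 100

    def test_seed_determinism(self, geometry, swirl_field, default_run):
        records, _ = default_run
        again, _ = run_simulation(
            get_formulation("F1"), geometry, swirl_field, 100, seed=42, collect_impacts=True
        )
        assert fates_to_dataframe(records).equals(fates_to_dataframe(again))

    def test_timestep_halving_barely_moves_emitted_fraction(
        self, geometry, swirl_field, default_run
    ):
        records, _ = default_run
        halved, _ = run_simulation(
            get_formulation("F1"),
            geometry,
            swirl_field,
            100,
            seed=42,
            cfl_displacement=0.1e-3,
            dt_floor=0.5e-6,
        )
        ef = summarize_fates(records, "mass").emitted_fraction
        ef_halved = summarize_fates(halved, "mass").emitted_fraction
        assert abs(ef - ef_halved) < 2.0

    def test_small_particles_impact_below_capture_velocity_more_often(self, wide_span_run):
        """At the grid plane, where all sizes arrive at similar speeds, fine
        particles (2-5 um) fall below their capture velocity more readily
        than coarse ones (7-9 um)."""
        records, impacts = wide_span_run
        diameter = {r.particle_id: r.d_g_um for r in records}
        grid_hits = [e for e in impacts if e.region == "grid"]
        fine = [e for e in grid_hits if 2.0 <= diameter[e.particle_id] <= 5.0]
        coarse = [e for e in grid_hits if 7.0 <= diameter[e.particle_id] <= 9.0]
        assert len(fine) >= 10 and len(coarse) >= 10
        stick_rate = lambda evs: sum(e.v_n < e.v_cr for e in evs) / len(evs)
        assert stick_rate(fine) >= stick_rate(coarse)
        margin = lambda evs: statistics.median(e.v_n / e.v_cr for e in evs)
        assert margin(fine) < margin(coarse)

    def test_missing_seed_rejected(self, geometry, swirl_field):
        with pytest.raises(ValidationError):
            run_simulation(get_formulation("F1"), geometry, swirl_field, 10, seed=None)


class TestSummarizeFates:
    def _record(self, pid, status, mass=1e-12, region=None, stuck_ever=False, impacts=0):
        return FateRecord(
            particle_id=pid,
            d_g_um=4.0,
            d_ae_um=4.1,
            mass_kg=mass,
            n_impacts=impacts,
            stuck_ever=stuck_ever,
            n_detachments=0,
            final_status=status,
            final_region=region,
        )

    def test_all_emitted(self):
        records = [self._record(i, EMITTED) for i in range(4)]
        summary = summarize_fates(records, "number")
        assert summary.emitted_fraction == 100.0
        assert summary.fraction_permanently_stuck == 0.0

    def test_half_stuck_equal_masses(self):
        records = [
            self._record(0, STUCK, region="chamber", stuck_ever=True, impacts=1),
            self._record(1, EMITTED),
        ]
        summary = summarize_fates(records, "mass")
        assert summary.emitted_fraction == 50.0
        assert summary.region_fractions["chamber"] == 100.0

    def test_detached_to_stuck_ratio(self):
        stuck = [
            self._record(i, STUCK, region="grid", stuck_ever=True, impacts=1) for i in range(12)
        ]
        detached = [
            self._record(12 + i, EMITTED, stuck_ever=True, impacts=2) for i in range(18)
        ]
        summary = summarize_fates(stuck + detached, "number")
        assert summary.detached_to_stuck_ratio == pytest.approx(1.5)
        assert summary.fraction_stuck_ever == pytest.approx(100.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            summarize_fates([], "mass")

    def test_mass_and_number_weightings_differ_when_masses_do(self):
        records = [
            self._record(0, EMITTED, mass=8e-12),
            self._record(1, STUCK, mass=2e-12, region="chamber", stuck_ever=True, impacts=1),
        ]
        assert summarize_fates(records, "number").emitted_fraction == 50.0
        assert summarize_fates(records, "mass").emitted_fraction == pytest.approx(80.0)
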