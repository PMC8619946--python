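import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dpitrack.errors import ValidationError
from dpitrack.wallmodel import (
    BOUNCE,
    REMAINS_STUCK,
    ROLLS,
    SLIDES,
    STICK,
    DetachmentForces,
    MaterialParams,
    adhesion_force,
    capture_velocity,
    contact_geometry,
    detachment_mode,
    el_batch_parameter,
    evaluate_detachment,
    impact_outcome,
    wall_drag_force,
    wall_lift_force,
)
from oracles import capture_velocity_oracle


class TestElBatchParameter:
    def test_reference_value(self, materials):
        assert el_batch_parameter(materials, 1050.0) == pytest.approx(3.48e-6, rel=2e-3)

    def test_decreases_with_density(self, materials):
        values = [el_batch_parameter(materials, rho) for rho in (900, 1050, 1300)]
        assert values[0] > values[1] > values[2]

    def test_compliance_identity_at_zero_poisson(self):
        materials = MaterialParams(v_s=0.0)
        # with v_s = 0 the wall compliance k1 reduces to 1/(pi E_s); E scales accordingly
        k1 = 1.0 / (math.pi * materials.E_s)
        k2 = (1 - materials.v_p**2) / (math.pi * materials.E_p)
        expected = 0.51 * (5 * math.pi**2 * (k1 + k2) / (4 * 1050.0**1.5)) ** 0.4
        assert el_batch_parameter(materials, 1050.0) == pytest.approx(expected, rel=1e-12)


class TestCaptureVelocity:
    def test_reference_values(self, materials):
        assert capture_velocity(5e-6, 1050.0, materials) == pytest.approx(1.60, abs=0.01)
        assert capture_velocity(10e-6, 1050.0, materials) == pytest.approx(0.596, abs=0.005)

    def test_agrees_with_arbitrary_precision_oracle(self, materials):
        """Double-precision composition matches 50-digit evaluation to 1e-9."""
        for d_um in (0.5, 1.0, 2.0, 5.0, 8.0, 13.0, 20.0):
            for rho in (900.0, 1050.0, 1150.0, 1300.0):
                ours = capture_velocity(d_um * 1e-6, rho, materials)
                oracle = capture_velocity_oracle(d_um * 1e-6, rho)
                assert ours == pytest.approx(oracle, rel=1e-9)

    @given(st.floats(0.5, 19.0))
    def test_strictly_decreasing_in_diameter(self, d_um):
        materials = MaterialParams()
        v1 = capture_velocity(d_um * 1e-6, 1050.0, materials)
        v2 = capture_velocity((d_um + 0.5) * 1e-6, 1050.0, materials)
        assert v2 < v1

    @given(st.floats(900.0, 1250.0))
    def test_strictly_decreasing_in_density(self, rho):
        materials = MaterialParams()
        assert capture_velocity(5e-6, rho + 50.0, materials) < capture_velocity(
            5e-6, rho, materials
        )

    def test_vanishes_for_large_particles(self, materials):
        assert capture_velocity(1.0, 1050.0, materials) < 1e-6

    def test_nonpositive_diameter_rejected(self, materials):
        with pytest.raises(ValidationError):
            capture_velocity(0.0, 1050.0, materials)


class TestImpactOutcome:
    def test_zero_normal_speed_sticks(self):
        event, v_out = impact_outcome((1.0, 0.0, 0.0), (0.0, 0.0, 1.0), v_cr=0.5, e_n=0.8)
        assert event.outcome == STICK
        assert np.allclose(v_out, 0.0)

    def test_bounce_reflects_normal_and_preserves_tangential(self):
        v_cr = 0.5
        event, v_out = impact_outcome(
            (3.0, 0.0, -2 * v_cr), (0.0, 0.0, 1.0), v_cr=v_cr, e_n=0.8
        )
        assert event.outcome == BOUNCE
        assert event.v_n == pytest.approx(2 * v_cr)
        assert v_out[2] == pytest.approx(0.8 * 2 * v_cr)  # reversed, scaled
        assert v_out[0] == pytest.approx(3.0)  # tangential untouched

    def test_exact_tie_sticks(self):
        event, _ = impact_outcome((0.0, 0.0, -0.5), (0.0, 0.0, 1.0), v_cr=0.5, e_n=0.8)
        assert event.outcome == STICK

    def test_bounce_dissipates_kinetic_energy(self):
        _, v_out = impact_outcome((1.0, 2.0, -3.0), (0.0, 0.0, 1.0), v_cr=0.1, e_n=0.7)
        assert np.linalg.norm(v_out) < np.linalg.norm([1.0, 2.0, -3.0])

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValidationError):
            impact_outcome((0, 0, -1), (0, 0, 2.0), v_cr=0.5, e_n=0.8)


class TestForceClosures:
    def test_adhesion_reference_value_and_linearity(self):
        assert adhesion_force(5e-6, 0.039) == pytest.approx(4.59e-7, rel=2e-3)
        assert adhesion_force(10e-6, 0.039) == pytest.approx(2 * adhesion_force(5e-6, 0.039))
        assert adhesion_force(5e-6, 0.0) == 0.0

    def test_drag_reference_value(self, materials):
        assert wall_drag_force(5e-6, 1.0, materials) == pytest.approx(1.43e-9, rel=3e-3)
        assert wall_drag_force(5e-6, 0.0, materials) == 0.0

    def test_plain_stokes_recovered_without_corrections(self):
        materials = MaterialParams(f=1.0, C_u=1.0)
        expected = 3 * math.pi * materials.mu * 5e-6 * 2.0
        assert wall_drag_force(5e-6, 2.0, materials) == pytest.approx(expected, rel=1e-12)

    def test_lift_saffman_form(self, materials):
        d_p, u_rel, shear = 5e-6, 1.0, 1e3
        expected = (
            1.615 * materials.mu * d_p**2 * u_rel
            * math.sqrt(materials.rho_air * shear / materials.mu)
        )
        assert wall_lift_force(d_p, u_rel, shear, materials) == pytest.approx(expected)
        assert wall_lift_force(d_p, u_rel, 0.0, materials) == 0.0

    def test_lift_disabled_switch(self):
        materials = MaterialParams(lift_enabled=False)
        assert wall_lift_force(5e-6, 1.0, 1e3, materials) == 0.0

    def test_contact_geometry_reference_and_scaling(self, materials):
        a5, b5 = contact_geometry(5e-6, materials)
        compliance = (1 - materials.v_s**2) / materials.E_s + (1 - materials.v_p**2) / materials.E_p
        K = (4.0 / 3.0) / compliance
        expected_a = (9 * math.pi * materials.W_A * (2.5e-6) ** 2 / (2 * K)) ** (1 / 3)
        assert a5 == pytest.approx(expected_a, rel=1e-12)
        assert b5 == pytest.approx(a5**2 / 5e-6, rel=1e-12)
        assert b5 < 2.5e-6
        a10, _ = contact_geometry(10e-6, materials)
        assert a10 / a5 == pytest.approx(2 ** (2 / 3), rel=1e-9)

    def test_contact_vanishes_without_adhesion(self):
        materials = MaterialParams(W_A=0.0)
        assert contact_geometry(5e-6, materials) == (0.0, 0.0)


class TestDetachmentMode:
    def test_zero_fluid_forces_remain_stuck(self, materials):
        mode, _ = evaluate_detachment(5e-6, 0.0, 0.0, materials)
        assert mode == REMAINS_STUCK

    def test_sliding_boundary_inclusive(self):
        # rolling moment balance false, sliding friction balance exactly met
        forces = DetachmentForces(F_D=0.5, F_L=0.0, F_st=1.0, a=1e-7, b=1e-9)
        assert detachment_mode(forces, d_p=1e-9, k_s=0.5) == SLIDES

    def test_rolling_reported_when_both_mechanisms_trigger(self):
        forces = DetachmentForces(F_D=10.0, F_L=0.0, F_st=1e-6, a=1e-7, b=1e-9)
        assert detachment_mode(forces, d_p=5e-6, k_s=0.5) == ROLLS

    def test_default_regime_near_wall_flow_cannot_detach(self, materials):
        """At a 1 m/s near-wall slip, drag is ~1.4 nN versus a ~0.23 uN
        friction threshold: deposited particles stay put."""
        mode, forces = evaluate_detachment(5e-6, 1.0, 1e3, materials)
        assert mode == REMAINS_STUCK
        assert forces.F_D < 0.01 * materials.k_s * forces.F_st

    def test_rolling_precedes_sliding_for_spheres(self, materials):
        """Sweeping slip speed upward, the first detachment mode met is rolling."""
        for u in np.linspace(1.0, 60.0, 120):
            mode, _ = evaluate_detachment(5e-6, float(u), 0.0, materials)
            if mode != REMAINS_STUCK:
                assert mode == ROLLS
                break
        else:
            pytest.fail("no detachment found in sweep")


class TestMaterialParams:
    def test_table_defaults(self, materials):
        assert (materials.E_s, materials.E_p) == (4.1e9, 1.0e9)
        assert (materials.v_s, materials.v_p) == (0.35, 0.40)
        assert (materials.W_A, materials.k_s, materials.f) == (0.039, 0.50, 1.70)
        assert (materials.C_u, materials.mu, materials.rho_air) == (1.0, 1.7894e-5, 1.225)

    def test_invalid_poisson_ratio_rejected(self):
        with pytest.raises(ValidationError):
            MaterialParams(v_p=0.5)

    def test_override_preserves_other_fields(self, materials):
        changed = materials.with_overrides(E_p=2e9)
        assert changed.E_p == 2e9 and changed.E_s == materials.E_s
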