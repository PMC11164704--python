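import math

import numpy as np
import pytest

from thermosoar import (
    AirVelocity,
    ControlState,
    GliderParams,
    GliderState,
    InstabilityError,
    aerodynamic_forces,
    derivatives,
    detect_instability,
    integrate,
    step,
    steady_circle,
    steady_straight_glide,
    vulture_params,
)
from thermosoar.flight_dynamics import STILL_AIR, PHYSICS_DT, PitchMonitor

STILL = AirVelocity(0.0, 0.0, 0.0)


def level_state(V=15.0, gamma_deg=0.0, chi_deg=0.0, z=500.0):
    return GliderState(0.0, 0.0, z, V, math.radians(gamma_deg),
                       math.radians(chi_deg))


class TestAerodynamicForces:
    def test_v_squared_scaling(self, glider):
        c = ControlState(sigma=10.0, alpha=5.0, beta=2.0)
        f1 = aerodynamic_forces(level_state(V=10.0), c, STILL, glider)
        f2 = aerodynamic_forces(level_state(V=20.0), c, STILL, glider)
        assert f2.L == pytest.approx(4 * f1.L)
        assert f2.D == pytest.approx(4 * f1.D)
        assert f2.C == pytest.approx(4 * f1.C)

    def test_zero_sideslip_zero_side_force(self, glider):
        f = aerodynamic_forces(level_state(), ControlState(beta=0.0), STILL, glider)
        assert f.C == 0.0

    def test_drag_positive(self, glider):
        for alpha in (-10.0, 0.0, 6.0, 20.0):
            f = aerodynamic_forces(
                level_state(), ControlState(alpha=alpha), STILL, glider
            )
            assert f.D > 0

    def test_forces_act_on_the_air_relative_speed(self, glider):
        # V is the air-relative speed: the same V gives the same forces
        # regardless of the ambient air motion
        c = ControlState(alpha=6.0)
        f_still = aerodynamic_forces(level_state(V=15.0), c, STILL, glider)
        moving = AirVelocity(5.0, 0.0, 1.0)
        f_wind = aerodynamic_forces(level_state(V=15.0), c, moving, glider)
        assert f_wind.L == pytest.approx(f_still.L)

    def test_zero_airspeed_is_an_error(self, glider):
        s = level_state(V=0.0)
        with pytest.raises(InstabilityError):
            aerodynamic_forces(s, ControlState(), STILL, glider)


class TestDerivatives:
    def test_climb_rate_identity(self, glider):
        # dz/dt = V sin(gamma) in still air for any state
        for gam in (-20.0, -5.0, 0.0, 10.0):
            s = level_state(gamma_deg=gam)
            d = derivatives(s, ControlState(), STILL, glider)
            assert d[2] == pytest.approx(s.V * math.sin(s.gamma))

    def test_updraft_adds_kinematically(self, glider):
        # a uniform updraft lifts the whole trajectory: dz gains +w, the
        # air-relative block is untouched
        s = level_state(gamma_deg=-5.0)
        d0 = derivatives(s, ControlState(), STILL, glider)
        d1 = derivatives(s, ControlState(), AirVelocity(0, 0, 1.8), glider)
        assert d1[2] == pytest.approx(d0[2] + 1.8)
        assert d1[3:] == pytest.approx(d0[3:])

    def test_level_force_balance_freezes_gamma(self, glider):
        # find V where L = m g at alpha=6, sigma=0, gamma=0: gamma_dot = 0
        cl = glider.lift_coefficient(math.radians(6.0))
        V = math.sqrt(2 * glider.m * glider.g / (glider.rho * glider.S * cl))
        d = derivatives(level_state(V=V), ControlState(alpha=6.0), STILL, glider)
        assert d[4] == pytest.approx(0.0, abs=1e-12)

    def test_positive_bank_turns(self, glider):
        d = derivatives(
            level_state(), ControlState(sigma=20.0, alpha=6.0), STILL, glider
        )
        assert d[5] > 0

    def test_planar_glide_when_wings_level(self, glider):
        d = derivatives(level_state(gamma_deg=-3.0), ControlState(sigma=0.0),
                        STILL, glider)
        assert d[5] == pytest.approx(0.0, abs=1e-15)

    def test_vertical_glide_singular(self, glider):
        s = level_state(gamma_deg=-90.0)
        with pytest.raises(InstabilityError):
            derivatives(s, ControlState(), STILL, glider)


class TestIntegration:
    def test_energy_dissipated_only_by_drag(self, glider):
        # d/dt (0.5 m V^2 + m g z) = -D V in still air; compare the energy
        # drop over each step with the drag-power quadrature of a 10x finer
        # oracle integration
        c = ControlState(sigma=15.0, alpha=6.0)
        s = level_state(V=16.0, gamma_deg=-3.0)
        t = 0.0
        for _ in range(40):
            e0 = 0.5 * glider.m * s.V**2 + glider.m * glider.g * s.z
            fine = s
            power = 0.0
            for _ in range(10):
                f = aerodynamic_forces(fine, c, STILL, glider)
                v_air = fine.V  # still air
                power += f.D * v_air * (PHYSICS_DT / 10)
                fine = step(fine, c, STILL_AIR, t, PHYSICS_DT / 10, glider)
            s1 = step(s, c, STILL_AIR, t, PHYSICS_DT, glider)
            e1 = 0.5 * glider.m * s1.V**2 + glider.m * glider.g * s1.z
            assert e1 - e0 == pytest.approx(-power, rel=1e-3)
            assert e1 < e0  # strictly dissipative
            s = s1
            t += PHYSICS_DT

    def test_endpoint_convergence_under_refinement(self, glider):
        # dt versus dt/10 endpoint difference below 0.1 m over 200 s
        c = ControlState(sigma=30.0, alpha=8.0)
        s0 = level_state(V=15.0, gamma_deg=-5.0, z=1000.0)
        ends = []
        for dt in (PHYSICS_DT, PHYSICS_DT / 10):
            s = integrate(s0, c, STILL_AIR, 0.0, 200.0, dt, glider)
            ends.append(np.array([s.x, s.y, s.z]))
        assert np.linalg.norm(ends[0] - ends[1]) < 0.1

    def test_long_glide_settles_at_baseline_sink(self, glider):
        c = ControlState(sigma=0.0, alpha=6.0)
        s = level_state(V=15.0, gamma_deg=-5.0, z=2000.0)
        s = integrate(s, c, STILL_AIR, 0.0, 200.0, PHYSICS_DT, glider)
        ref = steady_straight_glide(6.0, glider)
        assert s.vz == pytest.approx(ref.vz, rel=0.01)
        assert ref.vz == pytest.approx(-0.75, abs=1e-6)

    def test_circling_steady_state_matches_algebraic_solver(self, glider):
        sig, alp = 30.0, 8.0
        ref = steady_circle(sig, alp, glider)
        c = ControlState(sigma=sig, alpha=alp)
        s = level_state(V=ref.V, gamma_deg=math.degrees(ref.gamma), z=2000.0)
        s = integrate(s, c, STILL_AIR, 0.0, 100.0, PHYSICS_DT, glider)
        # radius from the turn rate, sink from the state
        d = derivatives(s, c, STILL, glider)
        radius = s.V * math.cos(s.gamma) / d[5]
        assert radius == pytest.approx(ref.radius, rel=0.01)
        assert s.vz == pytest.approx(ref.vz_sink, rel=0.01)

    def test_bad_dt_rejected(self, glider):
        with pytest.raises(ValueError):
            step(level_state(), ControlState(), STILL_AIR, 0.0, 0.0, glider)


class TestInstabilityDetection:
    def test_oscillating_pitch_is_stable(self):
        gam = [math.radians(8.0) * math.sin(0.3 * i) for i in range(2000)]
        assert detect_instability(gam) is False

    def test_monotonic_winding_flags(self):
        gam = [math.radians(0.5) * i for i in range(1000)]  # winds past 360
        assert detect_instability(gam) is True

    def test_direction_change_resets_accumulator(self):
        up = [math.radians(0.5) * i for i in range(400)]  # 200 deg up
        down = [up[-1] - math.radians(0.5) * i for i in range(400)]
        assert detect_instability(up + down + up) is False

    def test_singular_state_flags(self, glider):
        slow = level_state(V=1.5)
        assert detect_instability([], slow) is True
        steep = GliderState(0, 0, 500, 15.0, math.radians(91.0), 0.0)
        assert detect_instability([], steep) is True

    def test_negative_lift_dive_goes_singular(self, glider):
        # full nose-down: negative lift pitches the path through vertical,
        # which the integrator reports as an instability event
        c = ControlState(sigma=0.0, alpha=-30.0)
        s = level_state(V=15.0, gamma_deg=0.0, z=2000.0)
        with pytest.raises(InstabilityError):
            integrate(s, c, STILL_AIR, 0.0, 60.0, PHYSICS_DT, glider)


class TestPitchMonitor:
    def test_full_turn_trips(self):
        mon = PitchMonitor(0.0)
        tripped = False
        for i in range(1, 800):
            if mon.update(math.radians(0.5) * i):
                tripped = True
                break
        assert tripped


def test_param_validation():
    with pytest.raises(ValueError):
        GliderParams(m=-1.0)
    with pytest.raises(ValueError):
        GliderParams(c_d0=0.0)


def test_heavier_glider_sinks_faster(glider):
    heavy = GliderParams(m=2 * glider.m)
    assert steady_straight_glide(6.0, heavy).vz < steady_straight_glide(6.0, glider).vz
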