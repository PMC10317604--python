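import math

import numpy as np
import pytest

from capilsep.device import (
    FluidProperties,
    Segment,
    cylindrical,
    rectangular,
)
from capilsep.flow import (
    FlowError,
    advance_flow,
    capillary_pressure,
    driving_pressure,
    effective_viscosity,
    hydraulic_resistance,
)
from conftest import make_uniform_config, make_vertical_config

WATERY = FluidProperties(viscosity_mu_l=1e-3, surface_tension_sigma=0.05)


def seg_cyl(radius, theta, length=1e-3, incl=0.0):
    return Segment(id="c", kind="vertical_well", length=length,
                   cross_section=cylindrical(radius), contact_angle=theta,
                   inclination=incl)


def seg_rect(w, d, theta, length=1e-3):
    return Segment(id="r", kind="horizontal_channel", length=length,
                   cross_section=rectangular(w, d), contact_angle=theta)


class TestCapillaryPressure:
    def test_neutral_angle_gives_zero(self):
        assert capillary_pressure(seg_cyl(1e-4, 90.0), WATERY) == pytest.approx(0.0)
        assert capillary_pressure(seg_rect(1e-4, 1e-4, 90.0), WATERY) == pytest.approx(0.0)

    def test_cylindrical_hand_value(self):
        # 2·0.05·cos60° / 0.5 mm = 100 Pa
        p = capillary_pressure(seg_cyl(0.5e-3, 60.0), WATERY)
        assert p == pytest.approx(100.0, rel=1e-12)

    def test_square_channel_doubles_parallel_plate(self):
        d = 2e-4
        square = capillary_pressure(seg_rect(d, d, 40.0), WATERY)
        sigma, ct = WATERY.surface_tension_sigma, math.cos(math.radians(40.0))
        parallel_plate = 2 * sigma * ct / d
        assert square == pytest.approx(2 * parallel_plate, rel=1e-12)

    def test_nonwetting_is_negative(self):
        assert capillary_pressure(seg_cyl(1e-4, 110.0), WATERY) < 0


class TestHydraulicResistance:
    def test_zero_wetted_length(self):
        assert hydraulic_resistance(seg_cyl(1e-3, 40.0), 0.0, 1e-3) == 0.0

    def test_cylindrical_hand_value(self):
        # 8µL/(πR⁴) with R = 1 mm, L = 1 mm, µ = 1 mPa·s:
        # 8·10⁻³·10⁻³·10⁻³/(π·10⁻¹²) ≈ 2.546×10⁶ Pa·s/m³
        r = hydraulic_resistance(seg_cyl(1e-3, 40.0), 1e-3, 1e-3)
        assert r == pytest.approx(8e-6 / (math.pi * 1e-12), rel=1e-12)
        assert r == pytest.approx(2.546e6, rel=1e-3)

    def test_linear_in_viscosity_and_length(self):
        s = seg_rect(1e-3, 2e-4, 40.0)
        r1 = hydraulic_resistance(s, 5e-4, 1e-3)
        assert hydraulic_resistance(s, 5e-4, 2e-3) == pytest.approx(2 * r1)
        assert hydraulic_resistance(s, 1e-3, 1e-3) == pytest.approx(2 * r1)

    def test_dimension_swap_convention(self):
        # rectangular formula requires d ≤ w; swapped dimensions must agree
        a = hydraulic_resistance(seg_rect(1e-3, 2e-4, 40.0), 1e-3, 1e-3)
        b = hydraulic_resistance(seg_rect(2e-4, 1e-3, 40.0), 1e-3, 1e-3)
        assert a == pytest.approx(b)

    def test_negative_length_rejected(self):
        with pytest.raises(FlowError):
            hydraulic_resistance(seg_cyl(1e-3, 40.0), -1e-6, 1e-3)


class TestEffectiveViscosity:
    def test_initial_and_disabled(self):
        f = FluidProperties(viscosity_mu_l=3e-3, coagulation_tau_c=math.inf)
        assert effective_viscosity(f, 0.0) == 3e-3
        assert effective_viscosity(f, 1e6) == 3e-3

    def test_one_time_constant_is_e_fold(self):
        f = FluidProperties(viscosity_mu_l=3e-3, coagulation_tau_c=120.0)
        assert effective_viscosity(f, 120.0) == pytest.approx(3e-3 * math.e)


class TestDrivingPressure:
    def test_neutral_horizontal_chain_is_zero(self):
        cfg = make_uniform_config(contact_angle=90.0)
        assert driving_pressure(cfg, 1e-3) == pytest.approx(0.0)

    def test_band_entry_is_negative_on_default_chip(self, chip):
        from capilsep.flow import ChainGeometry

        geom = ChainGeometry(chip)
        x_band = float(geom.entry_x[chip.segment_index("hydrophobic_band")])
        assert driving_pressure(chip, x_band + 1e-9) < 0

    def test_vertical_column_hydrostatics(self):
        cfg = make_vertical_config()
        x = 5e-3
        fl = cfg.fluid
        p_cap = capillary_pressure(cfg.segments[0], fl)
        expected = p_cap - fl.density_rho_l * fl.gravity_g * x
        assert driving_pressure(cfg, x) == pytest.approx(expected, rel=1e-12)


class TestAdvanceFlow:
    def test_washburn_closed_form(self):
        # parallel-plate limit (w >> d): x(t) = sqrt(σ·cosθ·d·t / 3µ)
        d, theta = 1e-4, 50.0
        cfg = make_uniform_config(width=1000 * d, depth=d, contact_angle=theta,
                                  length=2e-2, viscosity=1.5e-3)
        sigma = cfg.fluid.surface_tension_sigma
        ct = math.cos(math.radians(theta))
        x_half = cfg.segments[0].length / 2
        t_half = x_half**2 * 3 * cfg.fluid.viscosity_mu_l / (sigma * ct * d)
        traj = advance_flow(cfg, t_end=t_half, dt_max=t_half / 2000)
        assert traj.final().meniscus_position == pytest.approx(x_half, rel=0.01)

    def test_neutral_angle_never_advances(self):
        # cos(90°) carries a float epsilon, so the rate is not exactly zero;
        # the meniscus must stay at the regularisation length regardless
        cfg = make_uniform_config(contact_angle=90.0)
        traj = advance_flow(cfg, t_end=10.0, dt_max=0.1)
        assert traj.final().meniscus_position < 2e-6
        assert traj.final().flow_rate_Q < 1e-15

    def test_default_chip_stop_and_burst_events(self, chip):
        traj = advance_flow(chip, t_end=300.0, dt_max=0.1)
        labels = [e[1] for e in traj.events]
        assert "barrier_stop" in labels
        assert "barrier_burst" in labels
        assert labels.index("barrier_stop") < labels.index("barrier_burst")
        assert "segment_entry:hydrophobic_band" in labels

    def test_monotone_position_and_nonnegative_rate(self, chip):
        traj = advance_flow(chip, t_end=300.0, dt_max=0.1)
        assert np.all(np.diff(traj.positions) >= -1e-15)
        assert np.all(np.diff(traj.volumes) >= -1e-21)
        assert np.all(traj.flow_rates >= 0)

    def test_volume_continuity_with_flux_integral(self, chip):
        # the volume bookkeeping must equal the integral of the recorded flux
        traj = advance_flow(chip, t_end=200.0, dt_max=0.1)
        t = traj.times
        q = traj.flow_rates
        flux_integral = np.sum(q[1:] * np.diff(t))
        dv = traj.volumes[-1] - traj.volumes[0]
        assert abs(dv - flux_integral) <= 1e-6 * dv

    def test_step_size_convergence(self, chip):
        a = advance_flow(chip, t_end=150.0, dt_max=0.2).final().meniscus_position
        b = advance_flow(chip, t_end=150.0, dt_max=0.1).final().meniscus_position
        assert abs(a - b) <= 1e-3 * b

    def test_jurin_equilibrium_height(self):
        cfg = make_vertical_config()
        fl = cfg.fluid
        h_j = (2 * fl.surface_tension_sigma * math.cos(math.radians(30.0))
               / (fl.density_rho_l * fl.gravity_g * 2e-4))
        traj = advance_flow(cfg, t_end=2000.0, dt_max=0.5)
        final = traj.final()
        assert np.all(np.diff(traj.positions) >= -1e-15)  # monotone approach
        assert final.meniscus_position == pytest.approx(h_j, rel=0.02)
        assert final.meniscus_position < h_j  # from below
        assert final.flow_rate_Q < 1e-18  # Q → 0 at equilibrium

    def test_supply_metering_caps_filling(self, chip):
        # with the pump metering the inlet, the filled volume cannot exceed
        # the delivered volume
        traj = advance_flow(chip, t_end=120.0, dt_max=0.1)
        from capilsep.device import ul_per_min_to_m3_per_s

        pump = ul_per_min_to_m3_per_s(chip.operating.pump_rate)
        for s in traj.states:
            assert s.filled_volume <= pump * s.time + 2e-12 + 1.2e-12
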