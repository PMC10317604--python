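import math

import numpy as np
import pytest

from capilsep.device import ul_to_m3, m3_to_ul
from capilsep.flow import ChainGeometry, FlowState
from capilsep.transport import (
    ConcentrationField,
    SeparationSeries,
    TransportError,
    apply_barrier,
    run_separation,
    step_transport,
    update_mesh,
)
from capilsep.calibration import apply_parameters
from conftest import make_uniform_config


def full_domain_flow(geom, q):
    return FlowState(time=0.0, meniscus_position=geom.total_length,
                     filled_volume=geom.total_volume, flow_rate_Q=q,
                     effective_viscosity=1e-3, stopped=q == 0.0)


class TestStepTransport:
    def test_equilibrium_uniform_field_unchanged(self, uniform_geom):
        cfg, geom = uniform_geom
        f = ConcentrationField(geom, 100, geom.total_length, 0.6)
        before = f.omega_plasma.copy()
        for dt in (0.01, 1.0, 100.0):
            step_transport(f, full_domain_flow(geom, 0.0), dt, cfg)
        assert np.allclose(f.omega_plasma, before, atol=1e-14)

    def test_pure_advection_front_speed(self):
        # a step profile must translate at the flux velocity, within one cell
        cfg = make_uniform_config(diffusivity=0.0)
        geom = ChainGeometry(cfg)
        n = 400
        f = ConcentrationField(geom, n, geom.total_length, 0.0)
        f.m_plasma[: n // 4] = f.m_total[: n // 4]
        f.feed_omega = 1.0
        area = cfg.segments[0].area
        q = 2e-11
        travel = 0.2 * geom.total_length
        t_total = travel * area / q
        flow = full_domain_flow(geom, q)
        for _ in range(400):
            step_transport(f, flow, t_total / 400, cfg)
        centers = 0.5 * (f.face_positions()[:-1] + f.face_positions()[1:])
        om = f.omega_plasma
        front = np.interp(0.5, om[::-1], centers[::-1])
        expected = 0.25 * geom.total_length + travel
        assert abs(front - expected) <= geom.total_length / n

    def test_pure_diffusion_variance_growth(self):
        # second moment of a narrow pulse grows as 2·D·t (within 2%)
        D = 1e-9
        cfg = make_uniform_config(diffusivity=D)
        geom = ChainGeometry(cfg)
        n = 400
        f = ConcentrationField(geom, n, geom.total_length, 0.0)
        f.m_plasma[n // 2] = 0.2 * f.m_total[n // 2]
        centers = 0.5 * (f.face_positions()[:-1] + f.face_positions()[1:])

        def variance():
            m = f.m_plasma
            mu = (m * centers).sum() / m.sum()
            return ((centers - mu) ** 2 * m).sum() / m.sum()

        v0 = variance()
        t_total, dt = 200.0, 0.05
        flow = full_domain_flow(geom, 0.0)
        for _ in range(int(t_total / dt)):
            step_transport(f, flow, dt, cfg)
        assert variance() - v0 == pytest.approx(2 * D * t_total, rel=0.02)

    def test_receding_meniscus_rejected(self, uniform_geom):
        cfg, geom = uniform_geom
        f = ConcentrationField(geom, 50, geom.total_length, 0.6)
        shrunk = FlowState(time=0.0, meniscus_position=geom.total_length / 2,
                           filled_volume=0.0, flow_rate_Q=0.0,
                           effective_viscosity=1e-3, stopped=True)
        with pytest.raises(TransportError):
            step_transport(f, shrunk, 0.1, cfg)


class TestUpdateMesh:
    def test_identity(self, uniform_geom):
        _, geom = uniform_geom
        f = ConcentrationField(geom, 50, 1e-3, 0.6)
        before = f.m_plasma.copy()
        update_mesh(f, 1e-3)
        assert np.array_equal(f.m_plasma, before)

    def test_node_velocities_linear_in_reference_coordinate(self, uniform_geom):
        # pinned inlet, meniscus-following outlet: node at X moves at X·ds
        _, geom = uniform_geom
        s0, s1 = 2e-3, 4e-3
        f = ConcentrationField(geom, 50, s0, 0.6)
        x_before = np.asarray(f.mapping(f.reference_nodes))
        update_mesh(f, s1)
        x_after = np.asarray(f.mapping(f.reference_nodes))
        displacement = x_after - x_before
        assert displacement[0] == 0.0
        assert displacement[-1] == pytest.approx(s1 - s0)
        # interior node at X = 0.5 moves at half the meniscus displacement
        mid = 25
        assert displacement[mid] == pytest.approx(0.5 * (s1 - s0), rel=1e-12)
        assert np.allclose(displacement, f.reference_nodes * (s1 - s0))

    @pytest.mark.parametrize("s1", [3e-3, 4.7e-3])
    def test_total_mass_preserved(self, uniform_geom, s1):
        _, geom = uniform_geom
        f = ConcentrationField(geom, 64, 2e-3, 0.37)
        f.m_plasma *= np.linspace(0.2, 1.0, 64)  # non-uniform profile
        m0, t0 = f.total_plasma(), f.m_total.sum()
        update_mesh(f, s1)
        assert f.total_plasma() == pytest.approx(m0, rel=1e-10)
        assert f.m_total.sum() == pytest.approx(t0, rel=1e-10)

    def test_nonpositive_length_rejected(self, uniform_geom):
        _, geom = uniform_geom
        f = ConcentrationField(geom, 16, 1e-3, 0.5)
        with pytest.raises(TransportError):
            update_mesh(f, 0.0)


class TestBarrier:
    def _run(self, eps, n=100, steps=1500, omega=0.98, D=0.0,
             clean_downstream=False):
        """Drive a fully wetted column through the junction.  The volumetric
        flux is throttled by the face passage factor κ each step, mirroring
        the coupled solver (a barrier only retains what the flow respects)."""
        cfg = make_uniform_config(diffusivity=D, omega_plasma=omega,
                                  eps_cells=eps)
        geom = ChainGeometry(cfg)
        f = ConcentrationField(geom, n, geom.total_length, omega)
        f.feed_omega = omega
        if clean_downstream:
            f.m_plasma[n // 2:] = f.m_total[n // 2:]
        apply_barrier(f, cfg.species, n // 2)
        for _ in range(steps):
            q = 2e-11 * f.junction_kappa()
            step_transport(f, full_domain_flow(geom, q), 0.1, cfg)
        return f

    def test_perfect_filter_keeps_downstream_clean(self):
        f = self._run(eps=0.0, clean_downstream=True)
        n = f.n_cells
        # zero up to the converged tolerance of the junction split
        assert np.all(f.omega_cells[n // 2:] <= 1e-10)
        # retained mass accumulates upstream of the junction
        assert f.omega_cells[n // 2 - 1] > 1.0 - f.feed_omega

    def test_transparent_barrier_matches_no_barrier(self):
        cfg = make_uniform_config(diffusivity=1e-10, omega_plasma=0.7,
                                  eps_cells=1.0)
        geom = ChainGeometry(cfg)
        n = 80
        with_b = ConcentrationField(geom, n, geom.total_length, 0.7)
        without = ConcentrationField(geom, n, geom.total_length, 0.7)
        with_b.m_plasma *= np.linspace(0.5, 1.0, n)
        without.m_plasma = with_b.m_plasma.copy()
        apply_barrier(with_b, cfg.species, n // 2)
        flow = full_domain_flow(geom, 1e-11)
        for _ in range(200):
            step_transport(with_b, flow, 0.1, cfg)
            step_transport(without, flow, 0.1, cfg)
        assert np.allclose(with_b.omega_plasma, without.omega_plasma, atol=1e-12)

    def test_dilute_steady_state_ratio_approaches_epsilon(self):
        # downstream/upstream cell concentration ratio → ε for a dilute feed
        eps = 0.0098
        f = self._run(eps=eps, omega=0.9998, steps=3000)
        n = f.n_cells
        ratio = f.omega_cells[n // 2 + 5] / f.omega_cells[n // 2 - 1]
        assert ratio == pytest.approx(eps, rel=0.05)


class TestRunSeparation:
    def test_pure_plasma_collected_equals_outlet_fill(self, chip):
        # single-species feed, transparent barrier: collected volume is
        # exactly the liquid that has passed the outlet entry face
        cfg = apply_parameters(chip, {"eps_cells": 1.0})
        import dataclasses

        species = tuple(
            dataclasses.replace(
                s,
                initial_mass_fraction_omega0=1.0 if s.name == "plasma" else 0.0,
            )
            for s in cfg.species
        )
        cfg = dataclasses.replace(cfg, species=species,
                                  operating=dataclasses.replace(
                                      cfg.operating, hematocrit=0.0))
        res = run_separation(cfg, t_end=6.0, n_cells=100, dt_max=0.5)
        geom = ChainGeometry(cfg)
        x_out = geom.entry_x[cfg.segment_index("outlet_channel")]
        v_past = (res.field._volume_vec(np.array([res.field.length]))[0]
                  - res.field._volume_vec(np.array([x_out]))[0]
                  + res.field.outflow_total)
        assert res.collected_ul == pytest.approx(m3_to_ul(v_past), rel=1e-9)

    def test_global_plasma_mass_conservation(self, chip):
        # plasma fed in = plasma in the domain + plasma that left the chip
        res = run_separation(chip, t_end=8.0, n_cells=150, dt_max=0.25)
        f = res.field
        v_in = res.trajectory.volumes[-1] + f.outflow_total
        plasma_in = chip.plasma.initial_mass_fraction_omega0 * v_in
        plasma_now = f.total_plasma() + f.outflow_plasma
        assert plasma_now == pytest.approx(plasma_in, rel=1e-8)

    def test_discrete_maximum_principle_without_barrier(self):
        # with a transparent barrier ω must stay within [feed, initial] bounds
        cfg = make_uniform_config(diffusivity=1e-9, omega_plasma=0.6,
                                  eps_cells=1.0, injected_ul=1e6)
        res = run_separation(cfg, t_end=3.0, n_cells=100, dt_max=0.25)
        om = res.field.omega_plasma
        assert np.all(om >= 0.6 - 1e-10)
        assert np.all(om <= 1.0 + 1e-10)

    def test_omega_bounded_with_barrier(self, chip):
        res = run_separation(chip, t_end=6.0, n_cells=100, dt_max=0.25)
        om = res.field.omega_plasma
        assert np.all(om >= -1e-12) and np.all(om <= 1 + 1e-12)

    def test_collected_volume_non_decreasing(self, chip):
        res = run_separation(chip, t_end=10.0, n_cells=100, dt_max=0.25)
        assert np.all(np.diff(res.series.collected_plasma_volume) >= 0)

    def test_downstream_cells_monotone_in_barrier_strength(self, chip):
        # stronger retention (smaller ε) must never increase the cell mass
        # reaching the outlet side
        geom = ChainGeometry(chip)
        x_j = geom.entry_x[chip.segment_index("hydrophobic_band")]
        passed = []
        for eps in (1.0, 0.5, 0.25, 0.0):
            cfg = apply_parameters(chip, {"eps_cells": max(eps, 1e-5)})
            if eps == 0.0:
                import dataclasses

                species = tuple(
                    s if s.name == "plasma"
                    else dataclasses.replace(s, barrier_transmission_epsilon=0.0)
                    for s in cfg.species
                )
                cfg = dataclasses.replace(cfg, species=species)
            res = run_separation(cfg, t_end=6.0, n_cells=100, dt_max=0.5)
            f = res.field
            cells_beyond = (
                f.m_total.sum() - f.total_plasma()
                - (f.m_total - f.m_plasma)[
                    : int(np.floor(x_j / (f.length / f.n_cells)))
                ].sum()
            )
            cells_out = f.outflow_total - f.outflow_plasma
            passed.append(cells_beyond + cells_out)
        assert all(a >= b - 1e-15 for a, b in zip(passed, passed[1:]))

    def test_grid_convergence_of_collected_volume(self, chip):
        cfg = apply_parameters(chip, {"tau_c": 500.0, "D_f": 1e-9})
        a = run_separation(cfg, t_end=12.0, n_cells=200, dt_max=0.5).collected_ul
        b = run_separation(cfg, t_end=12.0, n_cells=400, dt_max=0.5).collected_ul
        assert abs(a - b) <= 0.01 * b

    def test_snapshots_profile_shape(self, chip):
        res = run_separation(chip, t_end=5.0, n_cells=64, dt_max=0.5,
                             snapshot_times=(2.0, 4.0))
        assert len(res.snapshots) == 2
        t_min, x, om = res.snapshots[0]
        assert t_min == pytest.approx(2.0, abs=0.02)
        assert x.shape == om.shape == (64,)
        assert np.all(np.diff(x) > 0)


class TestSeparationSeries:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(TransportError):
            SeparationSeries(times=np.array([1.0, 1.0]),
                             collected_plasma_volume=np.array([0.0, 0.1]))

    def test_rejects_decreasing_volume(self):
        with pytest.raises(TransportError):
            SeparationSeries(times=np.array([1.0, 2.0]),
                             collected_plasma_volume=np.array([0.5, 0.1]))

    def test_interp_is_monotone(self):
        s = SeparationSeries(times=np.array([1.0, 2.0, 4.0]),
                             collected_plasma_volume=np.array([0.0, 1.0, 1.5]))
        t = np.linspace(0.5, 5.0, 40)
        v = s.interp(t)
        assert np.all(np.diff(v) >= 0)
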