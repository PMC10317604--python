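"""Plasma mass transport on the moving filled domain.

The multicomponent Fick flux reduces, for a two-species (plasma / cells)
isothermal constant-property mixture, to a single advection–diffusion equation
for the plasma mass fraction ω on the growing liquid column behind the
meniscus.  The moving mesh is the 1D reduction of a Laplace mesh equation:
with the inlet pinned and the outermost node following the meniscus, node
velocities stretch linearly in the reference coordinate X ∈ [0, 1].

Discretisation: finite volume on N cells uniform in X, implicit (backward
Euler) in time, first-order upwind advection with an exact swept-volume ALE
correction (so a uniform field stays exactly uniform on the moving mesh),
central diffusion.  The hydrophobic junction multiplies the species fluxes
across its face by the barrier transmission ε (plasma 1, cells ε_cells) and
throttles the bulk conductance by the face passage factor
κ = ω_plasma + ε·ω_cells — the concentration-polarisation feedback by which
retained cells slow the flow ("the cells act as the filter").

Densities of the two species are taken equal (constant ρ_l), so mass and
volume fractions coincide and all bookkeeping below is in volume units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.linalg import solve_banded

from .device import ChipConfig, SpeciesProperties, m3_to_ul, ul_to_m3
from .flow import (
    ChainGeometry,
    FlowState,
    FlowTrajectory,
    _flow_rate,
    _supply_volume,
    effective_viscosity,
    MIN_WETTED_LENGTH,
    POSITION_TOL,
)


class TransportError(RuntimeError):
    """Scheme failure: mesh tangling, negative mass fraction, bad input."""


@dataclass
class SeparationSeries:
    """(time, collected plasma volume) observations or predictions.

    times in minutes, volumes in µl; volumes non-negative and non-decreasing.
    """

    times: np.ndarray  # min
    collected_plasma_volume: np.ndarray  # µl
    source: str = "model"  # experiment | model | synthetic

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.collected_plasma_volume = np.asarray(
            self.collected_plasma_volume, dtype=float
        )
        if self.times.shape != self.collected_plasma_volume.shape:
            raise TransportError("times and volumes must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise TransportError("times must be strictly increasing")
        if np.any(self.collected_plasma_volume < -1e-12):
            raise TransportError("collected volumes must be non-negative")
        if self.times.size and np.any(np.diff(self.collected_plasma_volume) < -1e-9):
            raise TransportError("collected volumes must be non-decreasing")

    def interp(self, times_min: np.ndarray) -> np.ndarray:
        """Monotone piecewise-linear interpolation of the volumes."""
        return np.interp(np.asarray(times_min, dtype=float),
                         self.times, self.collected_plasma_volume)


class ConcentrationField:
    """Plasma content on the moving 1D domain.

    The reference grid is N cells uniform in X ∈ [0, 1]; the mapping to the
    physical coordinate is x(X, t) = X·s(t) with s the wetted length.  Each
    cell carries its plasma volume and its total material volume (equal to the
    geometric cell volume whenever the column is fully liquid-filled).
    """

    def __init__(
        self,
        geom: ChainGeometry,
        n_cells: int,
        length: float,
        omega0: float,
    ):
        if n_cells < 2:
            raise TransportError("need at least 2 cells")
        if length <= 0:
            raise TransportError("domain length must be positive")
        self.geom = geom
        self.n_cells = int(n_cells)
        self.length = float(length)
        vols = self.cell_volumes()
        self.m_total = vols.copy()
        self.m_plasma = omega0 * vols
        self.barrier_face: int | None = None
        self.barrier_eps: float = 1.0
        self.feed_omega: float = omega0
        self.outflow_plasma = 0.0
        self.outflow_total = 0.0

    # --- geometry ------------------------------------------------------------
    @property
    def reference_nodes(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_cells + 1)

    def mapping(self, X: np.ndarray | float) -> np.ndarray | float:
        """Reference → physical coordinate, x(X) = X·s (strictly increasing)."""
        return np.asarray(X) * self.length

    def face_positions(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_cells + 1)

    def cell_volumes(self, length: float | None = None) -> np.ndarray:
        s = self.length if length is None else length
        faces = np.linspace(0.0, s, self.n_cells + 1)
        w = self._volume_vec(faces)
        return np.diff(w)

    def _volume_vec(self, x: np.ndarray) -> np.ndarray:
        g = self.geom
        idx = np.clip(np.searchsorted(g.entry_x, x, side="right") - 1, 0,
                      len(g.segments) - 1)
        return g.entry_v[idx] + (x - g.entry_x[idx]) * g.areas[idx]

    def _area_vec(self, x: np.ndarray) -> np.ndarray:
        g = self.geom
        idx = np.clip(np.searchsorted(g.entry_x, x, side="right") - 1, 0,
                      len(g.segments) - 1)
        return g.areas[idx]

    # --- composition ---------------------------------------------------------
    @property
    def omega_plasma(self) -> np.ndarray:
        out = np.zeros(self.n_cells)
        filled = self.m_total > 0
        out[filled] = self.m_plasma[filled] / self.m_total[filled]
        return out

    @property
    def omega_cells(self) -> np.ndarray:
        out = np.zeros(self.n_cells)
        filled = self.m_total > 0
        out[filled] = 1.0 - self.m_plasma[filled] / self.m_total[filled]
        return out

    def total_plasma(self) -> float:
        return float(self.m_plasma.sum())

    def plasma_beyond(self, x_cut: float) -> float:
        """Plasma volume currently located downstream of lab position x_cut."""
        faces = self.face_positions()
        w = self._volume_vec(faces)
        w_cut = self._volume_vec(np.array([max(0.0, min(x_cut, self.length))]))[0]
        lo = np.maximum(w[:-1], w_cut)
        frac = np.clip((w[1:] - lo) / np.where(self.m_total > 0, self.m_total, 1.0),
                       0.0, 1.0)
        return float(np.sum(self.m_plasma * frac))

    def junction_kappa(self) -> float:
        """Passage factor κ = ω_p + ε·ω_c of the barrier face's upwind cell."""
        if self.barrier_face is None:
            return 1.0
        i = max(self.barrier_face - 1, 0)
        if self.m_total[i] <= 0:
            return 1.0
        om = self.m_plasma[i] / self.m_total[i]
        return om + self.barrier_eps * (1.0 - om)

    def copy(self) -> "ConcentrationField":
        new = ConcentrationField.__new__(ConcentrationField)
        new.__dict__.update(self.__dict__)
        new.m_total = self.m_total.copy()
        new.m_plasma = self.m_plasma.copy()
        return new


def apply_barrier(
    field: ConcentrationField,
    species: tuple[SpeciesProperties, ...],
    junction_index: int | None,
) -> ConcentrationField:
    """Attach the hydrophobic-junction barrier at mesh face ``junction_index``.

    Species fluxes across that face are scaled by their barrier transmission ε
    (plasma ε = 1 by construction; the non-plasma species supplies ε_cells);
    retained mass therefore accumulates in the cells upstream of the face.
    ``junction_index=None`` removes the barrier.  Returns the same field.
    """
    if junction_index is not None and not (
        0 < junction_index < field.n_cells
    ):
        raise TransportError("junction face must be interior to the domain")
    eps = 1.0
    for sp in species:
        if sp.name != "plasma":
            eps = sp.barrier_transmission_epsilon
    field.barrier_face = junction_index
    field.barrier_eps = eps
    return field


def update_mesh(field: ConcentrationField, new_length: float) -> ConcentrationField:
    """Stretch the mesh to ``new_length`` and remap the field conservatively.

    The 1D Laplace mesh equation with pinned inlet and meniscus-following
    outlet gives node velocities linear in X: the node at X moves at X times
    the meniscus speed.  The material field is remapped by exact overlap
    integration in volume measure, so total species mass is preserved; on
    growth, the newly swept tip region holds no material yet (it is filled by
    the transport fluxes, not by the mesh motion).
    """
    if new_length <= 0:
        raise TransportError("new_length must be positive")
    if new_length == field.length:
        return field
    s_old, s_new = field.length, float(new_length)
    n = field.n_cells
    old_w = field._volume_vec(np.linspace(0.0, s_old, n + 1))
    new_w = field._volume_vec(np.linspace(0.0, s_new, n + 1))

    def remap(mass: np.ndarray) -> np.ndarray:
        # density of `mass` per unit volume on old cells, integrated over new cells
        dens = np.where(np.diff(old_w) > 0, mass / np.maximum(np.diff(old_w), 1e-300), 0.0)
        cum = np.concatenate([[0.0], np.cumsum(mass)])

        def cum_at(w: np.ndarray) -> np.ndarray:
            wc = np.clip(w, old_w[0], old_w[-1])
            idx = np.clip(np.searchsorted(old_w, wc, side="right") - 1, 0, n - 1)
            return cum[idx] + dens[idx] * (wc - old_w[idx])

        return np.diff(cum_at(new_w))

    m_plasma = remap(field.m_plasma)
    m_total = remap(field.m_total)
    if np.any(np.diff(new_w) <= 0):
        raise TransportError("mesh tangling: mapping not strictly increasing")
    field.m_plasma = m_plasma
    field.m_total = m_total
    field.length = s_new
    return field


def step_transport(
    field: ConcentrationField,
    flow: FlowState,
    dt: float,
    config: ChipConfig,
) -> ConcentrationField:
    """Advance ω by one implicit finite-volume step on the moving domain.

    ``flow`` carries the step-end meniscus position (the new domain length)
    and the volumetric flow rate Q feeding the column.  The ALE mesh-motion
    correction uses exact swept volumes, upwind advection is implicit, and
    diffusion is central with a zero-flux meniscus face and a feed-composition
    ghost cell at the inlet while liquid is being supplied.
    """
    if dt <= 0:
        raise TransportError("dt must be positive")
    s_new = flow.meniscus_position
    if s_new < field.length - POSITION_TOL:
        raise TransportError("meniscus must not recede")
    n = field.n_cells
    q = max(0.0, flow.flow_rate_Q)

    X = field.reference_nodes
    v_old = field._volume_vec(X * field.length)
    v_new = field._volume_vec(X * s_new)
    vol_old = np.diff(v_old)
    vol_new = np.diff(v_new)
    if np.any(vol_new <= 0):
        raise TransportError("mesh tangling: non-positive cell volume")

    # expected growth vs supplied volume must agree (flow/transport coupling)
    growth = v_new[-1] - v_old[-1]
    q_dt = q * dt
    if growth > q_dt * (1 + 1e-6) + 1e-20:
        raise TransportError("domain growth exceeds supplied volume")

    # face advective transfer volumes (lab flux minus exact swept volume)
    sweep = v_new - v_old
    phi = q_dt - sweep  # per face, signed
    c = phi / dt  # advective rate per face

    # diffusion conductances at interior faces (step-end geometry)
    D = config.plasma.diffusivity_D_f
    dx = s_new / n
    faces_x = X * s_new
    G = np.zeros(n + 1)
    if D > 0:
        G[1:n] = D * field._area_vec(faces_x[1:n]) / dx

    # barrier: the plasma flux through the junction face is c·ω/κ (flux-ratio
    # split, implicit in ω so it self-limits as the face depletes); the cell
    # flux is the complement.  κ is iterated to self-consistency below, which
    # makes the split exact (a perfect filter passes exactly zero cells).
    # Diffusive exchange across the band is suppressed by ε.
    jf = field.barrier_face
    kappa = field.junction_kappa() if jf is not None else 1.0
    if jf is not None:
        G[jf] *= field.barrier_eps

    cp = np.maximum(c, 0.0)
    cm = np.maximum(-c, 0.0)

    feed = field.feed_omega
    inlet_open = q > 0.0
    G0 = 0.0
    if inlet_open and D > 0:
        G0 = D * field._area_vec(np.array([0.0]))[0] / (0.5 * dx)

    base_rhs = vol_old * field.omega_plasma  # old plasma mass per cell
    j = np.arange(1, n)
    omega = field.omega_plasma

    for _ in range(20):
        k_face = np.ones(n + 1)
        if jf is not None:
            k_face[jf] = 1.0 / max(kappa, 1e-12)

        diag = vol_new.copy()
        lower = np.zeros(n)
        upper = np.zeros(n)
        rhs = base_rhs.copy()

        # face j between cell j-1 and cell j, j = 1..n-1
        diag[:-1] += dt * (cp[j] * k_face[j] + G[j])  # outflow from cell j-1
        upper[:-1] = -dt * (cm[j] + G[j])
        diag[1:] += dt * (cm[j] + G[j])  # backward outflow from cell j
        lower[1:] = -dt * (cp[j] * k_face[j] + G[j])

        # inlet face (j = 0): advective feed + ghost-cell diffusion
        diag[0] += dt * (cm[0] + G0)
        rhs[0] += dt * (cp[0] * feed + G0 * feed)

        # meniscus / outlet face (j = n): upwind outflow, zero diffusive flux
        diag[-1] += dt * cp[n] * k_face[n]

        ab = np.zeros((3, n))
        ab[0, 1:] = upper[:-1]
        ab[1, :] = diag
        ab[2, :-1] = lower[1:]
        omega = solve_banded((1, 1), ab, rhs)

        if jf is None:
            break
        om_u = min(max(omega[jf - 1], 0.0), 1.0)
        kappa_new = om_u + field.barrier_eps * (1.0 - om_u)
        resid = kappa_new - kappa
        if abs(resid) <= 1e-12:
            kappa = kappa_new
            break
        # secant acceleration of the scalar fixed point κ = g(κ)
        if "_prev" in locals() and abs(resid - _prev[1]) > 1e-300:
            kappa_next = kappa - resid * (kappa - _prev[0]) / (resid - _prev[1])
            if not 0.0 < kappa_next <= 1.0:
                kappa_next = kappa_new
        else:
            kappa_next = kappa_new
        _prev = (kappa, resid)
        kappa = kappa_next

    if np.any(omega < -1e-10) or np.any(omega > 1.0 + 1e-10):
        raise TransportError(
            f"mass fraction out of [0,1]: min {omega.min()}, max {omega.max()}"
        )
    omega = np.clip(omega, 0.0, 1.0)

    m_plasma = omega * vol_new

    out_plasma = dt * cp[n] * omega[-1]
    field.outflow_plasma += out_plasma
    field.outflow_total += dt * cp[n]

    field.m_plasma = m_plasma
    field.m_total = vol_new.copy()
    field.length = s_new
    return field


@dataclass
class SeparationResult:
    """Bundle returned by :func:`run_separation`."""

    trajectory: FlowTrajectory
    series: SeparationSeries
    snapshots: list[tuple[float, np.ndarray, np.ndarray]]  # (t_min, x, omega)
    collected_ul: float
    field: ConcentrationField


def run_separation(
    config: ChipConfig,
    t_end: float,
    n_cells: int = 200,
    dt_max: float = 0.1,
    snapshot_times: tuple[float, ...] = (),
    output_interval: float = 6.0,
) -> SeparationResult:
    """Run the coupled flow + transport separation model (deterministic).

    Parameters
    ----------
    t_end : minutes of chip operation.
    n_cells : finite-volume cells on the moving domain.
    dt_max : maximum time step, s.
    snapshot_times : minutes at which to store (x, ω) profiles.
    output_interval : spacing of the collected-volume series, s.

    Collected plasma volume is the plasma mass that has passed the entry face
    of the outlet segment (the experiment's collection point), divided by the
    plasma density — i.e. plasma currently in the outlet segment plus plasma
    that has left the chip.
    """
    if t_end <= 0:
        raise TransportError("t_end must be positive")
    geom = ChainGeometry(config)
    t_end_s = t_end * 60.0

    # junction = entry face of the hydrophobic band; collection point = entry
    # face of the outlet segment (chains without a band have no junction;
    # without an outlet segment, collection is the chip-end outflow)
    band_idx = next(
        (i for i, s in enumerate(config.segments)
         if s.wettability_zone == "hydrophobic_band"),
        None,
    )
    x_junction = float(geom.entry_x[band_idx]) if band_idx is not None else None
    outlet_idx = next(
        (i for i, s in enumerate(config.segments)
         if s.kind == "outlet_channel"),
        None,
    )
    x_outlet = (float(geom.entry_x[outlet_idx]) if outlet_idx is not None
                else geom.total_length)

    feed = config.plasma.initial_mass_fraction_omega0
    field = ConcentrationField(geom, n_cells, MIN_WETTED_LENGTH, feed)
    field.feed_omega = feed

    traj = FlowTrajectory()
    t = 0.0
    v = geom.volume_to(field.length)
    was_stopped = was_bursting = False
    last_seg = 0

    out_times = [0.0]
    out_vols = [0.0]
    next_out = output_interval
    snaps: list[tuple[float, np.ndarray, np.ndarray]] = []
    snap_queue = sorted(snapshot_times)

    def collected_now() -> float:
        return field.plasma_beyond(x_outlet) + field.outflow_plasma

    def record_state(q, stopped):
        traj.states.append(
            FlowState(
                time=t,
                meniscus_position=field.length,
                filled_volume=v,
                flow_rate_Q=q,
                effective_viscosity=effective_viscosity(config.fluid, t),
                stopped=stopped,
            )
        )

    record_state(0.0, False)
    collected_max = 0.0
    max_steps = int(t_end_s / dt_max * 4) + 10_000
    for _ in range(max_steps):
        if t >= t_end_s - 1e-12:
            break
        x = field.length
        # barrier active once the meniscus has entered the band
        if x_junction is not None and x > x_junction + POSITION_TOL:
            jf = int(np.clip(round(x_junction / (x / n_cells)), 1, n_cells - 1))
            apply_barrier(field, config.species, jf)
            kappa = field.junction_kappa()
        else:
            apply_barrier(field, config.species, None)
            kappa = 1.0

        q, stopped, bursting = _flow_rate(geom, config, x, t, throttle=kappa)
        # supply can only sustain what remains; liquid that left the chip
        # counts against the injected sample too
        v_in = v + field.outflow_total
        avail = _supply_volume(config, t) - v_in
        fully_wetted = x >= geom.total_length - POSITION_TOL
        if v_in >= ul_to_m3(config.operating.injected_volume) - 1e-18:
            q = 0.0
            stopped = True

        if bursting and not was_bursting:
            traj.events.append((t, "barrier_burst"))
        if stopped and not was_stopped:
            traj.events.append((t, "flow_stop"))
        was_bursting, was_stopped = bursting, stopped

        dt = min(dt_max, t_end_s - t)
        if q > 0:
            # over one step the inlet can deliver the backlog plus the pump feed
            pump_q = ul_to_m3(config.operating.pump_rate) / 60.0
            q = min(q, max(0.0, avail) / dt + pump_q)
            q = min(q, max(0.0, _supply_volume(config, t + dt) - v_in) / dt)
            if not fully_wetted:
                # do not overrun the chip end in one step
                dv_cap = geom.total_volume - v
                if q * dt > dv_cap:
                    dt = max(dv_cap / q, 1e-6)

        if q > 0:
            dv = q * dt
            if not fully_wetted:
                v_new = min(v + dv, geom.total_volume)
                s_new = geom.x_of_volume(v_new)
                dv = v_new - v
                v = v_new
            else:
                s_new = field.length
                v += 0.0  # fully wetted: inflow leaves at the outlet
            flow_state = FlowState(
                time=t + dt,
                meniscus_position=s_new,
                filled_volume=v,
                flow_rate_Q=dv / dt if not fully_wetted else q,
                effective_viscosity=effective_viscosity(config.fluid, t),
                stopped=False,
            )
            step_transport(field, flow_state, dt, config)
        else:
            # stationary liquid: diffusion still acts
            flow_state = FlowState(
                time=t + dt,
                meniscus_position=field.length,
                filled_volume=v,
                flow_rate_Q=0.0,
                effective_viscosity=effective_viscosity(config.fluid, t),
                stopped=True,
            )
            if field.length > 10 * MIN_WETTED_LENGTH:
                step_transport(field, flow_state, dt, config)
        t += dt

        new_seg = geom.seg_index_at(field.length, advancing=True)
        if new_seg != last_seg:
            for sidx in range(last_seg + 1, new_seg + 1):
                traj.events.append((t, f"segment_entry:{config.segments[sidx].id}"))
            last_seg = new_seg
        record_state(q, q == 0.0)

        if t >= next_out - 1e-9 or t >= t_end_s - 1e-12:
            collected_max = max(collected_max, collected_now())
            out_times.append(t / 60.0)
            out_vols.append(m3_to_ul(collected_max))
            next_out += output_interval
        while snap_queue and t / 60.0 >= snap_queue[0] - 1e-9:
            snap_queue.pop(0)
            centers = 0.5 * (field.face_positions()[:-1] + field.face_positions()[1:])
            snaps.append((t / 60.0, centers.copy(), field.omega_plasma.copy()))
    else:
        raise TransportError("separation run exceeded the step budget")

    series = SeparationSeries(
        times=np.array(out_times[1:]),
        collected_plasma_volume=np.maximum.accumulate(np.array(out_vols[1:])),
        source="model",
    )
    return SeparationResult(
        trajectory=traj,
        series=series,
        snapshots=snaps,
        collected_ul=m3_to_ul(collected_max),
        field=field,
    )
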