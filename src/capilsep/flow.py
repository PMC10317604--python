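"""Quasi-1D capillary flow through the segment chain.

The 2D continuity + momentum balance is reduced to quasi-steady Poiseuille
(lubrication) flow driven by the Young–Laplace pressure of the advancing
meniscus, opposed by the hydrostatic head of the filled column and by the
viscous resistance of the wetted path.  A hydrophobic band acts as a
deterministic burst valve: passive flow stops while the net pressure at the
band is non-positive; a running syringe pump (a stiff flow source) forces the
band at the pump rate.  Coagulation enters as an exponential growth of the
effective viscosity, µ(t) = µ_l·exp(t/τ_c).

The integrator advances the *filled volume* (so volume bookkeeping equals the
flux integral exactly) with an adaptive explicit midpoint scheme and emits
events at segment boundaries and at barrier stop/burst.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .device import (
    ChipConfig,
    FluidProperties,
    Segment,
    ul_per_min_to_m3_per_s,
    ul_to_m3,
)

#: Minimum wetted length regularising the Washburn startup singularity, m.
MIN_WETTED_LENGTH = 1e-6

#: Absolute position tolerance of the integrator, m.
POSITION_TOL = 1e-7


class FlowError(RuntimeError):
    """Integration failure (non-finite state, invalid meniscus position)."""


def capillary_pressure(segment: Segment, fluid: FluidProperties) -> float:
    """Young–Laplace entry pressure of the meniscus in ``segment``, Pa.

    Cylindrical bore: 2σcosθ/R.  Rectangular channel: 2σcosθ(1/w + 1/d).
    Positive drives the wetting liquid forward; negative (θ > 90°) opposes —
    the sign carries the burst-valve physics.
    """
    ct = math.cos(math.radians(segment.contact_angle))
    sigma = fluid.surface_tension_sigma
    cs = segment.cross_section
    if cs.shape == "cylindrical":
        return 2.0 * sigma * ct / cs.radius
    return 2.0 * sigma * ct * (1.0 / cs.width + 1.0 / cs.depth)


def hydraulic_resistance(segment: Segment, filled_length: float, mu: float) -> float:
    """Poiseuille resistance of a partially filled segment, Pa·s/m³.

    Cylindrical: 8µL/(πR⁴).  Rectangular: 12µL/(w·d³·(1 − 0.63 d/w)) with the
    convention d ≤ w (dimensions swapped if needed).  Linear in the wetted
    length and in the viscosity; zero wetted length has zero resistance.
    """
    if filled_length < 0:
        raise FlowError("filled_length must be non-negative")
    if mu <= 0:
        raise FlowError("viscosity must be positive")
    if filled_length == 0.0:
        return 0.0
    cs = segment.cross_section
    if cs.shape == "cylindrical":
        return 8.0 * mu * filled_length / (math.pi * cs.radius**4)
    w, d = cs.width, cs.depth
    if d > w:
        w, d = d, w
    return 12.0 * mu * filled_length / (w * d**3 * (1.0 - 0.63 * d / w))


def effective_viscosity(fluid: FluidProperties, t: float) -> float:
    """Coagulation-corrected viscosity µ(t) = µ_l·exp(t/τ_c), Pa·s.

    τ_c = ∞ disables coagulation (µ = µ_l for all t).
    """
    if t < 0:
        raise FlowError("time must be non-negative")
    if math.isinf(fluid.coagulation_tau_c):
        return fluid.viscosity_mu_l
    return fluid.viscosity_mu_l * math.exp(t / fluid.coagulation_tau_c)


class ChainGeometry:
    """Cached arc-length ↔ volume ↔ height maps of the segment chain."""

    def __init__(self, config: ChipConfig):
        self.config = config
        self.segments = config.segments
        n = len(self.segments)
        self.entry_x = np.zeros(n + 1)
        self.entry_v = np.zeros(n + 1)
        self.entry_h = np.zeros(n + 1)
        for i, s in enumerate(self.segments):
            self.entry_x[i + 1] = self.entry_x[i] + s.length
            self.entry_v[i + 1] = self.entry_v[i] + s.volume
            self.entry_h[i + 1] = self.entry_h[i] + s.length * math.sin(
                math.radians(s.inclination)
            )
        self.total_length = float(self.entry_x[-1])
        self.total_volume = float(self.entry_v[-1])
        self.areas = np.array([s.area for s in self.segments])

    def seg_index_at(self, x: float, advancing: bool = False) -> int:
        """Segment index containing x; ``advancing`` biases boundary hits to
        the downstream segment (the wall the meniscus is about to enter)."""
        if x < -POSITION_TOL or x > self.total_length + POSITION_TOL:
            raise FlowError(f"meniscus position {x} outside the chain")
        x = min(max(x, 0.0), self.total_length)
        i = bisect_right(self.entry_x, x) - 1
        if advancing and i > 0 and x <= self.entry_x[i] + POSITION_TOL:
            pass  # bisect_right already biases to the downstream segment at a boundary
        return min(i, len(self.segments) - 1)

    def area_at(self, x: float) -> float:
        return float(self.areas[self.seg_index_at(x)])

    def volume_to(self, x: float) -> float:
        i = self.seg_index_at(x)
        return float(self.entry_v[i] + (x - self.entry_x[i]) * self.areas[i])

    def x_of_volume(self, v: float) -> float:
        v = min(max(v, 0.0), self.total_volume)
        i = min(bisect_right(self.entry_v, v) - 1, len(self.segments) - 1)
        return float(self.entry_x[i] + (v - self.entry_v[i]) / self.areas[i])

    def height_to(self, x: float) -> float:
        """Vertical rise of the filled path from inlet to x, m."""
        i = self.seg_index_at(x)
        s = self.segments[i]
        return float(
            self.entry_h[i]
            + (x - self.entry_x[i]) * math.sin(math.radians(s.inclination))
        )

    def chain_resistance(self, x: float, mu: float) -> float:
        """Total Poiseuille resistance of the wetted path [0, x], Pa·s/m³."""
        x = max(x, MIN_WETTED_LENGTH)
        i = self.seg_index_at(x)
        r = 0.0
        for j in range(i):
            r += hydraulic_resistance(self.segments[j], self.segments[j].length, mu)
        r += hydraulic_resistance(self.segments[i], x - self.entry_x[i], mu)
        return r


@dataclass(frozen=True)
class FlowState:
    """Instantaneous state of the filling front."""

    time: float  # s
    meniscus_position: float  # m, arc length from inlet
    filled_volume: float  # m³
    flow_rate_Q: float  # m³/s
    effective_viscosity: float  # Pa·s
    stopped: bool


@dataclass
class FlowTrajectory:
    """Time-ordered flow states plus labelled events."""

    states: list[FlowState] = field(default_factory=list)
    events: list[tuple[float, str]] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.meniscus_position for s in self.states])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([s.filled_volume for s in self.states])

    @property
    def flow_rates(self) -> np.ndarray:
        return np.array([s.flow_rate_Q for s in self.states])

    def final(self) -> FlowState:
        return self.states[-1]


def driving_pressure(config: ChipConfig, state: FlowState | float) -> float:
    """Net quasi-static driving pressure at the meniscus, Pa.

    Capillary entry pressure of the segment the meniscus is advancing into,
    minus the hydrostatic head ρ_l·g·Δh of the filled column.  A running pump
    is handled as a flow source in :func:`advance_flow`, not as a pressure
    term here.
    """
    x = state.meniscus_position if isinstance(state, FlowState) else float(state)
    geom = ChainGeometry(config)
    return _driving_pressure(geom, config.fluid, x)


def _driving_pressure(geom: ChainGeometry, fluid: FluidProperties, x: float) -> float:
    seg = geom.segments[geom.seg_index_at(x, advancing=True)]
    p_cap = capillary_pressure(seg, fluid)
    head = fluid.density_rho_l * fluid.gravity_g * geom.height_to(x)
    return p_cap - head


def _supply_volume(config: ChipConfig, t: float) -> float:
    """Liquid delivered to the inlet by time t, m³ (pump metering)."""
    v_inj = ul_to_m3(config.operating.injected_volume)
    if config.operating.pump_rate <= 0:
        return v_inj  # purely passive: full sample loaded at t = 0
    return min(v_inj, ul_per_min_to_m3_per_s(config.operating.pump_rate) * t)


def _flow_rate(
    geom: ChainGeometry,
    config: ChipConfig,
    x: float,
    t: float,
    throttle: float = 1.0,
) -> tuple[float, bool, bool]:
    """Instantaneous flow rate at meniscus position x and time t.

    Returns ``(Q, stopped, bursting)``.  ``throttle`` multiplies the passive
    conductance (used by the coupled separation solver for the junction
    passage factor; 1 for pure flow).
    """
    fluid = config.fluid
    mu = effective_viscosity(fluid, t)
    p_net = _driving_pressure(geom, fluid, x)
    resistance = geom.chain_resistance(x, mu)
    if resistance <= 0:
        raise FlowError("zero chain resistance with finite pressure")
    q_passive = throttle * max(0.0, p_net) / resistance

    pump_q = ul_per_min_to_m3_per_s(config.operating.pump_rate)
    supplied = _supply_volume(config, t)
    filled = geom.volume_to(x)
    supply_left = supplied - filled > -1e-18

    if p_net <= 0.0:
        seg = geom.segments[geom.seg_index_at(x, advancing=True)]
        at_barrier = seg.wettability_zone == "hydrophobic_band"
        if at_barrier and pump_q > 0 and supply_left and filled < ul_to_m3(
            config.operating.injected_volume
        ):
            return pump_q, False, True  # stiff pump forces the band: burst
        return 0.0, True, False

    if pump_q > 0 and filled >= supplied - 1e-18:
        # the chip would drink faster than the pump delivers: supply-limited
        q = min(q_passive, pump_q)
    else:
        q = q_passive
    if filled >= ul_to_m3(config.operating.injected_volume) - 1e-18:
        q = 0.0  # sample exhausted
    return q, q == 0.0, False


def advance_flow(config: ChipConfig, t_end: float, dt_max: float = 0.1) -> FlowTrajectory:
    """Integrate the filling front to ``t_end`` seconds (deterministic).

    Advances the filled volume with an adaptive explicit midpoint scheme,
    emitting events at segment entries and at barrier stop/burst; ends early
    when the meniscus reaches the chip outlet.
    """
    if t_end <= 0:
        raise FlowError("t_end must be positive")
    geom = ChainGeometry(config)
    traj = FlowTrajectory()

    t = 0.0
    v = geom.volume_to(MIN_WETTED_LENGTH)
    flux_integral = 0.0
    v0 = v
    last_seg = 0
    was_stopped = False
    was_bursting = False

    def record(t, x, v, q, stopped):
        traj.states.append(
            FlowState(
                time=t,
                meniscus_position=x,
                filled_volume=v,
                flow_rate_Q=q,
                effective_viscosity=effective_viscosity(config.fluid, t),
                stopped=stopped,
            )
        )

    x = geom.x_of_volume(v)
    q, stopped, bursting = _flow_rate(geom, config, x, t)
    record(t, x, v, q, stopped)

    max_steps = 2_000_000
    for _ in range(max_steps):
        if t >= t_end or x >= geom.total_length - POSITION_TOL:
            break
        q1, stopped, bursting = _flow_rate(geom, config, x, t)

        if bursting and not was_bursting:
            traj.events.append((t, "barrier_burst"))
        was_bursting = bursting
        if stopped and not was_stopped:
            traj.events.append((t, "barrier_stop" if _driving_pressure(
                geom, config.fluid, x) <= 0 else "supply_exhausted"))
        was_stopped = stopped

        if q1 <= 0.0:
            # stationary; pressure field is time-invariant apart from viscosity,
            # which only decays Q further — fast-forward in dt_max chunks
            t = min(t + 50 * dt_max, t_end)
            record(t, x, v, 0.0, True)
            continue

        # step limited by dt_max, segment boundary and 2% relative volume growth
        seg_i = geom.seg_index_at(x, advancing=True)
        v_next_boundary = geom.entry_v[seg_i + 1]
        dv_limit = max(v * 0.02, geom.total_volume * 1e-6)
        dt = min(dt_max, dv_limit / q1, t_end - t)
        # midpoint evaluation
        v_mid = min(v + 0.5 * dt * q1, geom.total_volume)
        q2, _, _ = _flow_rate(geom, config, geom.x_of_volume(v_mid), t + 0.5 * dt)
        q_step = q2 if q2 > 0 else q1
        dv = dt * q_step
        if v + dv > v_next_boundary and v_next_boundary - v > 1e-21:
            # land exactly on the segment boundary
            dt = (v_next_boundary - v) / q_step
            dv = v_next_boundary - v
        v = min(v + dv, geom.total_volume)
        flux_integral += dv
        t += dt
        x = geom.x_of_volume(v)

        new_seg = geom.seg_index_at(x, advancing=True)
        if new_seg != last_seg:
            for s in range(last_seg + 1, new_seg + 1):
                traj.events.append((t, f"segment_entry:{geom.segments[s].id}"))
            last_seg = new_seg

        if not np.isfinite(v) or not np.isfinite(t):
            raise FlowError("non-finite state during flow integration")
        record(t, x, v, q_step, False)
    else:
        raise FlowError("flow integration exceeded the step budget")

    if x >= geom.total_length - POSITION_TOL:
        traj.events.append((t, "outlet_reached"))
    # volume bookkeeping equals the flux integral by construction
    assert abs((v - v0) - flux_integral) <= 1e-12 * max(v, 1e-30)
    return traj
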