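"""Calibration of the reduced-order model to a separation time series.

The free parameters (any subset of hydrophilic/hydrophobic contact angle,
effective dispersion D_f, coagulation time constant τ_c, and the cell barrier
transmission ε_cells) are fitted by bounded derivative-free local search
(Nelder–Mead from a fixed documented start) minimising the mean squared error
between the model's collected-plasma volumes, interpolated to the observation
times, and the observations.  The cell transmission is normally not part of
the time-series fit: the cell-count table constrains it independently and
analytically (ε = output/input for the reference analyte).

In the reference-replication fit only {τ_c, D_f} are free: four observation
points cannot identify more, and the remaining parameters are fixed device
properties.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .device import ChipConfig, ConfigError, Segment
from .metrics import CellCountTable, FitReport, fit_report
from .transport import SeparationSeries, run_separation

#: Parameter registry: name -> (transform, default bounds, default initial)
#: Transform "log" optimises log10(value); bounds/initial on the natural scale.
PARAMETERS = {
    "tau_c": ("log", (60.0, 6.0e4), 900.0),  # s
    "D_f": ("log", (1.0e-11, 1.0e-7), 1.0e-9),  # m²/s
    "eps_cells": ("log", (1.0e-5, 1.0), 1.0e-2),
    "hydrophilic_angle": ("linear", (5.0, 85.0), 40.0),  # degrees
    "hydrophobic_angle": ("linear", (95.0, 175.0), 110.0),  # degrees
}

#: Free parameters of the reference-replication fit.
REPLICATION_FREE = ("tau_c", "D_f")


class CalibrationError(RuntimeError):
    pass


def apply_parameters(config: ChipConfig, params: dict[str, float]) -> ChipConfig:
    """Return a copy of ``config`` with the named model parameters replaced."""
    unknown = set(params) - set(PARAMETERS)
    if unknown:
        raise CalibrationError(f"unknown parameter(s) {sorted(unknown)}")
    fluid = config.fluid
    if "tau_c" in params:
        fluid = dataclasses.replace(fluid, coagulation_tau_c=params["tau_c"])
    species = list(config.species)
    if "D_f" in params:
        species = [
            dataclasses.replace(s, diffusivity_D_f=params["D_f"]) for s in species
        ]
    if "eps_cells" in params:
        species = [
            s if s.name == "plasma"
            else dataclasses.replace(s, barrier_transmission_epsilon=params["eps_cells"])
            for s in species
        ]
    segments = list(config.segments)
    for key, zone in (
        ("hydrophilic_angle", "hydrophilic_coated"),
        ("hydrophobic_angle", "hydrophobic_band"),
    ):
        if key in params:
            segments = [
                dataclasses.replace(s, contact_angle=params[key])
                if s.wettability_zone == zone else s
                for s in segments
            ]
    return dataclasses.replace(
        config,
        fluid=fluid,
        species=tuple(species),
        segments=tuple(segments),
    )


@dataclass
class CalibrationSpec:
    """What to fit and how.

    free_parameters : names from the parameter registry.
    bounds / initial : per-parameter overrides of the registry defaults.
    n_cells, dt_max : forward-model resolution used during the fit.
    xatol_rel, fatol : optimiser tolerances; max_evaluations caps model runs.
    """

    free_parameters: tuple[str, ...] = REPLICATION_FREE
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    n_cells: int = 200
    dt_max: float = 0.5
    xatol_rel: float = 5e-3
    fatol: float = 1e-5
    max_evaluations: int = 200

    def __post_init__(self) -> None:
        for name in self.free_parameters:
            if name not in PARAMETERS:
                raise CalibrationError(f"unknown free parameter {name!r}")
            lo, hi = self.bounds.get(name, PARAMETERS[name][1])
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise CalibrationError(f"bounds for {name!r} must be finite and ordered")
            x0 = self.initial.get(name, PARAMETERS[name][2])
            if not lo <= x0 <= hi:
                raise CalibrationError(f"initial value for {name!r} outside bounds")

    def param_bounds(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, PARAMETERS[name][1])

    def param_initial(self, name: str) -> float:
        return self.initial.get(name, PARAMETERS[name][2])


@dataclass
class CalibrationResult:
    fitted: dict[str, float]
    report: FitReport
    converged: bool
    n_evaluations: int
    loss_initial: float
    loss_optimum: float
    config: ChipConfig  # calibrated configuration
    extrapolated_completion_time: float | None = None


def _to_internal(value: float, name: str) -> float:
    return math.log10(value) if PARAMETERS[name][0] == "log" else value


def _from_internal(z: float, name: str, bounds: tuple[float, float]) -> float:
    v = 10.0**z if PARAMETERS[name][0] == "log" else z
    return min(max(v, bounds[0]), bounds[1])


def calibrate(
    config: ChipConfig,
    observations: SeparationSeries,
    spec: CalibrationSpec | None = None,
) -> CalibrationResult:
    """Fit the free parameters to the observed collected-volume series.

    Deterministic given identical inputs; returns the best point found even
    if the evaluation budget is exhausted (flagged via ``converged``).
    """
    spec = spec or CalibrationSpec()
    obs_t = observations.times
    obs_v = observations.collected_plasma_volume
    if obs_t.size < 2:
        raise CalibrationError("need at least 2 observations")
    t_end = float(obs_t.max())
    names = list(spec.free_parameters)
    bounds_nat = [spec.param_bounds(n) for n in names]
    z0 = np.array([_to_internal(spec.param_initial(n), n) for n in names])
    z_bounds = [
        tuple(sorted((_to_internal(lo, n), _to_internal(hi, n))))
        for n, (lo, hi) in zip(names, bounds_nat)
    ]

    n_evals = 0

    def model_volumes(params: dict[str, float]) -> np.ndarray:
        cfg = apply_parameters(config, params)
        result = run_separation(
            cfg, t_end=t_end, n_cells=spec.n_cells, dt_max=spec.dt_max
        )
        return result.series.interp(obs_t)

    def loss(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        params = {
            n: _from_internal(zi, n, b) for n, zi, b in zip(names, z, bounds_nat)
        }
        try:
            pred = model_volumes(params)
        except Exception:
            return 1e6
        return float(np.mean((obs_v - pred) ** 2))

    loss0 = loss(z0)
    res = minimize(
        loss,
        z0,
        method="Nelder-Mead",
        bounds=z_bounds,
        options={
            "maxfev": spec.max_evaluations,
            "xatol": spec.xatol_rel,
            "fatol": spec.fatol,
            "adaptive": False,
        },
    )
    z_best = res.x if res.fun <= loss0 else z0
    fitted = {
        n: _from_internal(zi, n, b) for n, zi, b in zip(names, z_best, bounds_nat)
    }
    pred = model_volumes(fitted)
    report = fit_report(obs_v, pred)
    return CalibrationResult(
        fitted=fitted,
        report=report,
        converged=bool(res.success),
        n_evaluations=n_evals,
        loss_initial=loss0,
        loss_optimum=float(min(res.fun, loss0)),
        config=apply_parameters(config, fitted),
    )


def fit_transmission(counts: CellCountTable, analyte: str = "RBC") -> float:
    """Barrier transmission of the cellular phase from the count table.

    ε = output/input for the reference analyte — the purity datum constrains
    it independently of the time-series fit.
    """
    inp, out = counts.get(analyte)
    if inp <= 0:
        raise CalibrationError(f"analyte {analyte!r} has non-positive input count")
    return out / inp


def completion_time_from_series(
    times_min: np.ndarray,
    collected_ul: np.ndarray,
    available_ul: float,
    completion_fraction: float,
) -> float:
    """First time at which collected/available reaches the target fraction.

    Linear interpolation between the bracketing samples; ``inf`` (the explicit
    non-attainment sentinel) if the series never crosses.
    """
    if not 0.0 <= completion_fraction <= 1.0:
        raise CalibrationError("completion_fraction must lie in [0, 1]")
    if completion_fraction == 0.0:
        return 0.0
    target = completion_fraction * available_ul
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(collected_ul, dtype=float)
    above = v >= target
    if not above.any():
        return math.inf
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (target - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extrapolate_completion(
    config: ChipConfig,
    result: CalibrationResult,
    completion_fraction: float = 0.999,
    hard_cap: float = 500.0,
    n_cells: int = 200,
    dt_max: float = 1.0,
) -> float:
    """Time (min) for the calibrated model to reach the completion fraction.

    Runs the calibrated configuration forward until collected volume over the
    available plasma (injected volume × (1 − HCT)) crosses the target, or the
    hard cap is reached — in which case the explicit sentinel ``inf`` is
    returned, never a fabricated time.
    """
    if completion_fraction == 0.0:
        return 0.0
    cfg = result.config
    available = cfg.operating.injected_volume * cfg.operating.plasma_fraction
    sim = run_separation(cfg, t_end=hard_cap, n_cells=n_cells, dt_max=dt_max,
                         output_interval=30.0)
    t = completion_time_from_series(
        sim.series.times,
        sim.series.collected_plasma_volume,
        available,
        completion_fraction,
    )
    result.extrapolated_completion_time = t
    return t
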