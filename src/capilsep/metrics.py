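"""Separation performance metrics.

Purity per CBC analyte (1 − output/input), plasma recovery fraction relative
to the plasma content of the injected sample, and the model-validation
statistics: coefficient of determination R² and mean squared error.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CBC_ANALYTES = ("WBC", "RBC", "HGB", "HCT")

#: Analytes whose printed units are ambiguous (not counts per µl); their
#: purity is still computed but flagged.
UNIT_AMBIGUOUS_ANALYTES = ("HGB", "HCT")


class MetricsError(ValueError):
    pass


@dataclass
class CellCountTable:
    """Per-analyte input/output values from a cell counter.

    rows: (analyte, input_value, output_value) in the counter's printed units
    (counts per µl for WBC/RBC; instrument units for HGB/HCT).
    """

    rows: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for analyte, inp, out in self.rows:
            if analyte in seen:
                raise MetricsError(f"duplicate analyte {analyte!r}")
            seen.add(analyte)
            if inp < 0 or out < 0:
                raise MetricsError(f"analyte {analyte!r}: values must be >= 0")

    def analytes(self) -> list[str]:
        return [r[0] for r in self.rows]

    def get(self, analyte: str) -> tuple[float, float]:
        for a, inp, out in self.rows:
            if a == analyte:
                return inp, out
        raise KeyError(analyte)

    def purity_by_analyte(self) -> dict[str, float]:
        return {a: plasma_purity(inp, out) for a, inp, out in self.rows if inp > 0}


@dataclass
class FitReport:
    """Goodness of fit between an experimental and a modelled series."""

    r_squared: float
    mse: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise MetricsError("r_squared cannot exceed 1")
        if self.mse < 0:
            raise MetricsError("mse must be non-negative")

    @property
    def n(self) -> int:
        return len(self.residuals)


def plasma_purity(input_count: float, output_count: float) -> float:
    """Plasma purity for one analyte: 1 − output/input.

    Monotone decreasing in the output count and invariant to rescaling both
    counts by a common factor.  A value below 0 (output above input) signals a
    data error and is returned unclamped with a warning.
    """
    if input_count <= 0:
        raise MetricsError("input_count must be strictly positive")
    if output_count < 0:
        raise MetricsError("output_count must be non-negative")
    value = 1.0 - output_count / input_count
    if output_count > input_count:
        warnings.warn(
            "output count exceeds input count: negative purity signals a data error",
            stacklevel=2,
        )
    elif value < 0.0:
        value = 0.0  # exact floating underflow only
    return value


def recovery_fraction(
    collected_ul: float,
    injected_ul: float,
    hematocrit: float,
    rounded_hct: bool = False,
) -> float:
    """Percentage of the injected sample's plasma that was collected.

    100·collected/(injected·(1 − HCT)).  With ``rounded_hct`` the haematocrit
    is first rounded to 2 decimals (the convention under which the reference
    dataset's headline recovery is reproduced); the choice is logged.
    """
    if injected_ul <= 0:
        raise MetricsError("injected volume must be positive")
    if not 0.0 <= hematocrit < 1.0:
        raise MetricsError("hematocrit must lie in [0, 1)")
    if collected_ul < 0:
        raise MetricsError("collected volume must be non-negative")
    hct = round(hematocrit, 2) if rounded_hct else hematocrit
    logger.info(
        "recovery_fraction: using %s haematocrit %.4f",
        "rounded" if rounded_hct else "exact",
        hct,
    )
    available = injected_ul * (1.0 - hct)
    if collected_ul > available:
        warnings.warn(
            "collected volume exceeds available plasma: dilution or measurement error",
            stacklevel=2,
        )
    return 100.0 * collected_ul / available


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (reporting convention for percentages)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def mse(experimental: np.ndarray, modelled: np.ndarray) -> float:
    """Mean squared error Σ(x_exp − x_model)²/N."""
    x = np.asarray(experimental, dtype=float)
    m = np.asarray(modelled, dtype=float)
    if x.shape != m.shape or x.ndim != 1:
        raise MetricsError("series must be 1D and of equal length")
    if x.size < 1:
        raise MetricsError("need at least one point")
    return float(np.mean((x - m) ** 2))


def r_squared(experimental: np.ndarray, modelled: np.ndarray) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    SS_tot is taken about the mean of the experimental series.  A constant
    experimental series has SS_tot = 0 and raises.
    """
    x = np.asarray(experimental, dtype=float)
    m = np.asarray(modelled, dtype=float)
    if x.shape != m.shape or x.ndim != 1 or x.size < 2:
        raise MetricsError("series must be 1D, equal length, at least 2 points")
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot <= 0:
        raise MetricsError("experimental series is constant (SS_tot = 0)")
    ss_res = float(np.sum((x - m) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared_difference_form(experimental: np.ndarray, modelled: np.ndarray) -> float:
    """The displayed difference-of-sums form of R²:
    (Σ(x_exp − x_avg)² − Σ(x_exp − x_model)²) / Σ(x_exp − x_avg)².

    Algebraically identical to :func:`r_squared`; kept as an independent
    evaluation path for the equivalence property test.
    """
    x = np.asarray(experimental, dtype=float)
    m = np.asarray(modelled, dtype=float)
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot <= 0:
        raise MetricsError("experimental series is constant (SS_tot = 0)")
    ss_res = float(np.sum((x - m) ** 2))
    return (ss_tot - ss_res) / ss_tot


def fit_report(experimental: np.ndarray, modelled: np.ndarray) -> FitReport:
    x = np.asarray(experimental, dtype=float)
    m = np.asarray(modelled, dtype=float)
    return FitReport(
        r_squared=r_squared(x, m),
        mse=mse(x, m),
        residuals=x - m,
    )
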