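"""Synthetic study data with the statistical structure the analysis assumes.

Two generators mirror the two study tables: a saturating separation series
(forward model at ground-truth parameters plus additive truncated-Gaussian
measurement noise, projected back to monotone non-decreasing volumes) and a
cell-count table (Poisson sampling of the counted aliquot at the true input
concentration and at input × transmission for the output).  A single integer
seed controls all randomness.

The noise models are package choices — the study reports no replicate
variability — and every parameter of them is configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .calibration import apply_parameters
from .device import ChipConfig
from .metrics import CellCountTable
from .transport import SeparationSeries, run_separation


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Ground truth and sampling model for synthetic data.

    ground_truth_parameters : model parameters applied to the chip config
        (names from the calibration parameter registry).
    observation_times : min, strictly increasing.
    volume_noise_sd : µl, additive Gaussian truncated at 0 total volume.
    count_means : per-analyte true input concentration, counts per µl.
    true_transmission : per-analyte transmitted fraction ε.
    aliquot_volume : µl counted by the instrument (Poisson denominator).
    seed : integer; recorded in all outputs.
    """

    ground_truth_parameters: dict[str, float] = field(default_factory=dict)
    observation_times: tuple[float, ...] = (3.0, 7.0, 9.0, 12.0)
    volume_noise_sd: float = 0.1
    count_means: dict[str, float] = field(
        default_factory=lambda: {"WBC": 7.11e3, "RBC": 4.42e6}
    )
    true_transmission: dict[str, float] = field(
        default_factory=lambda: {"WBC": 7.0e1 / 7.11e3, "RBC": 4.34e4 / 4.42e6}
    )
    count_sampling: str = "poisson"
    aliquot_volume: float = 1.0
    seed: int = 0
    n_cells: int = 200
    dt_max: float = 0.1

    def __post_init__(self) -> None:
        if self.volume_noise_sd < 0:
            raise SyntheticError("volume noise sd must be >= 0")
        if self.aliquot_volume <= 0:
            raise SyntheticError("aliquot volume must be > 0")
        if any(t2 <= t1 for t1, t2 in zip(self.observation_times,
                                          self.observation_times[1:])):
            raise SyntheticError("observation times must be strictly increasing")

    def digest(self) -> str:
        payload = {
            k: (sorted(v.items()) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _isotonic_projection(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-decreasing sequences."""
    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    # (value, weight) blocks
    vals = list(y)
    wts = [1.0] * n
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            w = wts[i] + wts[i + 1]
            v = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / w
            vals[i:i + 2] = [v]
            wts[i:i + 2] = [w]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty(n)
    pos = 0
    for v, w in zip(vals, wts):
        out[pos:pos + int(w)] = v
        pos += int(w)
    return out


def noiseless_series(spec: SyntheticSpec, config: ChipConfig) -> SeparationSeries:
    """Forward model at the ground-truth parameters, sampled at the
    observation times (no noise)."""
    cfg = apply_parameters(config, spec.ground_truth_parameters)
    sim = run_separation(
        cfg,
        t_end=float(max(spec.observation_times)),
        n_cells=spec.n_cells,
        dt_max=spec.dt_max,
    )
    times = np.asarray(spec.observation_times, dtype=float)
    return SeparationSeries(
        times=times,
        collected_plasma_volume=sim.series.interp(times),
        source="synthetic",
    )


def generate_series(
    spec: SyntheticSpec,
    config: ChipConfig,
    clean: SeparationSeries | None = None,
) -> SeparationSeries:
    """Synthetic separation series: model + truncated-Gaussian noise,
    isotonically projected to restore monotone volumes.  Reproducible given
    the seed.  A precomputed noiseless series may be passed to amortise the
    forward model over many replicates."""
    if clean is None:
        clean = noiseless_series(spec, config)
    if spec.volume_noise_sd == 0:
        return clean
    rng = np.random.default_rng(spec.seed)
    noisy = clean.collected_plasma_volume + rng.normal(
        0.0, spec.volume_noise_sd, size=clean.times.shape
    )
    noisy = np.maximum(noisy, 0.0)  # volumes cannot be negative
    noisy = _isotonic_projection(noisy)
    return SeparationSeries(
        times=clean.times, collected_plasma_volume=noisy, source="synthetic"
    )


def generate_counts(spec: SyntheticSpec) -> CellCountTable:
    """Synthetic cell-count table: Poisson counts on the counted aliquot.

    input ~ Poisson(mean·aliquot)/aliquot, output ~ Poisson(mean·ε·aliquot)/
    aliquot, per analyte.  Reproducible given the seed."""
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for analyte in sorted(spec.count_means):
        mean = spec.count_means[analyte]
        eps = spec.true_transmission.get(analyte, 0.0)
        inp = rng.poisson(mean * spec.aliquot_volume) / spec.aliquot_volume
        out = rng.poisson(mean * eps * spec.aliquot_volume) / spec.aliquot_volume
        rows.append((analyte, float(inp), float(out)))
    return CellCountTable(rows=rows)
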