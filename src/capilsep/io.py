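"""CSV/JSON I/O, run manifests, and the reference-replication driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationSpec,
    calibrate,
    extrapolate_completion,
    fit_transmission,
)
from .device import ChipConfig, default_chip
from .metrics import (
    CellCountTable,
    MetricsError,
    UNIT_AMBIGUOUS_ANALYTES,
    recovery_fraction,
    round_half_away,
)
from .transport import SeparationSeries, TransportError

logger = logging.getLogger(__name__)


class IOError_(ValueError):
    pass


# --- packaged reference dataset ----------------------------------------------

def _data_path(name: str):
    return resources.files("capilsep.data").joinpath(name)


def reference_series() -> SeparationSeries:
    """The reference experimental separation series shipped with the package
    (collected plasma volume at 3/7/9/12 min)."""
    with resources.as_file(_data_path("reference_series.csv")) as p:
        return read_series(p)


def reference_counts() -> CellCountTable:
    """The reference CBC table (inlet whole blood vs outlet plasma)."""
    with resources.as_file(_data_path("reference_counts.csv")) as p:
        return read_counts(p)


def reference_chip() -> ChipConfig:
    """The packaged default chip configuration file, parsed."""
    from .device import load_config

    with resources.as_file(_data_path("default_chip.json")) as p:
        return load_config(p)


# --- series ------------------------------------------------------------------

def read_series(path: str | Path) -> SeparationSeries:
    """Read a separation series CSV (columns time_min, volume_ul)."""
    df = pd.read_csv(path)
    for col in ("time_min", "volume_ul"):
        if col not in df.columns:
            raise IOError_(f"{path}: missing required column {col!r}")
    times = df["time_min"].to_numpy(dtype=float)
    vols = df["volume_ul"].to_numpy(dtype=float)
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise IOError_(
                f"{path}: non-increasing time at data row {i + 1} "
                f"(t={times[i]} after t={times[i - 1]})"
            )
    try:
        return SeparationSeries(times=times, collected_plasma_volume=vols,
                                source="experiment")
    except TransportError as exc:
        raise IOError_(f"{path}: {exc}") from exc


def write_series(series: SeparationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": series.times, "volume_ul": series.collected_plasma_volume}
    ).to_csv(path, index=False)


# --- cell counts -------------------------------------------------------------

def read_counts(path: str | Path) -> CellCountTable:
    """Read a cell-count CSV (columns analyte, input_value, output_value)."""
    df = pd.read_csv(path)
    for col in ("analyte", "input_value", "output_value"):
        if col not in df.columns:
            raise IOError_(f"{path}: missing required column {col!r}")
    try:
        return CellCountTable(
            rows=[
                (str(r.analyte), float(r.input_value), float(r.output_value))
                for r in df.itertuples()
            ]
        )
    except MetricsError as exc:
        raise IOError_(f"{path}: {exc}") from exc


def write_counts(counts: CellCountTable, path: str | Path) -> None:
    pd.DataFrame(
        counts.rows, columns=["analyte", "input_value", "output_value"]
    ).to_csv(path, index=False)


# --- manifest ----------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record written next to every output set."""

    subcommand: str
    config_hash: str
    input_hashes: dict[str, str]
    seed: int | None
    tool_version: str
    timestamp: str

    def write(self, output_dir: str | Path) -> Path:
        out = Path(output_dir) / "manifest.json"
        out.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                  sort_keys=True) + "\n")
        return out


def _hash_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def make_manifest(
    subcommand: str,
    config: ChipConfig,
    input_files: dict[str, str | Path] | None = None,
    seed: int | None = None,
) -> RunManifest:
    from .device import config_to_dict

    return RunManifest(
        subcommand=subcommand,
        config_hash=_hash_obj(config_to_dict(config)),
        input_hashes={k: _hash_file(v) for k, v in (input_files or {}).items()},
        seed=seed,
        tool_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


# --- reference replication driver --------------------------------------------

def replicate_paper(
    output_dir: str | Path,
    completion_fraction: float = 0.999,
    max_evaluations: int = 200,
) -> RunManifest:
    """Run the full reference analysis and write a single JSON summary.

    Pipeline: default chip → calibrate {τ_c, D_f} against the packaged
    separation series → purity/recovery report against the packaged CBC table
    → completion-time extrapolation.  Summary keys: recovery_pct,
    purity_by_analyte, r_squared, mse, completion_time_99_9.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    stage = "load reference data"
    try:
        series = reference_series()
        counts = reference_counts()
        chip = default_chip()

        stage = "calibrate"
        spec = CalibrationSpec(max_evaluations=max_evaluations)
        result = calibrate(chip, series, spec)

        stage = "report"
        purity = {
            a: p for a, p in counts.purity_by_analyte().items()
        }
        recovery = recovery_fraction(
            collected_ul=float(series.collected_plasma_volume[-1]),
            injected_ul=chip.operating.injected_volume,
            hematocrit=chip.operating.hematocrit,
            rounded_hct=True,
        )

        stage = "extrapolate completion"
        completion = extrapolate_completion(chip, result, completion_fraction)

        summary = {
            "recovery_pct": round_half_away(recovery, 1),
            "purity_by_analyte": {a: purity[a] for a in sorted(purity)},
            "unit_ambiguous_analytes": list(UNIT_AMBIGUOUS_ANALYTES),
            "r_squared": result.report.r_squared,
            "mse": result.report.mse,
            "fitted_parameters": result.fitted,
            "epsilon_cells_from_counts": fit_transmission(counts, "RBC"),
            "completion_time_99_9": (
                None if math.isinf(completion) else completion
            ),
            "completion_attained": not math.isinf(completion),
        }
        (output_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"replication failed at stage: {stage}") from exc

    manifest = make_manifest("replicate-paper", chip)
    manifest.write(output_dir)
    return manifest
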