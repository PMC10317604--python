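"""Chip, fluid and species definitions for the plasma-separation model.

The device is described as an ordered chain of flow segments (inlet channel →
vertical well, split into a lower hydrophilic section, a hydrophobic band and
an upper hydrophilic section → outlet channel).  Every physical symbol used by
the flow and transport solvers lives here: segment geometry and wettability,
bulk fluid properties (viscosity, density, surface tension, gravity, the
coagulation time constant), per-species transport properties (effective
diffusivity, feed mass fraction, barrier transmission) and the operating
conditions (injected volume, pump rate, haematocrit).

All quantities are SI internally; microlitres and minutes appear only at I/O
boundaries (see :func:`ul_to_m3` and friends).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

# unit conversions (I/O boundary only)
UL_TO_M3 = 1e-9
M3_TO_UL = 1e9
MIN_TO_S = 60.0
S_TO_MIN = 1.0 / 60.0


def ul_to_m3(v_ul: float) -> float:
    """Convert a volume in microlitres to cubic metres."""
    return v_ul * UL_TO_M3


def m3_to_ul(v_m3: float) -> float:
    """Convert a volume in cubic metres to microlitres."""
    return v_m3 * M3_TO_UL


def ul_per_min_to_m3_per_s(q: float) -> float:
    return q * UL_TO_M3 / MIN_TO_S


def m3_per_s_to_ul_per_min(q: float) -> float:
    return q * M3_TO_UL * MIN_TO_S


class ConfigError(ValueError):
    """A chip configuration violated its schema or an invariant."""


SEGMENT_KINDS = ("horizontal_channel", "vertical_well", "outlet_channel")
WETTABILITY_ZONES = ("hydrophilic_coated", "hydrophobic_band", "native")


@dataclass(frozen=True)
class CrossSection:
    """Channel cross-section: rectangular(width, depth) or cylindrical(radius).

    Dimensions in metres.
    """

    shape: str  # "rectangular" | "cylindrical"
    width: float = 0.0
    depth: float = 0.0
    radius: float = 0.0

    def __post_init__(self) -> None:
        if self.shape == "rectangular":
            if self.width <= 0 or self.depth <= 0:
                raise ConfigError("rectangular cross-section needs width > 0 and depth > 0")
        elif self.shape == "cylindrical":
            if self.radius <= 0:
                raise ConfigError("cylindrical cross-section needs radius > 0")
        else:
            raise ConfigError(f"unknown cross-section shape {self.shape!r}")

    @property
    def area(self) -> float:
        """Flow area in m²."""
        if self.shape == "rectangular":
            return self.width * self.depth
        return math.pi * self.radius**2


def rectangular(width: float, depth: float) -> CrossSection:
    return CrossSection(shape="rectangular", width=width, depth=depth)


def cylindrical(radius: float) -> CrossSection:
    return CrossSection(shape="cylindrical", radius=radius)


@dataclass(frozen=True)
class Segment:
    """One element of the flow chain.

    Parameters
    ----------
    id : str
        Label, e.g. ``"inlet_channel"``.
    kind : str
        One of ``horizontal_channel``, ``vertical_well``, ``outlet_channel``.
    length : float
        Arc length along the flow path, m.
    cross_section : CrossSection
    contact_angle : float
        Effective advancing contact angle, degrees; wetting if < 90.
    inclination : float
        Degrees from horizontal; +90 is vertical upward flow.
    wettability_zone : str
        One of ``hydrophilic_coated``, ``hydrophobic_band``, ``native``.
    """

    id: str
    kind: str
    length: float
    cross_section: CrossSection
    contact_angle: float
    inclination: float = 0.0
    wettability_zone: str = "native"

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ConfigError(f"segment {self.id!r}: unknown kind {self.kind!r}")
        if self.wettability_zone not in WETTABILITY_ZONES:
            raise ConfigError(
                f"segment {self.id!r}: unknown wettability zone {self.wettability_zone!r}"
            )
        if self.length <= 0:
            raise ConfigError(f"segment {self.id!r}: length must be > 0")
        if not 0.0 < self.contact_angle < 180.0:
            raise ConfigError(
                f"segment {self.id!r}: contact angle must lie in (0, 180) degrees"
            )
        if not -90.0 <= self.inclination <= 90.0:
            raise ConfigError(f"segment {self.id!r}: inclination must lie in [-90, 90]")

    @property
    def area(self) -> float:
        return self.cross_section.area

    @property
    def volume(self) -> float:
        return self.area * self.length


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of the sample liquid.

    viscosity_mu_l : Pa·s — effective (low-shear) viscosity µ_l of whole blood.
    density_rho_l : kg/m³ — density ρ_l.
    surface_tension_sigma : N/m — surface tension σ.
    gravity_g : m/s² — gravitational acceleration g.
    coagulation_tau_c : s — time constant of exponential viscosity growth
        µ(t) = µ_l·exp(t/τ_c); ``inf`` disables coagulation.
    """

    viscosity_mu_l: float = 0.012
    density_rho_l: float = 1060.0
    surface_tension_sigma: float = 0.058
    gravity_g: float = 9.81
    coagulation_tau_c: float = math.inf

    def __post_init__(self) -> None:
        for name in ("viscosity_mu_l", "density_rho_l", "surface_tension_sigma", "gravity_g"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"fluid property {name} must be strictly positive")
        if not self.coagulation_tau_c > 0:
            raise ConfigError("coagulation_tau_c must be > 0 (inf disables coagulation)")


@dataclass(frozen=True)
class SpeciesProperties:
    """Transported species: the wetting plasma phase or the cellular phase.

    diffusivity_D_f : m²/s — effective axial dispersion coefficient D^f.
    molecular_weight_M : kg/mol — nominal; eliminated by the binary-mixture
        reduction (kept for configuration completeness).
    initial_mass_fraction_omega0 : feed mass fraction ω0.
    barrier_transmission_epsilon : fraction ε of the species that crosses the
        hydrophobic junction (plasma: 1; cells: the measured transmitted
        fraction, output/input count ratio).
    """

    name: str
    diffusivity_D_f: float
    initial_mass_fraction_omega0: float
    barrier_transmission_epsilon: float = 1.0
    molecular_weight_M: float = 0.066  # albumin-scale placeholder, unused by solvers

    def __post_init__(self) -> None:
        if self.diffusivity_D_f < 0:
            raise ConfigError(f"species {self.name!r}: diffusivity must be >= 0")
        if not 0.0 <= self.initial_mass_fraction_omega0 <= 1.0:
            raise ConfigError(f"species {self.name!r}: ω0 must lie in [0, 1]")
        if not 0.0 <= self.barrier_transmission_epsilon <= 1.0:
            raise ConfigError(f"species {self.name!r}: ε must lie in [0, 1]")


@dataclass(frozen=True)
class OperatingConditions:
    """Run conditions: injected sample volume, pump metering rate, haematocrit.

    Volumes in µl and rates in µl/min (I/O-facing convention); converted to SI
    by the solvers.
    """

    injected_volume: float = 10.0  # µl
    pump_rate: float = 0.8  # µl/min; 0 = purely passive
    hematocrit: float = 0.399
    run_duration: float = 12.0  # min

    def __post_init__(self) -> None:
        if self.injected_volume <= 0:
            raise ConfigError("injected_volume must be > 0")
        if self.pump_rate < 0:
            raise ConfigError("pump_rate must be >= 0")
        if not 0.0 <= self.hematocrit < 1.0:
            raise ConfigError("hematocrit must lie in [0, 1)")
        if self.run_duration <= 0:
            raise ConfigError("run_duration must be > 0")

    @property
    def plasma_fraction(self) -> float:
        """Plasma volume fraction of the injected sample, 1 − HCT."""
        return 1.0 - self.hematocrit


@dataclass(frozen=True)
class ChipConfig:
    """The complete device + fluid + species + operating configuration."""

    segments: tuple[Segment, ...]
    fluid: FluidProperties
    species: tuple[SpeciesProperties, ...]
    operating: OperatingConditions

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigError("segment chain must be non-empty")
        names = [s.name for s in self.species]
        if names.count("plasma") != 1:
            raise ConfigError("exactly one species must be named 'plasma'")
        total = sum(s.initial_mass_fraction_omega0 for s in self.species)
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(
                f"species mass fractions must sum to 1 (got {total!r})"
            )

    # --- convenience accessors -------------------------------------------------
    @property
    def plasma(self) -> SpeciesProperties:
        return next(s for s in self.species if s.name == "plasma")

    @property
    def cells(self) -> SpeciesProperties | None:
        return next((s for s in self.species if s.name != "plasma"), None)

    def segment_index(self, seg_id: str) -> int:
        for i, s in enumerate(self.segments):
            if s.id == seg_id:
                return i
        raise KeyError(seg_id)

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    @property
    def total_volume(self) -> float:
        return sum(s.volume for s in self.segments)

    def segment_entry_positions(self) -> list[float]:
        """Arc-length position of each segment's entry face, plus the chip end."""
        pos = [0.0]
        for s in self.segments:
            pos.append(pos[-1] + s.length)
        return pos

    def segment_at(self, x: float) -> tuple[int, Segment]:
        """Segment containing arc-length position x (entry-inclusive)."""
        if x < 0 or x > self.total_length * (1 + 1e-12):
            raise ConfigError(f"position {x} outside the segment chain")
        acc = 0.0
        for i, s in enumerate(self.segments):
            if x <= acc + s.length or i == len(self.segments) - 1:
                return i, s
            acc += s.length
        raise AssertionError("unreachable")


# --- the reference device -----------------------------------------------------

#: Nominal geometry of the reference chip.  Printed device constants: bottom
#: channel depth 180 µm, top channel depth 100 µm, well height 4 mm with a 1 mm
#: hydrophobic band, 10 µl input, 0.8 µl/min pump, HCT 0.399.  Channel lengths
#: and widths and the well bore are nominal mm-scale values chosen once for the
#: reference device (see docs/methods.md).
DEFAULT_GEOMETRY = {
    "inlet_length": 3.0e-3,
    "inlet_width": 2.5e-4,
    "inlet_depth": 1.8e-4,
    "well_radius": 2.8e-4,
    "well_lower_length": 2.5e-3,
    "band_length": 1.0e-3,
    "well_upper_length": 0.5e-3,
    "outlet_length": 5.0e-3,
    "outlet_width": 1.2e-3,
    "outlet_depth": 1.0e-4,
}

#: Default effective contact angles (calibration parameters; initial values).
DEFAULT_ANGLES = {"hydrophilic": 40.0, "hydrophobic": 110.0, "native": 100.0}

#: Default effective axial dispersion coefficient for both species, m²/s.
DEFAULT_DIFFUSIVITY = 1.0e-9

#: Default cell transmission across the hydrophobic junction: the measured
#: RBC output/input count ratio of the reference dataset.
DEFAULT_CELL_TRANSMISSION = 4.34e4 / 4.42e6


def default_chip(
    hematocrit: float = 0.399,
    coagulation_tau_c: float = math.inf,
    diffusivity: float = DEFAULT_DIFFUSIVITY,
    cell_transmission: float = DEFAULT_CELL_TRANSMISSION,
    hydrophilic_angle: float = DEFAULT_ANGLES["hydrophilic"],
    hydrophobic_angle: float = DEFAULT_ANGLES["hydrophobic"],
) -> ChipConfig:
    """The reference chip: 5-segment chain with a hydrophobic band in the well.

    Returns the device used throughout the package: a horizontal inlet channel
    (180 µm deep), a vertical cylindrical well of total height 4 mm whose top
    1 mm carries the hydrophobic band (split lower-hydrophilic / band /
    upper-hydrophilic), and a horizontal outlet channel (100 µm deep).
    """
    g = DEFAULT_GEOMETRY
    segs = (
        Segment(
            id="inlet_channel",
            kind="horizontal_channel",
            length=g["inlet_length"],
            cross_section=rectangular(g["inlet_width"], g["inlet_depth"]),
            contact_angle=hydrophilic_angle,
            inclination=0.0,
            wettability_zone="hydrophilic_coated",
        ),
        Segment(
            id="well_lower",
            kind="vertical_well",
            length=g["well_lower_length"],
            cross_section=cylindrical(g["well_radius"]),
            contact_angle=hydrophilic_angle,
            inclination=90.0,
            wettability_zone="hydrophilic_coated",
        ),
        Segment(
            id="hydrophobic_band",
            kind="vertical_well",
            length=g["band_length"],
            cross_section=cylindrical(g["well_radius"]),
            contact_angle=hydrophobic_angle,
            inclination=90.0,
            wettability_zone="hydrophobic_band",
        ),
        Segment(
            id="well_upper",
            kind="vertical_well",
            length=g["well_upper_length"],
            cross_section=cylindrical(g["well_radius"]),
            contact_angle=hydrophilic_angle,
            inclination=90.0,
            wettability_zone="hydrophilic_coated",
        ),
        Segment(
            id="outlet_channel",
            kind="outlet_channel",
            length=g["outlet_length"],
            cross_section=rectangular(g["outlet_width"], g["outlet_depth"]),
            contact_angle=hydrophilic_angle,
            inclination=0.0,
            wettability_zone="hydrophilic_coated",
        ),
    )
    fluid = FluidProperties(coagulation_tau_c=coagulation_tau_c)
    species = (
        SpeciesProperties(
            name="plasma",
            diffusivity_D_f=diffusivity,
            initial_mass_fraction_omega0=1.0 - hematocrit,
            barrier_transmission_epsilon=1.0,
        ),
        SpeciesProperties(
            name="cells",
            diffusivity_D_f=diffusivity,
            initial_mass_fraction_omega0=hematocrit,
            barrier_transmission_epsilon=cell_transmission,
        ),
    )
    operating = OperatingConditions(hematocrit=hematocrit)
    return ChipConfig(segments=segs, fluid=fluid, species=species, operating=operating)


# --- (de)serialisation --------------------------------------------------------

_FLUID_DEFAULTS = FluidProperties()
_OPERATING_DEFAULTS = OperatingConditions()


def _cross_section_from_dict(d: dict, seg_id: str) -> CrossSection:
    try:
        shape = d["shape"]
    except KeyError as exc:
        raise ConfigError(f"segment {seg_id!r}: cross_section missing 'shape'") from exc
    if shape == "rectangular":
        return rectangular(float(d["width"]), float(d["depth"]))
    if shape == "cylindrical":
        return cylindrical(float(d["radius"]))
    raise ConfigError(f"segment {seg_id!r}: unknown cross-section shape {shape!r}")


def _segment_from_dict(d: dict) -> Segment:
    seg_id = d.get("id", "<unnamed>")
    for req in ("id", "kind", "length", "cross_section", "contact_angle"):
        if req not in d:
            raise ConfigError(f"segment {seg_id!r}: missing required field {req!r}")
    return Segment(
        id=d["id"],
        kind=d["kind"],
        length=float(d["length"]),
        cross_section=_cross_section_from_dict(d["cross_section"], seg_id),
        contact_angle=float(d["contact_angle"]),
        inclination=float(d.get("inclination", 0.0)),
        wettability_zone=d.get("wettability_zone", "native"),
    )


def _with_defaults(d: dict, defaults, label: str) -> dict:
    base = asdict(defaults)
    unknown = set(d) - set(base)
    if unknown:
        raise ConfigError(f"{label}: unknown field(s) {sorted(unknown)}")
    for k, v in base.items():
        if k not in d:
            logger.info("config %s: field %r not given, using default %r", label, k, v)
    out = dict(base)
    out.update(d)
    # JSON has no inf; accept the strings "inf"/"Infinity" for tau_c
    if "coagulation_tau_c" in out and isinstance(out["coagulation_tau_c"], str):
        out["coagulation_tau_c"] = float(out["coagulation_tau_c"])
    return out


def config_to_dict(config: ChipConfig) -> dict:
    """Plain-dict (JSON/YAML ready) representation of a ChipConfig."""
    d = asdict(config)
    d["segments"] = [
        {**seg, "cross_section": {k: v for k, v in seg["cross_section"].items()
                                  if not (isinstance(v, float) and v == 0.0) or k == "shape"}}
        for seg in d["segments"]
    ]
    fluid = d["fluid"]
    if math.isinf(fluid["coagulation_tau_c"]):
        fluid["coagulation_tau_c"] = "inf"
    return d


def config_from_dict(d: dict) -> ChipConfig:
    if "segments" not in d or not d["segments"]:
        raise ConfigError("config: missing required field 'segments'")
    segments = tuple(_segment_from_dict(s) for s in d["segments"])
    fluid = FluidProperties(**_with_defaults(d.get("fluid", {}), _FLUID_DEFAULTS, "fluid"))
    if "species" not in d:
        raise ConfigError("config: missing required field 'species'")
    species = []
    for sd in d["species"]:
        if "name" not in sd:
            raise ConfigError("species entry missing required field 'name'")
        kwargs = dict(sd)
        species.append(SpeciesProperties(**kwargs))
    operating = OperatingConditions(
        **_with_defaults(d.get("operating", {}), _OPERATING_DEFAULTS, "operating")
    )
    return ChipConfig(
        segments=segments, fluid=fluid, species=tuple(species), operating=operating
    )


def load_config(path: str | Path) -> ChipConfig:
    """Load a chip configuration from a JSON or YAML file.

    Unspecified fluid/operating fields take documented defaults (logged at INFO).
    Raises :class:`ConfigError` naming the offending field or segment.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return config_from_dict(data)


def write_config(config: ChipConfig, path: str | Path) -> None:
    """Write a chip configuration as pretty-printed JSON (round-trips exactly)."""
    path = Path(path)
    path.write_text(json.dumps(config_to_dict(config), indent=2, sort_keys=True) + "\n")
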