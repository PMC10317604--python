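import math

import numpy as np
import pytest

from capilsep.device import (
    ChipConfig,
    FluidProperties,
    OperatingConditions,
    Segment,
    SpeciesProperties,
    cylindrical,
    default_chip,
    rectangular,
)
from capilsep.flow import ChainGeometry


@pytest.fixture(scope="session")
def chip() -> ChipConfig:
    return default_chip()


def make_uniform_config(
    length: float = 1e-2,
    width: float = 1e-3,
    depth: float = 2e-4,
    contact_angle: float = 60.0,
    diffusivity: float = 0.0,
    omega_plasma: float = 0.6,
    eps_cells: float = 0.0098,
    viscosity: float = 1.5e-3,
    surface_tension: float = 0.05,
    injected_ul: float = 1e6,
    pump_rate: float = 0.0,
) -> ChipConfig:
    """Single horizontal rectangular segment: the clean oracle geometry."""
    seg = Segment(
        id="channel",
        kind="horizontal_channel",
        length=length,
        cross_section=rectangular(width, depth),
        contact_angle=contact_angle,
        inclination=0.0,
        wettability_zone="hydrophilic_coated",
    )
    species = [
        SpeciesProperties(
            name="plasma",
            diffusivity_D_f=diffusivity,
            initial_mass_fraction_omega0=omega_plasma,
        )
    ]
    if omega_plasma < 1.0:
        species.append(
            SpeciesProperties(
                name="cells",
                diffusivity_D_f=diffusivity,
                initial_mass_fraction_omega0=1.0 - omega_plasma,
                barrier_transmission_epsilon=eps_cells,
            )
        )
    return ChipConfig(
        segments=(seg,),
        fluid=FluidProperties(
            viscosity_mu_l=viscosity, surface_tension_sigma=surface_tension
        ),
        species=tuple(species),
        operating=OperatingConditions(
            injected_volume=injected_ul, pump_rate=pump_rate, hematocrit=1 - omega_plasma
        ),
    )


def make_vertical_config(
    radius: float = 2e-4,
    contact_angle: float = 30.0,
    length: float | None = None,
) -> ChipConfig:
    """Single vertical cylindrical capillary (Jurin-rise geometry)."""
    fluid = FluidProperties(viscosity_mu_l=5e-3)
    h_jurin = (
        2 * fluid.surface_tension_sigma * math.cos(math.radians(contact_angle))
        / (fluid.density_rho_l * fluid.gravity_g * radius)
    )
    seg = Segment(
        id="capillary",
        kind="vertical_well",
        length=length or 2 * h_jurin,
        cross_section=cylindrical(radius),
        contact_angle=contact_angle,
        inclination=90.0,
        wettability_zone="hydrophilic_coated",
    )
    sp = (SpeciesProperties(name="plasma", diffusivity_D_f=0.0,
                            initial_mass_fraction_omega0=1.0),)
    return ChipConfig(
        segments=(seg,),
        fluid=fluid,
        species=sp,
        operating=OperatingConditions(injected_volume=1e6, pump_rate=0.0,
                                      hematocrit=0.0),
    )


@pytest.fixture(scope="session")
def uniform_geom():
    cfg = make_uniform_config()
    return cfg, ChainGeometry(cfg)


@pytest.fixture(scope="session")
def calibrated(chip):
    """Full reference calibration of {tau_c, D_f}; shared across tests."""
    from capilsep.calibration import CalibrationSpec, calibrate
    from capilsep.io import reference_series

    return calibrate(chip, reference_series(), CalibrationSpec())
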