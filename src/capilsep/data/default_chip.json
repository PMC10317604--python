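{
  "fluid": {
    "coagulation_tau_c": "inf",
    "density_rho_l": 1060.0,
    "gravity_g": 9.81,
    "surface_tension_sigma": 0.058,
    "viscosity_mu_l": 0.012
  },
  "operating": {
    "hematocrit": 0.399,
    "injected_volume": 10.0,
    "pump_rate": 0.8,
    "run_duration": 12.0
  },
  "segments": [
    {
      "contact_angle": 40.0,
      "cross_section": {
        "depth": 0.00018,
        "shape": "rectangular",
        "width": 0.00025
      },
      "id": "inlet_channel",
      "inclination": 0.0,
      "kind": "horizontal_channel",
      "length": 0.003,
      "wettability_zone": "hydrophilic_coated"
    },
    {
      "contact_angle": 40.0,
      "cross_section": {
        "radius": 0.00028,
        "shape": "cylindrical"
      },
      "id": "well_lower",
      "inclination": 90.0,
      "kind": "vertical_well",
      "length": 0.0025,
      "wettability_zone": "hydrophilic_coated"
    },
    {
      "contact_angle": 110.0,
      "cross_section": {
        "radius": 0.00028,
        "shape": "cylindrical"
      },
      "id": "hydrophobic_band",
      "inclination": 90.0,
      "kind": "vertical_well",
      "length": 0.001,
      "wettability_zone": "hydrophobic_band"
    },
    {
      "contact_angle": 40.0,
      "cross_section": {
        "radius": 0.00028,
        "shape": "cylindrical"
      },
      "id": "well_upper",
      "inclination": 90.0,
      "kind": "vertical_well",
      "length": 0.0005,
      "wettability_zone": "hydrophilic_coated"
    },
    {
      "contact_angle": 40.0,
      "cross_section": {
        "depth": 0.0001,
        "shape": "rectangular",
        "width": 0.0012
      },
      "id": "outlet_channel",
      "inclination": 0.0,
      "kind": "outlet_channel",
      "length": 0.005,
      "wettability_zone": "hydrophilic_coated"
    }
  ],
  "species": [
    {
      "barrier_transmission_epsilon": 1.0,
      "diffusivity_D_f": 1e-09,
      "initial_mass_fraction_omega0": 0.601,
      "molecular_weight_M": 0.066,
      "name": "plasma"
    },
    {
      "barrier_transmission_epsilon": 0.009819004524886878,
      "diffusivity_D_f": 1e-09,
      "initial_mass_fraction_omega0": 0.399,
      "molecular_weight_M": 0.066,
      "name": "cells"
    }
  ]
}
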