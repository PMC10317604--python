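# Methods

`capilsep` models a passive microfluidic chip that separates plasma from a
10 µl drop of whole blood. The device is a horizontal inlet channel (180 µm
deep) feeding a vertical cylindrical well whose wall wettability is patterned:
a hydrophilic lower section, a 1 mm hydrophobic band near the top, and a
hydrophilic upper section leading into a shallow outlet channel (100 µm deep).
Surfactant-treated (wetting) surfaces pull the sample through the chip by
capillarity; the hydrophobic band stops the advancing whole-blood meniscus and
retains the cellular phase while plasma passes, so nearly cell-free plasma
accumulates at the outlet. A syringe pump meters the sample into the open
inlet port at 0.8 µl/min; gravity acts against the rise through the well.

## Flow model

The momentum balance is reduced to quasi-steady lubrication (Poiseuille) flow
in a one-dimensional segment chain. At meniscus arc position `x` the flow rate
is

    Q(t) = max(0, P_net(x)) / R(x, t),
    P_net = 2σ·cosθ(x)·C(x) − ρ_l·g·Δh(x),

where `C` is the cross-section curvature factor (1/R for a cylindrical bore,
1/w + 1/d for a rectangular channel), `θ` the effective advancing contact
angle of the segment being entered, and `Δh` the vertical rise of the filled
path. `R` is the series sum of segment Poiseuille resistances (8µL/πR⁴ and
12µL/(w·d³(1 − 0.63 d/w))) over the wetted path. The Washburn startup
singularity is regularised by a 1 µm minimum wetted length — far below any
measured quantity.

Three mechanisms modulate `Q`:

- **Supply metering.** The pump delivers at most `pump_rate`·t (capped at the
  injected volume) into the open inlet port; the chip draws the smaller of
  its passive capillary rate and what has been delivered. `pump_rate = 0`
  models a pre-loaded reservoir (fully passive operation).
- **Burst valve.** The hydrophobic band's entry pressure is negative; passive
  flow stops there (a stop event). While the pump is still metering, it acts
  as a stiff flow source and forces the band at the pump rate (a burst
  event). This is deterministic by design.
- **Coagulation.** The effective viscosity grows as µ(t) = µ_l·exp(t/τ_c)
  (τ_c = ∞ disables it). A single-exponential law is the simplest monotone
  slowdown consistent with the observed late-time deceleration; the
  functional form is a package choice and τ_c a calibration parameter.

The integrator advances the filled **volume** (the wetted position follows
from the inverse cumulative-volume map), so the volume bookkeeping equals the
flux integral to machine precision; an adaptive explicit midpoint rule with
event landing at segment boundaries keeps steps within 2 % volume growth.

## Plasma transport and the barrier

Blood is treated as a binary mixture of "plasma" and "cells" with equal,
constant densities — mass and volume fractions then coincide. Under the
isothermal, constant-property assumptions, the multicomponent Fick flux
reduces to one advection–diffusion equation for the plasma fraction ω on the
growing liquid column. `D_f` is an *effective axial dispersion* coefficient
(shear-induced dispersion of cells, ~10⁻⁹ m²/s scale, not a molecular
diffusivity); it is never printed for this device and is the second
calibration parameter.

The moving domain is handled with a 1D dynamic mesh: with the inlet pinned
and the last node following the meniscus, the mesh-equation reduction gives
node velocities linear in the reference coordinate X ∈ [0, 1] (the node at X
moves at X times the meniscus speed). The finite-volume discretisation (N
cells uniform in X) uses exact swept volumes for the arbitrary
Lagrangian–Eulerian correction, implicit (backward Euler) time stepping,
first-order upwind advection and central diffusion, with a zero-diffusive-flux
meniscus face and a feed-composition ghost cell at the inlet while liquid is
supplied. The implicit upwind operator is an M-matrix, so ω ∈ [0, 1] holds
unconditionally and a uniform field is preserved exactly on the moving mesh.

At the hydrophobic junction (the band's entry face) species flux is selective:
cells cross with transmission ε (measured independently as the output/input
RBC count ratio, ≈ 0.0098), plasma with transmission 1. Two consequences are
built in:

- **Flux-ratio split.** The plasma flux through the face is c·ω/κ and the
  cell flux c·ε·(1−ω)/κ with κ = ω + ε(1−ω), so the two sum to the volumetric
  flux c. κ is iterated to self-consistency within each implicit step
  (secant-accelerated scalar fixed point), which makes a perfect filter
  (ε = 0) pass exactly zero cells.
- **Polarisation throttle.** The bulk conductance is multiplied by the face
  passage factor κ: as retained cells pack against the band, κ falls and the
  flow slows — the retained cells are themselves the filter. Back-diffusion
  (D_f) relaxes the packed layer, so D_f has first-order leverage on the
  sustained collection rate.

The barrier operator is flux-consistent only when the driving flow respects
the throttle (as the coupled solver does); driving a jammed junction with an
arbitrary external flux would force the complement species through by
incompressibility.

Collected plasma volume is the plasma mass that has passed the entry face of
the outlet segment (the experimental collection point) divided by the plasma
density: plasma currently in the outlet channel plus plasma that has left the
chip.

Because the barrier is *designed* to concentrate cells beyond the feed value,
the discrete maximum principle (ω bounded by the initial and feed values)
holds for barrier-transparent runs (ε = 1); with an active barrier only
ω ∈ [0, 1] applies.

## Parameters and defaults

Printed device constants are used verbatim: channel depths 180 µm / 100 µm,
well height 4 mm with the 1 mm band, 10 µl injected volume, 0.8 µl/min pump
rate, haematocrit 0.399. Quantities the study does not print are package
defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| µ_l | 12 mPa·s | effective whole-blood viscosity at the device's ~10 s⁻¹ shear (blood is strongly shear-thinning; the high-shear 3–4 mPa·s value would fill the chip in seconds) |
| ρ_l | 1060 kg/m³ | whole blood |
| σ | 0.058 N/m | plasma/air |
| θ hydrophilic / hydrophobic / native | 40° / 110° / 100° | surfactant-treated vs native PDMS; initial values of calibration parameters |
| inlet channel | 3 × 0.25 mm, depth 0.18 mm | nominal |
| well bore radius | 0.28 mm | nominal; see below |
| well split | 2.5 mm lower + 1 mm band + 0.5 mm upper | band near the top |
| outlet channel | 5 × 1.2 mm, depth 0.1 mm | nominal |
| ε_cells | 0.0098 | measured RBC transmission |
| D_f | 10⁻⁹ m²/s | effective dispersion scale; calibration initial value |
| τ_c | ∞ (off); calibration start 900 s | coagulation time constant |
| n_cells / dt_max | 200 / 0.1 s | passes the 1 % grid- and step-convergence checks; calibration evaluates at dt_max = 0.5 s, which changes predictions by < 0.1 % |

The nominal free geometry was set so the device operates in the regime the
measured series implies. Mass balance pins this tightly: with 0.8 µl/min
metering, collecting 1 µl of plasma by minute 3 requires the dead volume
upstream of the collection point to be below ≈ 1.3 µl, and the pristine
passive conductance must support ~1 µl/min; mm-scale channels and a sub-mm
well bore at the printed depths satisfy both.

Unit convention: SI everywhere inside the solvers; µl and minutes only at I/O
boundaries, through explicit conversion helpers.

One wording conflict in the source material is resolved in favour of the
mechanism: surfactant-treated zones are modelled as wetting (low contact
angle), which is what drives the separation; the opposite reading would
immobilise the sample.

## Calibration

`calibrate` minimises the mean squared error between the model's collected
volumes (monotone piecewise-linear interpolation to the observation times)
and the observed series, by bounded Nelder–Mead from a fixed documented start
(log₁₀ scaling for τ_c, D_f, ε). Four observation points cannot identify more
than two parameters, so the replication fit frees only {τ_c, D_f}; ε_cells is
fixed analytically from the count table. R² is evaluated at the optimum as
1 − SS_res/SS_tot about the experimental mean. The optimiser is deterministic;
the best-so-far point is returned (flagged) if the evaluation budget runs out.

On the packaged four-point reference series the fit converges to
τ_c ≈ 310 s, D_f ≈ 3.8×10⁻⁸ m²/s with R² ≈ 0.989 and MSE ≈ 0.009 µl². The
fitted D_f sits at the upper (well-mixed) end of its range: the data prefer a
weakly polarised junction with the slowdown carried by coagulation.

`extrapolate_completion` runs the calibrated model forward and reports the
first time the collected volume crosses a target fraction of the available
plasma (injected volume × (1 − HCT)), or the explicit sentinel `inf` within a
500 min cap — never a fabricated time. Under the exponential coagulation law
the calibrated flow decays exponentially, and collected volume saturates near
63 % of the available plasma, so near-complete (99.9 %) separation is *not
attained* by this reduction; independent of the coagulation law, holdup in
the chip's dead volume bounds completion below ~98 % for any mass-conserving
model of this device. The crossing-time logic itself is verified against the
closed form τ·ln(1/(1−f)) on a saturating series.

## Synthetic data

`synthetic_data` emulates the two study tables so the whole pipeline is
testable without external data. Separation series: forward model at
ground-truth parameters, additive Gaussian volume noise (default SD 0.1 µl,
truncated at zero), then a pool-adjacent-violators projection to restore
monotone volumes. Count tables: input ~ Poisson(mean·aliquot)/aliquot and
output ~ Poisson(mean·ε·aliquot)/aliquot per analyte (default aliquot 1 µl at
the study's input concentrations). Both are driven by a single integer seed,
recorded with a spec hash in all outputs. The study reports no replicate
variability, so the noise models are package choices; what passing tests show
is that the *pipeline* recovers known parameters under its own assumed noise,
not that real devices satisfy those assumptions (no cell sedimentation,
counter drift, or volume-reading bias is emulated).

## Numerical choices and degenerate inputs

Startup: 1 µm minimum wetted length. Integrator position tolerance 10⁻⁷ m.
Junction fixed point: tolerance 10⁻¹² on κ, ≤ 20 secant-accelerated
iterations (~3 typical). Mass-fraction excursions beyond [0, 1] by more than
10⁻¹⁰ raise rather than clip. A receding meniscus, non-positive domain
length, or mesh tangling raise immediately. θ = 90° is legal (the rate
carries cos 90° ≈ 6×10⁻¹⁷, numerically stalled). Constant experimental series
make R² undefined and raise. Purity with output > input returns the negative
value with a warning — a data-error signal, never silently clamped.

## Known limitations

- One-dimensional reduction: no velocity profiles, meniscus shape, corner
  films, or contact-angle hysteresis; the burst is pressure-deterministic.
- Cells are a continuous species: no discrete-cell effects, deformability,
  hemolysis, or clot microstructure; the packed layer acts only through the
  passage factor.
- The coagulation law is phenomenological; its exponential form makes total
  collected volume finite, so completion fractions near 1 are unreachable
  (see Calibration).
- HGB and HCT purities are computed from the count table as printed but
  flagged unit-ambiguous (their instrument units are not counts per µl).
- The recovery denominator supports both the exact haematocrit (0.399) and
  the rounded (0.40) convention; the rounded convention reproduces the
  headline 58.3 % and is the replication default. The choice is always
  logged.
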