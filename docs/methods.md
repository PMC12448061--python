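# Methods

This note documents the models, parameter choices and numerical decisions
behind `putkit`, and what the synthetic-data tests do and do not demonstrate.

## Photoacoustic source

The PA transient of a laser-heated blood vessel is generated under stress
confinement (3 ns pulse ≪ 67 ns acoustic transit across a 0.1 mm vessel), so
the initial pressure is p₀ = Γ·µₐ·F. Units: Γ (dimensionless) × µₐ (cm⁻¹) ×
F (mJ/cm²) is an absorbed energy density in mJ/cm³ = 10³ J/m³ = kPa·10³,
i.e. 0.2 × 10 cm⁻¹ × 100 mJ/cm² → 0.2 MPa.

The waveform observed on the vessel axis is modelled as an N-shaped bipolar
pulse (leading compression, trailing tension) of support d/c, convolved
analytically with the Gaussian laser envelope and rescaled to peak p₀. This
reproduces the morphology of a cylindrical-absorber transient without
evaluating the exact Bessel-integral solution; the transient is antisymmetric,
so it integrates to zero — the far-field property that matters for how it
perturbs the bubble. The bubble is taken to be co-located with the vessel
axis; no geometric attenuation is applied. Fluence at depth is an input, not
computed (no optical transport model).

Default absorber values — µₐ = 10 cm⁻¹ (whole blood, 1064 nm class value) and
Γ = 0.2 — are fallbacks, overridable in every config; the vessel diameter
defaults to 0.1 mm.

## Drive synthesis

The ultrasound burst is an ideal sinusoid with the stated peak negative
pressure (PNP); the treatment configuration is 0.25 MHz, 500 cycles (2 ms),
10 Hz burst repetition (2 % duty cycle). Tissue attenuation, focusing and
standing waves are not modelled: depth-resolved PNP values are inputs. The PA
pulse is resampled onto the burst grid (≤1 ns step) and added at a delay; the
default placement centres its tension peak on a mid-burst rarefaction peak,
consistent with the observation that the threshold is insensitive to the
exact placement within the first half of the rarefaction cycle. The
delay-to-depth sweep is pure arithmetic: depth = delay × c with
c = 1.5 mm/µs, stepped by 500 ns per minute over a 4-minute session.

## Bubble model

Keller–Miksis equation with first-order compressibility:

    (1 − Ṙ/c)·R·R̈ + (3/2)·Ṙ²·(1 − Ṙ/3c)
        = (1 + Ṙ/c)·(p_L − p∞ − p_s(t))/ρ + (R/ρc)·d(p_L − p_s)/dt

with liquid pressure at the wall
p_L = p_g + p_v − 2σ/R − 4ηṘ/R and polytropic gas
p_g = p_g0·((R₀³ − h³)/(R³ − h³))^κ, where p_g0 = p∞ − p_v + 2σ/R₀ sets gas
content by equilibrium at R₀ and h = R₀/8.86 is the van der Waals hard core
that bounds compression during inertial collapse. The viscous part of dp_L/dt
contributes an R̈ term that is folded into the left-hand side.

Medium defaults (SI): ρ = 1000 kg/m³, σ = 0.072 N/m, κ = 1.4 (adiabatic
air), p∞ = 101.325 kPa, p_v = 2.339 kPa, c = 1500 m/s, D = 2·10⁻⁹ m²/s,
air-saturated liquid (Cᵢ/C₀ = 1, C₀ = 0.85 mol/m³). The effective viscosity
is 0.002 Pa·s — between water (0.001) and high-shear whole blood (0.004);
blood is strongly shear-thinning and bubble-wall shear rates are extreme, so
a mid-range effective value is used and is the package's calibration choice:
with it, the 100-nm bubble's threshold brackets (dissolution at 0.6 MPa +
100 mJ/cm², growth at 0.8 MPa + 120 mJ/cm²) and the fluence-dependent
threshold decrease are reproduced. All values are config-overridable.

Physical picture at these parameters: the grow/dissolve boundary is a
Blake-type explosive-expansion barrier. Below ≈0.79 MPa (pure ultrasound)
the 100-nm bubble oscillates mildly behind the barrier and the Laplace
term dominates the rectified-diffusion balance → dissolution. The PA kick
pushes the bubble over the barrier at lower PNP the higher the fluence, so
the threshold falls from 0.794 MPa (F = 0) to 0.677 MPa (F = 200 mJ/cm²).
In a narrow band just below the pure-ultrasound threshold the PA-triggered
oscillation locks into a period-2 orbit (strong subharmonic at f/2); at
higher PNP every cycle resets to a near-identical violent collapse and the
motion is period-1.

### Rectified diffusion and fate

Gas exchange is decoupled from the radial dynamics within a burst. On the
steady window (first 25 % of the burst discarded, configurable) the
Eller–Flynn high-frequency flux is evaluated from the time averages ⟨R/R₀⟩
and ⟨(R/R₀)⁴⟩:

    dn/dt = 4πDR₀C₀·[ (Cᵢ/C₀)·⟨(R/R₀)⁴⟩ − (1 + 2σ/(p∞R₀))·⟨R/R₀⟩ ]

whose zero reproduces the classical growth threshold and whose undriven
limit is the quasi-static Epstein–Plesset dissolution rate (a unit test
checks both). Fate = GROW if flux > 0, DISSOLVE otherwise;
PERIOD_DOUBLED_GROWTH if growing and the Hann-windowed spectrum of R(t)/R₀
over the steady window has a line near f/2 exceeding 10 % (configurable) of
the line near f. Alternation of successive cycle maxima is used as a
cross-check in the tests. A trajectory that exceeds the runaway radius cap
(1 mm) is classified GROW directly; its padded tail is not used for spectra.

### Numerics

The ODE is integrated by an embedded Dormand–Prince 5(4) stepper (numba-
compiled) with per-component error control (rtol 10⁻⁶; absolute floors
10⁻¹³ m and 10⁻³ m/s), FSAL, and step-size limits of ×0.1–×5 per step.
Violent collapses push wall speeds towards the sound speed; the
compressibility factor is clamped at Ṙ/c ≤ 0.95 on the rebound side and the
hard core bounds gas compression — numerical regularizations, not physics
claims. Output is sampled on a uniform grid (128 points per drive cycle by
default) by linear interpolation across accepted steps; radius maxima, which
dominate the flux averages, occur on the slow growth phase and are well
resolved. Fate labels at the reference parameter combinations are invariant
to halving the tolerances and to extending the burst from 32 to 100 to 500
cycles (tested), which is why the regime map defaults to 32-cycle bursts
(441 cells in ≈10 s) while threshold searches use 100 cycles.

Accuracy oracles: small-amplitude ringdown matches the Minnaert-with-
surface-tension frequency within 5 % for R₀ ∈ [1, 10] µm; collapse from rest
matches the Rayleigh time 0.915·R_max·√(ρ/p∞) within 2 %; sub-resonant
forced response matches the linearized-oscillator amplitude within 5 %.

### Thresholds and regime map

`threshold_pressure` brackets the grow/dissolve transition in PNP ∈
[0, 1.5] MPa and bisects to 0.01 MPa (default). Because the fate predicate
is monotone in both PNP and fluence at these parameters and the bisection
visits the same midpoints for every fluence, threshold curves are exactly
non-increasing in fluence. Cells where both bracket ends share a fate are
reported as out-of-range results, not exceptions. The regime map classifies
every (PNP, fluence) grid cell independently; its boundary agrees with the
bisection threshold to one grid cell (tested).

## Active cavitation detection

Per-pixel temporal mean and sample SD (ddof = 1) over a zero-fluence
baseline stack; the tube structure is masked either explicitly or by Otsu
thresholding of the temporal-mean image dilated by 2 px. A frame is flagged
when any unmasked pixel exceeds µ_b + k·σ_b (k = 3); CP = flagged/total.
Per-pixel statistics are the default because B-mode speckle is spatially
inhomogeneous; a `global_baseline` switch pools one mean/SD over the ROI.
Frames are counted independently — bubbles persisting across consecutive
frames would inflate CP on real recordings; the synthetic generator draws
events independently per frame, so this caveat is not exercised here.

## OCT-A quantification

Speckle variance is the per-pixel population variance (÷N_rep) across the
repeated B-scans; the convention is recorded in the output metadata. Vessel
density is the mean OCT-A value inside the axial gate (150–300 µm at
3 µm/px by default) — raw intensity, not a binarized mask, with an Otsu
`binarize` option for sensitivity analysis. Normalized density divides by
the same-timepoint untreated mean; percent reduction is
(1 − treated/untreated)·100. The paired t statistic is computed directly
from the differences (t = d̄/(s_d/√n), n−1 df); all-zero differences give
t = 0, p = 1, and zero-variance non-zero differences are reported as a
degenerate result rather than an infinity.

## Synthetic data: what it emulates, and what it does not

**B-mode stacks.** A static tube phantom: one frozen speckle pattern per
phantom (shared between the baseline and test stacks of a series via
`pattern_seed`), a bright annulus for the hyperechoic tube walls, and
per-frame temporal noise truncated at 1.5 SD. The truncation emulates
bounded, quantized scanner noise in a fixed ROI and is what makes an
any-pixel µ+3σ rule over thousands of pixels meaningful: with unbounded
Gaussian tails such a rule would flag essentially every frame. Events are
2-px bright blobs at 6 temporal-noise SDs injected inside the lumen (clear
of the dilated wall mask) in a Bernoulli(p_event) subset of frames.
Detection on these stacks is therefore near-perfect by design; passing tests
demonstrate that the statistic is implemented correctly and recovers
programmed event rates, not that real scanner noise behaves this way.

**OCT series.** 8 mm × 8 mm lateral extent, 3 repeats per position, 3 µm
axial pitch. Vessel voxels (12 % areal fraction by default) are redrawn
independently per repeat (maximal flow decorrelation, SD 25); static tissue
shares one speckle realization across repeats up to 1-SD jitter. The treated
series retains a programmed fraction of vessel voxels. The small static
jitter floor biases recovered reductions downward by <1 percentage point at
the default contrast — well inside the ±3-point recovery tolerance. Not
emulated: velocity-dependent decorrelation, motion artefacts, depth-
dependent signal roll-off, vessel connectivity/geometry. The in vivo
reduction values themselves are not reproducible from raw data here (no
deposited recordings); recovery of programmed ground truth from synthetic
pairs is the stated substitute.

## Study runners and problem sizes

`study mechanism` runs the three reference trajectories (100-cycle bursts),
a five-fluence threshold curve and the 21 × 21 regime map (32-cycle bursts)
— ≈15 s on one CPU. `study phantom` generates a 5 × 5 (pressure × fluence)
grid of 100-frame stacks with a programmed linear event-probability surface
and detects it into a CP map. `study treatment` generates four regions per
(side, timepoint) with programmed Day-7 reductions of 45.20 % (top) and
36.06 % (bottom), quantifies densities and runs the paired tests; the
report is validated against the shipped JSON schema. Every run directory
contains a config snapshot and a log; deterministic stages are
bit-reproducible, stochastic ones seed-reproducible.

## Known limitations

- The exact parameter set of the reference bubble model is not published in
  the main text; the effective viscosity is a calibration choice (see above)
  and all medium parameters are explicit and overridable.
- Period doubling appears in a pressure band below the pure-ultrasound
  runaway threshold rather than extending to arbitrary PNP; at strong drive
  the per-cycle reset suppresses the subharmonic in this model.
- Single nucleus, deterministic: the measured CP map's stochastic nucleation
  is represented only through the synthetic generator's programmed
  probabilities.
- No beam modelling, no tissue attenuation, no histology quantification.
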