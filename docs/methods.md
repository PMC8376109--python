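# Methods

This note documents the models behind `xepcv`, the defaults and why they were
chosen, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Gas physics

Dynamic similarity between a ¹²⁹Xe inhalation and an equivalent air breath is
enforced by matching the Reynolds number Re = ρQD/(μA) and the Womersley
number α = D√(ωρ/μ). Both reduce to multiplication by the single factor
(ρ_src/μ_src)·(μ_tgt/ρ_tgt), implemented once (`similarity_factor`) so flow
rate and frequency rescale consistently; for identical gases the factor is
exactly 1. Package constants: ρ_Xe = 5.761 kg·m⁻³, μ_Xe = 2.28×10⁻⁵ Pa·s,
ρ_Air = 1.18 kg·m⁻³, μ_Air = 1.81×10⁻⁵ Pa·s, giving the ratio 3.876 (→ 3.88
at three significant figures).

Binary diffusion uses the first Chapman-Enskog approximation with the
8-parameter Neufeld correlation for the reduced collision integral Ω_D(T*)
and combining rules σ_AB = (σ_A+σ_B)/2, ε_AB = √(ε_A ε_B). Lennard-Jones
constants are standard tabulated values: Xe σ = 4.047 Å, ε/k = 231 K; air
σ = 3.711 Å, ε/k = 78.6 K. The xenon **molar mass is 129.0 g·mol⁻¹** — the
¹²⁹Xe isotope, not natural-abundance xenon (131.29): the imaged gas is
isotopically enriched, and the packaged density 5.761 kg·m⁻³ itself
corresponds to M ≈ 129 at standard conditions. Defaults are body temperature
(310 K) and 1 atm, under which the module yields 0.061 cm²/s for Xe-Xe
self-diffusion and 0.135 cm²/s for Xe in infinite dilution in air.

The Kolmogorov length (ν³/ε)^¼ requires a dissipation rate ε; the convenience
estimator ε ≈ U³/L (`dissipation_estimate`) is an order-of-magnitude
heuristic only and is flagged as such.

## Flow phantom

The ground-truth field is a rigid straight tube along the foot-head axis,
default radius 7.5 mm (hydraulic diameter 1.5 cm, a glottis-scale airway) and
length 0.2 m, with an optional Gaussian axisymmetric constriction. Two
profile modes:

* **steady** — quasi-steady Poiseuille, u(r,t) = 2Q(t)/(πR²)(1 − r²/R²);
* **oscillatory** — the breath trace is decomposed into its mean plus the
  first n Fourier harmonics (default 5) over the trace duration; the mean
  drives a Poiseuille term and each harmonic a classical Womersley
  Bessel-function profile normalized so its cross-section flux equals that
  harmonic exactly. This captures the flattened, phase-lagged profiles that
  matter when α ≈ 4.9 > 1. Below α = 10⁻⁴ the Bessel expression is replaced
  by its Poiseuille limit to avoid catastrophic cancellation; at α = 0.01 the
  Bessel path itself agrees with Poiseuille to ~10⁻¹¹ relative L2.

A constricted tube is treated quasi-1D: the local straight-tube profile with
the local radius carries the full Q(t) (continuity); secondary flows and
separation are deliberately out of scope. Flux through any cross-section
equals the (Fourier-reconstructed) drive to quadrature accuracy.

Sign convention: right-handed patient frame, components ordered (RL, AP, FH),
positive FH pointing foot→head. With the default `inhale_sign = −1`, inhaled
gas travels head→foot, so inhalation appears as negative v_FH, and the xenon
front enters at the head end.

The ¹²⁹Xe molar fraction c(s,t) obeys 1-D axial advection-diffusion with mean
speed Q(t)/A(s) and the binary diffusion coefficient (default: the
Chapman-Enskog Xe-air value). The solver is finite-volume with
minmod-limited second-order (MUSCL) advection, explicit central diffusion and
Heun time stepping under CFL 0.4; the flux form conserves tracer to machine
precision. On exhalation (Q < 0) gas re-enters from the lung end with the
zero-gradient (last-cell) composition — the real mixture is unknown, which is
exactly why exhalation dynamics are excluded from comparisons. Accuracy: with
the front resolved by ≥ 30 cells the profile matches the closed-form erfc
solution to < 1% (tests use 800 cells); at zero diffusion the front midpoint
is correct to one cell with a numerical transition band of ~±15 cells after
~180 cells of travel.

## Breath traces and synchronization

Traces are uniformly sampled CSV (`time_s,flow_mls,trigger_v`), inhalation
positive. Trigger detection is a rising-edge crossing of 2.5 V (half the 5 V
pulse), robust to sub-volt channel noise. Per-dynamic summaries average the
flow over [trigger, trigger + duration] by trapezoidal integration; a
negative window mean flags exhalation and drops that dynamic from downstream
comparison. Linear interpolation is used wherever the flow is needed between
samples.

The synthetic trace generator emulates the study maneuver — inhaling 1 L of
xenon slowly through the nose: ramp to an 80 mL/s plateau (≈1 L over 13 s),
ramp down, then exhalation at −150 mL/s, with 5 trigger pulses at 3.1 s
spacing starting 0.5 s in. The 13 s inhalation sits in the instructed 10-20 s
range and places the exhalation reversal inside the fifth dynamic window,
mirroring the reversal observed in dynamic #5 of the reference dataset.

## PC-MRI acquisition model

Geometry: sagittal slab along RL (default 10 mm) with fine in-plane voxels
(default 1.25 mm), world coordinates through a NIfTI affine, half-open voxels
centred on integer indices. Per voxel and dynamic:

* **Velocity** is the signal-weighted spatial mean of the field over a
  midpoint supersample of the voxel volume (default 4×4 in-plane × 9 slab
  points), weighted by lumen membership × local xenon fraction — this
  reproduces the partial-volume and slow-flow biases at the lumen boundary —
  then averaged evenly over 11 time points spanning the dynamic window.
  Temporal weighting is deliberately uniform: intra-window signal drift is a
  second-order effect, and an even mean makes the noiseless acquisition agree
  exactly with the reference resampling on fully-interior voxels (the
  pipeline's self-consistency anchor). A plain-mean switch exists for oracle
  comparisons.
* **Magnitude** is lumen fraction × mean xenon fraction × exp(−t/T₁) ×
  depletion^k, with T₁ = 20 s (airway-scale longitudinal relaxation of the
  hyperpolarized gas) and an RF depletion factor of 0.8 per dynamic — both
  exposed parameters; magnitude is therefore non-increasing across dynamics,
  reproducing the loss of late-dynamic SNR.
* **Phase encoding**: φ = π·v/venc wrapped to (−π, π] (venc default
  200 cm/s); velocities beyond venc alias (250 → −150 cm/s). Two abstract
  encodings at ±φ/2 receive independent complex Gaussian noise of scale σ;
  decoding their phase difference gives velocity noise
  σ_v = (√2/π)·venc·σ/magnitude. Full four-point Hadamard encoding is not
  modeled — the two-point abstraction already reproduces the SNR→σ_v
  relationship, which is all the analysis uses.
* **Magnitude noise** is additive Gaussian on the magnitude image (the
  high-SNR limit of the Rician distribution). This keeps the ROI-based SNR
  estimator (mean airway signal / background standard deviation) unbiased
  with respect to the σ entering the phase noise, so
  `velocity_uncertainty(venc, estimate_snr(...))` is directly the predicted
  voxel noise. Monte-Carlo sampling matches the closed form within 5% for
  SNR ∈ [5, 50].

All randomness flows from a single `numpy` generator seeded in
`AcquisitionParams`; identical seeds give bit-identical series.

## Reference resampling and mask operations

The reference side averages the analytic field with a **plain volume mean**
over the identical supersample and time points (out-of-lumen points
contribute zero velocity, as a volume average of the true field does). The
lumen mask keeps voxels with lumen fraction ≥ 0.5 (the acquisition does not
define how a clinical airway mask is drawn; 0.5 is the neutral choice).
Because acquisition is signal-weighted and resampling volume-weighted, they
agree exactly only on voxels fully inside the lumen — the residual boundary
disagreement *is* the partial-volume bias that motivates mask erosion.

Erosion is in-plane morphological erosion with the 4-connected cross, applied
independently per sagittal slice; lattice edges count as background. With
1.25 mm voxels and a 15 mm tube under a 10 mm slab, the partial-volume rim of
the thresholded mask is about two voxels wide, so the synthetic validation
uses 2 erosion iterations to reach the fully-interior region (a single
iteration — the typical in vivo choice — still leaves rim voxels at this
geometry).

Down-sampling partitions the in-plane grid into non-overlapping 3×3 blocks;
each output pixel is the mean over in-mask inputs and is itself in-mask when
at least 5 of 9 inputs were. The reduced-size block interpretation is the
default (consistent with reduced-size down-sampled maps); an overlapping
moving-average variant is available behind a flag for sensitivity analysis.
Out-of-mask pixels are excluded from every mean rather than zero-filled.

## Comparison statistics

Pairs are (v_MRI, v_reference) on the common mask, in cm/s internally.
Pearson r with the exact t-transform two-sided p (n − 2 degrees of freedom),
ordinary-least-squares best-fit line (the plotted "line of best fit" is taken
as OLS), Bland-Altman bias = mean(MRI − reference) with limits of agreement
bias ± 1.96·SD — positive bias means MRI reads higher. No multiple-testing
correction is applied. Components with (numerically) zero variance — e.g.
the identically-zero RL velocity of a noiseless straight-tube phantom —
report agreement but no correlation rather than failing. The velocity-cutoff
sweep recomputes r over pairs with |v_ref| ≥ cutoff and reports surviving n;
cutoffs leaving fewer than 3 pairs yield NaN, not an exception.

## Synthetic validation experiment

`run_synthetic_validation` chains trace → trigger sync → flow field + xenon
front → acquisition → per-dynamic resampling → report, writes every
intermediate (CSV/NIfTI/JSON with provenance hashes), and is bit-reproducible
under the master seed. Default problem size: a 30 × 160 mm sagittal FOV at
1.25 mm (1×24×128 voxels, one 10 mm slab), 5 dynamics of 3.1 s, 4/9-point
spatial supersampling and 11 time points per dynamic — a few tens of seconds
on one core; tests use shorter FOVs and fewer dynamics.

Configuration is a YAML-serializable dataclass with unit-suffixed keys,
validated by explicit checks in the constructor (same contract as a schema
document with fewer moving parts).

## What the synthetic experiments do and do not show

The phantom has exact no-slip laminar flow, a rigid axisymmetric lumen, a 1-D
(cross-section-uniform) concentration field and Gaussian noise. Passing the
suite demonstrates that the *comparison machinery* — dynamic similarity,
voxel averaging, phase encoding/decoding, erosion, down-sampling, correlation
and Bland-Altman — is internally consistent and recovers known ground truth,
including the expected directions of the partial-volume bias and the
down-sampling noise benefit. It does not demonstrate agreement for real
airways: turbulence and recirculation, airway-wall motion, registration
error, radial concentration gradients, flow-meter calibration error and
Rician noise at low SNR are all absent by design. In vivo agreement levels
(e.g. specific r values per velocity component) therefore cannot be inferred
from, and are not asserted by, this package.

## Known limitations

* Quasi-1D constriction model: no separation, jets or secondary flows.
* Two-point encoding abstraction; no k-space, off-resonance or coil effects.
* Concentration is axial-only; the slower xenon arrival *within* the
  boundary layer (a radial effect) is not represented, so the concentration
  contribution to the boundary bias is understated.
* The minmod limiter smears a zero-diffusion front over ~±15 cells at long
  advection distances; with physical diffusion resolved by ≥ 30 cells the
  error is < 1%.
* `estimate_snr` follows the ROI definition (mean/SD); with the additive-
  Gaussian magnitude model this is unbiased, but applied to real Rician
  magnitude data it would overestimate SNR by the Rayleigh factor ≈ 1.53.
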