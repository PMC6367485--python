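# Methods

This note records the models implemented in `coreshell`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real measurements.

## Size distributions

All particle populations are log-normal, parameterized by median *m* and
log-standard-deviation σ (`sigma_log`). A target relative standard
deviation maps to σ = √ln(1 + rel_sd²); the number-weighted mode is
*m*·e^{−σ²}. The reference series defaults to eleven members at nominal
5–250 nm with a size-independent relative SD of 5% — a realistic value for
commercial citrate-stabilized gold colloids, which are specified as narrow
and constant-width across the series. Log-normal is the standard choice for
grown colloids and matches how the AFM histograms are fitted downstream.

Shelled populations are deterministic transforms: hydrodynamic diameter =
core + 2*L* elementwise, which preserves the absolute distribution width.
All stochastic generators require an explicit integer seed and raise
otherwise; there is no hidden global RNG state anywhere in the package.

## AFM forward model and analysis

Synthetic topographs render each particle as a full (optionally oblate)
spheroid resting on the substrate: a particle of height *h* and equatorial
width *w* contributes z(r) = (h/2)(1 + √(1 − (2r/w)²)) inside r < w/2.
Particles are placed by rejection sampling with a 5-nm margin (no overlap,
no border contact); a tilted background plane and i.i.d. Gaussian pixel
noise are added on top. Tip convolution, cantilever dynamics, drift and
fluid-imaging artifacts are *not* modeled — the generator exists to
exercise the analysis chain with known ground truth, not to emulate an
instrument.

Analysis follows metrology practice:

- **Flattening.** One global least-squares plane per image, fitted over
  pixels outside an exclusion mask and subtracted everywhere. The operation
  is a projection (idempotent) and exact on noise-free planes. The pipeline
  uses a two-pass scheme: rough flatten, mask pixels > 3× the noise scale
  (dilated 3 px), re-flatten.
- **Detection.** Connected regions above a height threshold
  (per-member default: 40% of the nominal height, floored at 5× the noise
  SD), filtered by minimum area (4 px). Regions touching the border are
  excluded with reason `border`; regions with eccentricity > 0.95 with
  reason `fused`. Exclusions are flagged, never silently dropped.
- **Measurement.** Height is the peak value after flattening; the two
  perpendicular widths are extents at half-maximum height through the peak.
  Half-maximum was chosen over a fixed-height criterion because it is
  scale-free and least sensitive to threshold choice. Sub-pixel crossings
  are interpolated linearly; where the profile falls past the half level in
  a single pixel step (the equator of an upright particle, whose lower half
  is hidden from a top-view height map), the edge is taken at the pixel
  boundary — the unbiased estimator for an edge uniformly distributed
  within a pixel. This matters: linear interpolation at such cliffs clips
  about half a pixel per side and systematically shrinks widths.
- **Shape correction.** d_eq = (h·w₁·w₂)^{1/3}, the volume-preserving
  spheroid convention; the per-sample factor f = median(d_eq/h) (with MAD)
  converts height-only data via f·h. For deformable particles imaged
  height-only, the field-standard empirical factors (1.2 for oligo-DNA
  cores, 1.7 for siRNA cores) can be supplied through configuration instead.
- **Distribution fit.** Maximum likelihood on log-diameters (n ≥ 20);
  goodness is the SSR against expected counts on Doane bins.

## DLS forward model and inversions

g₁(τ) = Σ wᵢ e^{−q²Dᵢτ} with Rayleigh weights wᵢ ∝ dᵢ⁶,
q = 4πn sin(θ/2)/λ, Stokes–Einstein D = k_BT/(3πηd), and Siegert relation
g₂ = 1 + βg₁². Defaults: 25 °C water (η = 0.89 mPa·s), 633 nm, 173°
backscatter, β = 0.9. The d⁶ weighting is the Rayleigh limit and becomes
approximate above roughly a tenth of the wavelength; the 200- and 250-nm
members are therefore weighted only approximately (a user-supplied
weighting hook exists; Mie form factors are out of scope).

**Cumulant analysis** fits ln[(g₂−1)/β]/2 by a polynomial in τ over the
lags where g₂−1 exceeds 10% of its initial value. The fit defaults to
*third* order: with a quadratic, truncating the cumulant expansion biases
μ₂ low by ~11% for σ = 0.2 log-normal samples, while the cubic reduces the
bias to ~5% and leaves Γ̄ essentially exact (z-average error < 0.1%). The
z-average is the Stokes–Einstein diameter at D = Γ̄/q²; PDI = μ₂/Γ̄².
Closed forms used as oracles (verified independently by numerical
integration of the intensity-weighted log-normal): z-average =
m·e^{5.5σ²}; PDI = e^{σ²} − 1; the DLS−AFM gap m(e^{5.5σ²} − e^{−σ²}).

**NNLS inversion** solves nonnegative least squares for band amplitudes on
a 64-point log grid (1–1000 nm) with a second-difference smoothing penalty
(λ ladder 10⁻⁴…10⁻¹, escalated with a warning if a solve fails). Residual
rows are weighted by the observed g₁ floored at 0.05 and normalized to unit
RMS — the propagated inverse standard deviation of √((g₂−1)/β) under
additive g₂ noise — so the decayed tail, where the square root amplifies
noise, cannot steer the solution; the penalty matrix is divided by its row
count so λ values are comparable across grid sizes. Peak positions, not
amplitudes, are the claimed output; equivalence with any instrument's
proprietary regularization is only at that level.

## Shell-thickness inference

`ShellThicknessModel` fits d_dls = d_afm + Δ with slope fixed at 1 and
reports L = Δ/2. The slope is fixed because the bare reference series is
1:1 by construction; a free-slope OLS fit is attached to every result as a
diagnostic. Weights are inverse-variance when per-row uncertainties are
given, equal otherwise. The standard error is propagated from the stated
per-row uncertainties when available (so ±2·se is a genuine ≈95% interval);
otherwise it is estimated from residual scatter, where ±2·se coverage at
n = 7 is the t-distribution's ≈91%. Negative fitted shells are returned
with a warning flag, never clamped.

Screening: cores below 50 nm are flagged `curvature` (on curved surfaces
the same adsorbed volume yields a thinner brush; the effect is handled as a
cutoff rather than a correction formula), and rows with σ_log > 0.15 are
flagged `polydispersity` (a declared default for "narrow"; the divergence
between the intensity-weighted harmonic mean and the number-weighted mode
grows as the gap formula above). The end-to-end pipeline additionally
*corrects* each retained member by its predicted gap, computed from the
member's fitted (m, σ): screening bounds the bias, the correction removes
the remainder, and the Monte-Carlo calibration shows the combined estimator
is unbiased to ≈0.1 nm at realistic noise.

Uncertainty budget: combined standard uncertainty u_c = √Σuᵢ², expanded
U = k·u_c with k = 2 labeled as the 95% confidence interval. The default
instrument components are 2.8% (AFM heights) and 1.6% (DLS z-averages),
entered as expanded values and halved to standard form before combination.

## Shell chemistry and the growth model

- Brush law L = N·a^{5/3}·D^{1/3} with N = round(MW/44.05) (114 for 5-kDa
  PEG) and a = 0.35 nm; exact inverse D = (L/(N·a^{5/3}))³.
- Grafting density D = uptake/(count·πd²); titration saturation is the
  first step whose uptake increment falls below 1% of the added increment,
  and an unsaturated series is reported censored, not an error. The
  synthetic titration defaults to hard saturation (uptake = min(added,
  capacity)), matching the observed sharp plateau; a Langmuir-like softness
  parameter exists for robustness tests. Mass balance (uptake + supernatant
  = added) is enforced to a few ulps.
- Payload per particle = (π/6)d³·ρ·f/MW·N_A with ρ = 1370 µg/µL
  (≡ 1.37 g/cm³; note 1 µg/µL = 1 mg/mL = 10⁻²⁴ g/nm³) and oligo
  MW = 12850 g/mol. The DNA mass fraction defaults to the stoichiometric
  f = 330/(330 + (N/P)·43.1) — 0.657 at N/P = 4 — a declared stand-in for
  an unstated experimental bookkeeping choice.
- Equilibrium growth: condensation stops when conjugated PEG tiles the core
  surface at D* (0.5 chains/nm²); for monodisperse spheres at fixed total
  core volume, d = 6V·D*/P. Total PEG count is proportional to the degree
  of conjugation, so the 7%-vs-10% surface-area ratio is exactly 0.7,
  identically equal to the inverse diameter ratio. PEG per PEI uses 581
  amines per 25-kDa PEI (the all-amines reading; ratios are unaffected by
  this choice).
- Polydispersity vs blend ratio is only known qualitatively (widest near
  10:1, narrowing by 50:1), so the generator's schedule is a Gaussian bump
  in log blend ratio (base σ 0.08, amplitude 0.17, center 10:1, width 0.8)
  and is flagged as an assumption in every rendered report.

## Problem sizes and determinism

Default study sizes are desk-scale statistical choices: 60 particles per
series member for the end-to-end study (mode standard error ≪ the 1-nm
recovery target), 300+ particles for the imaging-chain recovery check, 200
seeds × 2 shell values for the estimator calibration (observed: bias
≈ −0.1 nm, 2σ coverage 0.96), 4000-particle samples for the cumulant/oracle
comparisons. `simulate` + `analyze` at a fixed seed reproduce every output
byte-for-byte; per-member seeds are derived with `SeedSequence`.

## Limitations

Synthetic topographs omit tip convolution and drift, so passing the imaging
tests demonstrates correctness of the measurement chain, not robustness to
those artifacts. The Rayleigh weighting overstates the intensity of the
largest series members. The curvature screen discards rather than corrects
sub-50-nm members, so the package cannot report shell thickness for very
small cores. Conjugation-degree chemistry (NMR), chromatographic method
development and zeta-potential physics are outside scope; uptake numbers
enter as inputs.
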