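# Methods

## Model

A fluorophore diffusing with coefficient D through a 3D-Gaussian confocal
observation volume (lateral 1/e² waist w₀, axial extent z₀) yields the
normalized fluctuation autocorrelation

G(τ) = (γ/N) · [1 + τ/τ_D]⁻¹ · [1 + (τ/τ_D)(w₀/z₀)²]⁻¹ᐟ²,  τ_D = w₀²/(4D).

γ is the illumination-profile factor relating the amplitude to the mean
occupancy, fixed at 0.35 (the 3D-Gaussian value 2⁻³ᐟ² rounded as used in
calibration practice); it is a property of the instrument model and is
never fitted. Two species of equal molecular brightness (the same single
fluorescent-protein tag whether free or vesicle-bound) combine
number-weighted:

G₂(τ) = γ/N² · (N₁G₁(τ) + N₂G₂(τ)),  N = N₁ + N₂,

and the bound fraction is p_b = N₂/N. Equal brightness is an assumption;
if binding quenched or enhanced the tag, p_b would need a brightness
correction.

Units are µm, s, µm²/s throughout; lags are stored in seconds.

### Amplitude conventions

The physical fluctuation amplitude of a 3D-Gaussian detection profile is
G(0) = 1/(c·V_eff) with V_eff = π³ᐟ²w₀²z₀. Written as G(0) = γ/N, the
occupancy the model reports is therefore N = γ·c·V_eff — for γ = 2⁻³ᐟ²
exactly the number of molecules in the profile-integral volume
(π/2)³ᐟ²w₀²z₀. `SimConfig.expected_occupancy` implements this relation,
and the simulator↔model closure test checks it.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| w₀ | 0.31 µm | calibrated beam waist (reference dye, D = 400 µm²/s) |
| z₀/w₀ | 5 | structure parameter; not stated by typical calibrations, held fixed during fits, configurable |
| γ | 0.35 | amplitude factor, fixed |
| noise_fraction | 0.02 | multiplicative ACF noise of one 30 s acquisition |
| n_curves | 25 | curves per condition (a typical per-pattern set) |
| N (occupancy) | 5 | mean molecules in focus for synthesized curves |

Condition presets (free D, bound D, % bound) are the measured operating
points of the eleven synaptic proteins and the two antibody controls. The
bound fractions of the antibody controls were not reported; both presets
use 20%, the mid-range of the measured 10–30% across proteins, chosen once
as a realistic operating point. The α-synuclein-on-vesicle preset uses the
on-pattern pair (67/4 µm²/s) with the tabulated 15% bound.

## Synthetic data: what it emulates and what it does not

`synthesize_acf` draws curves as model(τ)·(1 + ε·η(τ)) with η zero-mean,
unit-variance Gaussian noise correlated over ~3 neighbouring lags
(Gaussian smoothing of white noise, deterministically rescaled so the
ensemble mean stays exactly unbiased). This mimics the lag-correlated
scatter of measured curves at a level typical of 30 s acquisitions. It
does not model photophysics (triplet blinking, bleaching), detector
afterpulsing, or the near-surface artefacts of measurements close to the
coverslip; passing recovery tests therefore demonstrates correctness of
the estimator chain, not robustness to every artefact of real data.

`simulate_trace` runs independent Gaussian random walks (per-axis step
variance 2·D(state)·dt) in a periodic box centred on the volume, with
two-state Markov switching of D at per-step probabilities r·dt, a
3D-Gaussian detection profile, and Poisson photon noise. Configuration
validation enforces r·dt ≤ 0.1 and a per-step RMS displacement below
w₀/5. Bound particles stay mobile (D_bound > 0), matching the observed
slow-but-nonzero bound pool, and switching is spatially homogeneous — a
spatially resolved (vesicle-layer-only) variant is a possible extension.

Two systematic effects of the simulated measurement matter for validation:

* **Finite trace length.** The symmetrically normalized ACF estimator has
  the standard negative offset ∝ τ_int/T from normalizing by estimated
  means, which inflates fitted D on short traces (~15% at T = 1.5 s for
  τ_D ≈ 1 ms, ~6% at 6 s). Validation uses multi-second traces.
* **Finite periodic box.** A box at the minimum allowed 6×(w₀,w₀,z₀)
  supports only ~3 diffusion modes per axis inside the detection profile's
  k-support; an exact mode-sum calculation shows its ACF decays faster
  than the continuum model (fitted D +9% over a 6τ_D window). The
  simulator↔model oracle test therefore uses a 12 w₀ lateral box
  (residual ~+2%) and asserts fit-level agreement (D within 3 SE plus a
  2.5% box allowance; N within 10%). The 6× default remains fine for
  qualitative use; cost scales with box volume.

`simulate_sted_image` renders a hard-core point process (Poisson count at
the stated density, rejection sampling for the minimum separation) as
Gaussian PSFs with Poisson noise. It emulates spot geometry and shot
noise, not STED-specific effects (depletion-beam residuals, anisotropy).

## Fitting

Curves are fitted by trust-region nonlinear least squares with bounds
(N ∈ [10⁻³, 10⁴], τ_D within the lag range) and a log-spaced multi-start
over diffusion times (≈3 starts/decade; pairs with ratio ≥ 3 for the
two-component model), since the two-timescale objective has local minima.
Standard errors come from the Jacobian at the optimum.

**Residual weighting.** The default scales residuals by the inverse curve
amplitude ("relative" weighting). Correlation amplitudes span decades
across a quasi-logarithmic lag grid and the scatter of measured curves
grows with the amplitude, so unweighted least squares lets the short-lag
region dominate and destabilizes two-component fits when the two
timescales are within a factor ~5. Relative weighting equalizes the lag
contributions and is the matched estimator when noise is approximately
multiplicative. Unweighted (`weights=None`) and per-lag-SE weighting
(`weights="se"`, using the correlator's segment-derived errors) remain
available; fits of raw correlator output, whose near-zero tail would blow
up relative weights, should use `weights=None`.

**Canonical ordering and resolution.** After convergence the fast
component is reported as the free pool (τ_D1 < τ_D2 enforced). If the two
diffusion times are closer than a factor 3 the result is flagged
"unresolved"; parameters at bounds or non-convergence are flagged, never
silently dropped.

**Model selection.** `select_model` prefers one component unless the
two-component fit wins an F-test at α = 0.05 AND is resolved, with two
refinements chosen here: (i) the F-test degrees of freedom are deflated by
the integrated autocorrelation length of the fit residuals, because
per-lag ACF noise is correlated and an iid F-test is anticonservative
(it spuriously split ~25% of single-species curves before this
correction); (ii) a component holding less than 2% of the total occupancy
does not count as resolved — a sub-2% species is not detectable in a
single FCS curve.

**Calibration.** `calibrate_volume` fits the one-component model to a
reference-dye curve (the shape depends only on τ_D and z₀/w₀) and returns
w₀ = √(4·D_ref·τ_D); with the standard reference (D = 400 µm²/s at 25 °C)
and τ_D = 60.06 µs this gives w₀ = 310 nm.

**Aggregate exclusion.** Traces are rebinned to 10 ms; a trace is excluded
when ≥3 consecutive bins exceed median + 10·MAD (raw MAD, strict
inequality) — a sustained bright event as produced by a slowly crossing
aggregate, not shot noise. Thresholds are declared defaults, configurable
and logged.

## Energetics

With both states always accessible and the system equilibrated,
p_b/p_f = exp((E_f−E_b)/k_BT), so ΔE = ln(p_b/(1−p_b)) in k_BT. Setting
E_f = 3/2 k_BT (three translational degrees of freedom) gives
E_b = 3/2 − ln(p_b/(1−p_b)); detailed balance gives r_fb/r_bf = p_b/p_f.
Energies are reported as dimensionless multiples of k_BT; no absolute
temperatures. All measured bound fractions are below 1/2, so ΔE < 0 and
r_fb/r_bf < 1 throughout: binding is transient and entropy favours the
free state.

Because E_b is nonlinear (convex below p_b = 1/2), averaging energetics
per curve and evaluating at the mean p_b differ (Jensen's inequality).
Both modes are implemented (`per_point`, the default, and `of_mean`) and
the mode is recorded in every output; neither is asserted to reproduce any
particular published per-protein energy, whose exact averaging procedure
is not derivable from the summary statistics alone.

## Vesicle density

Images are bandpassed with a difference of Gaussians (defaults 0.5× and 3×
the PSF Gaussian sigma = FWHM/2.355): passes diffraction-limited spots,
removes pixel noise and slow background. Spots are local maxima above
median + k·(1.4826·MAD) of the filtered image (k = 5). The robust scale
is deliberate: on a dense spot field the raw standard deviation is
dominated by the spots themselves and a mean+k·SD threshold climbs above
genuine peaks, whereas the MAD tracks only the background noise — the
robust form is the reproducible stand-in for an "empirically defined"
manual threshold that still works at 15 spots/µm². Peaks closer than a
minimum distance are merged by non-maximum suppression and refined to
subpixel precision by a 3×3 intensity centroid.

Density is count/area. Spacing is reported as the mean nearest-neighbour
distance between spot centres and labelled as such; other pairwise
statistics of "inter-vesicle distance" exist and give different numbers
(a 2D Poisson process at 15 µm⁻² has a nearest-neighbour mean of
1/(2√15) ≈ 129 nm; a hard-core process at the same density sits higher).

## Statistics

Mann–Whitney U uses midranks; p-values are exact by enumeration for
combined samples ≤ 12 without ties and use the normal approximation with
tie correction otherwise. Kruskal–Wallis applies the tie-corrected H with
a χ² p-value; all-identical data degenerate to H = 0, p = 1. Two post-hoc
procedures are provided because "Tukey's post-hoc after Kruskal–Wallis" is
a nonstandard but occasionally reported combination: Dunn's z-tests on
mean ranks (default, optional Holm adjustment) and Tukey's HSD on
rank-transformed data.

## Numerical choices and degenerate inputs

* Multi-tau grid: first block of 16 unbinned lags (exactly equal to the
  brute-force estimator there), then blocks of 8 lags with doubling bin
  width; default lag range dt … duration/10. Per-lag standard errors, when
  requested, come from splitting the trace into 10 segments.
* Synthesized lag grid: 20 points/decade over 1 µs … 1 s.
* Zero-mean traces, all-nonpositive curves, sub-decade lag grids, infeasible
  spot packings and out-of-range bound fractions raise explicit errors;
  p_b ∈ {0, 1} is rejected with a divergence message rather than returning
  ±inf.
* All randomness flows through one seeded generator per call; seeds are
  recorded in output metadata, and pipeline outputs carry a configuration
  hash.

## Scale of the validation runs

Recovery tests use 25 curves per condition at 2% noise (matching a typical
per-pattern set of 30 s acquisitions); the Brownian-dynamics closure uses
six 3 s traces of 232 particles; null-calibration checks use 2000
simulated datasets. These sizes give standard errors a factor ≳3 below the
effects being checked while keeping the full suite fast.

## Known limitations

* No triplet/blinking term, anomalous-diffusion exponent, or FCCS variant;
  single-focus FCS only.
* The correlator emulates a quasi-logarithmic grid but is not claimed
  bit-compatible with any vendor's hardware lag layout; the ALV-style
  ASCII reader is a convenience dialect.
* Brightness is assumed state-independent; p_b is a number fraction.
* The density pipeline counts one vesicle per detected spot; overlapping
  vesicles within a PSF are not deconvolved.
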