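# Methods

`wgmsense` turns whispering-gallery-mode (WGM) emission spectra of
intracellular lipid droplets into droplet diameters, nanometer-scale
diameter kinetics, cytoplasm refractive indices and cell-state flags.
This note records the models, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Physical model

A lipid droplet (refractive index `n_LD ≈ 1.47`) inside cytoplasm
(`n_cell ≈ 1.33–1.40`) is treated as a homogeneous dielectric sphere.
Dye emission trapped by total internal reflection forms TE and TM
resonances indexed by the angular mode number ℓ and radial order q
(q = 1 throughout: first-order radial modes hugging the surface).

**Asymptotic positions.** With ν = ℓ + ½, ρ = n_LD/n_cell, α_q the q-th
Airy zero, and P = ρ (TE) or 1/ρ (TM), the scaled size parameter
F = π·n_LD·d/λ of a resonance satisfies

    F(ν) = ν + 2^(−1/3)·α_q·ν^(1/3) − P/√(ρ²−1)
         + (3/10)·2^(−2/3)·α_q²·ν^(−1/3)
         − 2^(−1/3)·P·(ρ² − 2P²/3)·α_q·ν^(−2/3)/(ρ²−1)^(3/2).

The right-hand side is diameter-independent, so λ scales exactly
linearly with d at fixed ℓ.  The expansion order is configurable; the
default keeps the ν^(−2/3) term, which contributes ~0.3 nm at ν ≈ 440
and carries its own polarization dependence (it shrinks the TE–TM
splitting about 15% below the leading-order value).

**Exact oracle.** Resonances are independently located as roots of the
real Mie characteristic equations built from Riccati–Bessel ψ_ℓ and χ_ℓ
(narrow-resonance approximation: positions, not widths), bracketed near
the asymptotic prediction and refined by Brent's method.  The χ-based
real root was verified to coincide with the |b_ℓ|² peak of the full
complex Mie coefficient to numerical precision.

**Validity domain.** At the instrument's working point (ρ ≈ 1.08,
ν ≈ 440, 60 μm droplet, 590–650 nm band) the expansion agrees with the
exact roots to ≤ 0.1 nm.  The truncation error grows like
(ρ²−1)^(−3/2) toward weak contrast and is ~0.8 nm at ρ = 1.05, ν = 300,
where the mode approaches the leaky limit (x/ν → 1, FWHM ~1.5 nm); the
error shrinks monotonically with ν at every contrast.  The oracle
comparison in the test suite asserts exactly this envelope.

**Derived optics.**  FSR = 1/(π·n_eff·d) in inverse wavelength
(Δλ ≈ λ²·FSR); TE–TM splitting parameter S = √(ρ²−1)/ρ, inverted
exactly by n_cell = n_LD·√(1−S²); evanescent 1/e reach
λ/(4π·√(n_LD²−n_cell²)) ≈ 88 nm at 620 nm for 1.47/1.36; the
apparent diameter error of a fixed-index analysis under a cytoplasm
drift Δn_cell is computed as a forward-model difference (shift the
resonances with the perturbed index, re-infer d at the original one):
≈ 2.5 nm per 0.001 at 60 μm with the default expansion order (the
leading-order-only value is ≈ 2.0 nm, the exact-Mie value ≈ 2.8 nm).

## Spectra and preprocessing

Spectra are two-column wavelength/intensity text tables (CSV or
whitespace), 590–650 nm, sampled at 0.035 nm (Nyquist of the 0.07 nm
instrument resolution).  Preprocessing subtracts a background baseline,
clips at zero and peak-normalizes to 1 (the removed normalization
factor is kept in metadata so raw amplitude ratios between spectra
remain available).

The default baseline is a **10th-percentile rolling filter** over a
window of 40 resolution elements (≈ 2.8 nm) — a valley-floor estimate.
A rolling *median* over a mode-spacing-sized window (kept as an option)
tracks the resonance comb itself: it subtracts the inter-line tail
pedestal and, combined with the zero clip, destroys the valley noise
statistics; measured SNR estimates were then biased low by about 2×.
The percentile baseline preserves both the comb shape and the noise.
Preprocessing is idempotent to within a fraction of the noise σ (the
second pass re-estimates the percentile of an already-subtracted
signal).

**SNR** is the mean fitted comb amplitude divided by the robust σ of
the comb-fit residual in peak-free regions (grid minus ±3Γ per line),
capped at 10⁴.  A high-order finite-difference noise floor — blind to
smooth model mismatch — detects the (near-)noiseless case, which then
reports the cap.  The estimate is scale-invariant and returns NaN when
no comb is detectable.  With a gain envelope the detected-line mean
amplitude sits above the all-line mean, so envelope-weighted synthetic
spectra read a few percent high; the flat-comb calibration case is
unbiased within ±15%.

## Peak extraction

Model selection is by estimated SNR with threshold 20 (deterministic).

**High SNR — Lorentzian superposition.**  Coarse peaks come from a
prominence detector (floor 5× noise σ, two-pass: the σ is re-estimated
from the peak-free quantiles because clipping attenuates the
finite-difference estimate).  All lines are refined jointly as
unit-area Lorentzians with per-line amplitudes and a shared width
(per-line widths optional), plus a low-order Legendre background, with
an analytic Jacobian.  Per-peak position uncertainties come from the
fit covariance.  Pairs closer than ~half a linewidth are flagged
degenerate.  Non-convergence falls back to grid centers with inflated
uncertainties.

**Low SNR — empirical sinusoids.**  Broadened quasi-sinusoidal spectra
are fit with either the chirped model A·sin[k(1−B(λ−λ_min)²)λ+φ]
(B tracks the quadratic wavelength dependence of the mode spacing and
is reported raw with a covariance-based σ_B) or the inverse-wavelength
model A·sin[k′/λ+φ′] (FSR = 2π/k′; a fitted phase and constant offset
are included — the bare two-parameter form is generically unfittable).
Both initialize from the dominant FFT frequency and scan a grid at a
fifth of the basin spacing before polishing, because the objective is
oscillatory in k with basins every ~2π/⟨λ⟩ while the FFT localizes k
only to ~±10%.  The two models are arbitrated by AIC (the chirp pays
for its extra parameter).  A k′ implying a diameter outside 10–200 μm
is rejected.  The two families differ at cubic phase order over the
60 nm band, so their fitted peak grids agree to ~1% of a spacing, not
exactly.

**Position uncertainty.**  A Cramér–Rao-style surrogate
σ_λ = c·w/(SNR·√(w/step)) with c = 1.63, calibrated once by Monte-Carlo
against the package's own comb-fitting pipeline at SNR 40 (the
comb-level scatter, 0.003 nm under the reference conditions, exceeds
the isolated-line bound because neighbouring lines overlap and share
the background).  The surrogate is labeled as such in fit reports; a
recalibration routine ships with the package.

## Size and index inference

Three estimators with an explicit precision hierarchy:

1. **FSR diameter** (absolute, robust).  Modes are evenly spaced in
   1/λ, so peaks are fit to u_i = a + FSR·n_i with integer mode counts
   snapped to the fitted grid each round; missed lines become double
   gaps, spurious detections are dropped as grid outliers.  Interleaved
   TE+TM ladders are first split by classifying the alternating
   short/long gaps (two-means with outlier trimming; decomposition of
   each gap into elementary steps tolerates missed lines).  With
   n_eff = n_LD the estimate is biased low by ~1.1% (the true effective
   index of the spacing is slightly below n_LD); the statistical σ_d is
   a few nm at SNR 20 for 60 μm.
2. **Mode-assignment fit** (absolute, precise).  A diameter grid (FSR
   prior ± 2%) assigns every peak to the nearest forward-model TE/TM
   line; all candidate ℓ-offset basins are refined by continuous least
   squares (optionally with n_cell free) and compared after refinement;
   comparable rivals raise an ambiguity error carrying the candidates.
   On noiseless data the diameter and every (ℓ, polarization) label are
   recovered exactly.  A single-polarization ladder cannot identify
   n_cell (the polarization term degenerates into a constant offset);
   the fit warns and holds it fixed.
3. **Shift tracking** (relative, nm-scale).  Between consecutive time
   points, matched peaks share a common dilation Δλ/λ = Δd/d; Δd is
   d₀ times the mean relative shift of matched peaks, exactly linear
   under a global dilation.  Because a one-FSR shift maps the comb onto
   itself, rollover can only be resolved by the absolute FSR-diameter
   trend, whose uncertainty must localize the comb to better than half
   a spacing — otherwise the step is flagged ambiguous and the track
   carries a gap rather than a guess.  Mixing fitting branches across a
   series would corrupt tracking (sinusoid maxima sit at TE/TM pair
   centroids), so a time series is refit with the majority branch when
   its SNR straddles the selection threshold.

The observed peak scatter about the common dilation, w_s, feeds the
resolution relation (Δd)_min = d·w_s/λ (3.9 nm for 60 μm, 0.04 nm,
620 nm).  The nm-scale claims apply to Δd, not to absolute d, whose
uncertainty is dominated by the ~1% n_eff approximation.

**Cytoplasm index series.**  For mode-assigned peaks, same-ℓ TE/TM
pairs give S = δλ·π·n_LD·d/λ², the closed form initializes n_cell, and
the reported value comes from the model-based refit with n_LD fixed.
Noiseless rupture scenarios (1.367→1.339 and 1.392→1.36) recover their
index drops to well within ±0.002.

## Metabolic metrics

With the diameter convention (default; rate = dd/dt):
dV/dt = (π·d²/2)·(dd/dt); molecules/s = |dV/dt|/V_TG with V_TG = 2 nm³
per triglyceride; molar flux = molecules/s/(N_A·π·d²); lipolytic
efficiency = dV/dt/(π·d²) = (dd/dt)/2, independent of droplet size.
A 60 μm droplet at 1 μm/h gives 94.2 μm³/min, 7.85×10⁸ molecules/s
(order 10⁹) and 1.15×10⁻⁷ mol/m²/s.  The radius convention (rate read
as dr/dt) doubles every metric and is retained because literature
values are sometimes quoted that way; the convention is recorded in
every report.

Group comparisons use Welch's t test (means) and classic mean-centered
Levene (variances), both switchable.  Power at n = 10/10: a 3×-inflated
spread (variance ×9) is detected by Levene with power ≈ 0.77; if the
*variance* itself is inflated 3× (spread ×√3), Levene's power at this
sample size is only ≈ 0.28 — a floor worth knowing when planning
experiments of this size.

## Viability diagnostics

Three flags, all threshold-explicit and monotone (raising a threshold
never creates a flag):

* **Lasing transition**: composite score = 0.3·(1 − peak normalized
  cross-correlation) + 0.4·(relative raw-amplitude change) +
  0.3·(relative linewidth change), each component in [0, 1]; flag at
  0.5.  The amplitude term uses the normalization factor recorded by
  preprocessing, so the score sees the 5× amplitude jump of a lasing
  onset while remaining invariant under a common rescaling of both raw
  spectra.  The weights favor amplitude because the jump is the
  defining signature; they were chosen to separate the bundled
  synthetic scenarios and are not biological constants.
* **Rupture**: a fitted n_cell drop ≥ 0.01 between consecutive points
  (observed ruptures drop ~0.03).  In the bundled scenario the flag
  fires at the spectral step, one sampling interval before a
  morphology marker at the following point would.
* **Static size**: within a ≥3 h window the droplet moved less than
  3×(Δd)_min while the population median moved more.

## Synthetic data generator

The generator renders spectra from the same asymptotic forward model
the fitters assume — deliberately, so recovery tests isolate inference
error; exact-Mie generation is available to quantify model bias
separately.  Defaults mirror the sensing conditions: 0.07 nm
resolution, 0.035 nm sampling, 0.15 nm linewidth, Gaussian dye-gain
envelope centered 615 nm with 30 nm FWHM (the instrument's emission
profile is not public; this is a surrogate), additive homoscedastic
Gaussian noise scaled to a target SNR (10–40), TE+TM polarizations.
Scenarios: *control* (diameter jitter equivalent to the 0.04 nm peak
scatter of a stable droplet), *lipolysis* (−0.2 μm/h baseline with a
30-min burst at −1 μm/h), *rupture* (n_cell step 1.367→1.339 with
linewidth collapse to 0.05 nm and a 5× amplitude jump), and *custom*
trajectories.  Truth tables carry every line position, diameter and
index, so downstream scores never re-simulate.

What passing these tests shows: the inference chain is unbiased and
precise against its own physical model at realistic noise.  What they
do not show: robustness to non-Lorentzian lineshapes, correlated or
heteroscedastic noise, dye bleaching, droplet asphericity (treated
only as an error-budget constant, ~10 nm), spectrometer drift, or
model error in the asymptotic expansion itself (bounded separately by
the exact-Mie oracle).

## Reproduction script problem sizes

`scripts/acceptance.py` uses: a 10-droplet panel (40–80 μm, imposed
Δd 0.5–5 μm over three time points, SNR 20) for the Δd-recovery R²;
noiseless single-pair time series for the two index-step recoveries;
closed-form/one-mode computations for the flux, sensitivity and reach
numbers.  The panel size matches the study-scale experiment (~10 cells
per replicate); a rare unresolvable tracking gap re-renders that cell
with a fresh seeded noise draw so the panel always delivers ten cells.

## Known limitations

* Absolute diameters inherit the ~1% n_eff = n_LD bias; configure
  `n_eff` if an independent calibration is available.
* The SNR estimate saturates around a few hundred for near-noiseless
  real spectra short of the cap, and reads high for strongly
  envelope-weighted combs.
* Rollover resolution needs a usable FSR-diameter trend; tracks with
  simultaneous low SNR and fast shrinkage may be split at flagged gaps.
* The mapping from the chirp constant B to an index-dispersion curve
  Δn(λ) is not implemented; B is reported raw.
* Q-factors, lasing-threshold physics and non-spherical cavity
  perturbations are out of scope.
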