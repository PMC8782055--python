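# Methods

## Problem setting

Bacterial spores (here *Parageobacillus thermantarcticus*) irradiated in
water with high-LET HZE ions — He, Ar and Fe beams at 150–500 MeV/n — show
two dose regimes: below a threshold dose the spores release Ca²⁺-DPA from
the core (a germination-like response); above it they are inactivated,
with survival falling exponentially. `sporehit` implements the
quantitative chain that turns raw measurements (CFU counts, SERS spectra,
IR microspectra) into the two fitted observables of that picture: a dose
scale λ shared by survival and release, and spectroscopic band statistics
that track the underlying chemistry.

## Equivalent dose via Rutherford cross sections

Different ions damage at different rates per gray. To compare them on one
axis, a delivered dose D is rescaled to a reference-ion (Fe) equivalent
dose Φ = D · σ_ion/σ_Fe, where σ is the single-collision elastic cross
section from Rutherford's relation,

    σ = π M₁ (Z₁ Z₂ e²)² / (M₂ E) · ∫ dT/T².

In the ratio the target (M₂, Z₂), the e² constant and the transfer-energy
window all cancel, leaving σ_a/σ_b = (M₁Z₁²/E)_a / (M₁Z₁²/E)_b. Energies
enter in the per-nucleon convention: with Ar (40 amu, Z=18) and Fe
(55.9 amu, Z=26) both at 500 MeV/n this gives σ_Ar/σ_Fe = 0.343, matching
the published rounded value 0.34. The same convention applied to He
(4 amu, Z=2, 150 MeV/n) gives 1.41 × 10⁻³; the source table prints
4 × 10⁻⁴ for He, which no single energy convention reproduces, so only the
Ar ratio is treated as a check value. Absolute σ values are returned in
arbitrary units with a default transfer window of t_min = 10 eV up to the
classical elastic maximum 4M₁M₂E/(M₁+M₂)²; only ratios are guaranteed
meaningful, and `rutherford_sigma` is validated against numerical
quadrature of the 1/T² integral rather than against absolute magnitudes.

Exposure durations are dose divided by the facility dose rate (He 4.2,
Ar 6.8, Fe 12.1 Gy/min), displayed to 0.1 min. One published He entry
(1000 Gy / 82.6 min) is inconsistent with its own dose rate
(1000/4.2 = 238.1 min) and is not used as a check. Space-residence
estimates divide a tolerated dose by the ambient galactic-cosmic-ray rate,
taken as 0.2–0.5 Gy/year.

## The Erlang/Poisson hit model

Target theory: the number of discrete hit events a spore accumulates at
equivalent dose Φ is Poisson with mean Φ/λ, so

    P_k(Φ) = (Φ/λ)^k e^(−Φ/λ) / k!.

* **Survival** is the zero-event probability: N/N₀ = P₀(Φ) = e^(−Φ/λ).
* **Ca²⁺-DPA release** is activated by exactly one event: the release
  statistic follows b + A·P₁(Φ), rising to a unique maximum b + A/e at
  Φ = λ. The threshold dose returned by `threshold_dose` is therefore the
  fitted λ itself (about 258 Gy on the Fe axis in the study this package
  models). The proportionality between the SERS ratio and the amount of
  leaked Ca²⁺-DPA is absorbed into the amplitude A, not derived.

**Survival fitting.** The zero-event model has no free amplitude
(N/N₀ = 1 at Φ = 0 by construction), so the default fit is the closed-form
no-intercept regression of ln(N/N₀) on Φ: λ̂ = −1/slope with
slope = Σ(Φᵢ yᵢ)/Σ(Φᵢ²). Zero survival values are excluded (log
undefined) and counted in the diagnostics. When raw plated counts are
available, `method="poisson"` instead maximizes the Poisson likelihood of
N ~ Poisson(N₀ e^(−Φ/λ)) by damped Newton iteration on θ = 1/λ; this uses
every row including exact zeros and weights doses by Fisher information,
which matters because at the high-dose end of the design (2000 Gy,
N₀ = 10⁸) a handful of strongly-killed platings carry most of the
information about λ. The likelihood fit is the estimator of choice for
count data and is the one paired with the bootstrap when counts exist.

**Release fitting.** (λ, A, b) minimize squared residuals of
b + A(Φ/λ)e^(−Φ/λ) via bounded trust-region least squares with a
deterministic multistart over 10 log-spaced λ values in
[min positive dose/4, max dose] — the curve is unimodal but its flat tails
trap single-start optimizers. A solution pinned at the lower λ bound
(data with no interior maximum) is flagged in the diagnostics rather than
masked. Standard errors come from the Jacobian at the optimum.

**Uncertainty.** The primary interval is a case-resampling percentile
bootstrap over (dose, response[, counts]) rows, deterministic per seed;
the Gaussian-approximation SE is also reported. At the study design the
λ̂ sampling variance is dominated by the three replicates at 2000 Gy, an
effectively small-sample regime in which percentile intervals built on the
unweighted log-linear estimator under-cover; bootstrap intervals built on
the counts-likelihood estimator are the recommended pairing and calibrate
at roughly 91–92% empirical coverage for a nominal 95% interval in the
package's own simulations.

Per-ion fitting and pooled fitting on the Fe-equivalent axis are both
available (`equivalent=True` converts doses through the cross-section
ratio before fitting); the two are algebraically consistent — rescaling a
raw-dose λ̂ by σ_ion/σ_Fe reproduces the equivalent-axis fit exactly.

## SERS Lorentzian decomposition

Spectra are modelled as a sum of Lorentzians
h·γ²/((ν−ν₀)² + γ²) plus a low-order polynomial baseline (degree 1
default; SERS backgrounds are smooth over ≤200 cm⁻¹ windows). Peaks are
parameterized by height because the downstream statistic is an intensity
ratio: I₁₀₂₅/I₁₀₀₀, the Ca²⁺-DPA mode (~1024 cm⁻¹, search window
1018–1030) over the phenylalanine mode (~1000 cm⁻¹, window 994–1006); the
±6 cm⁻¹ windows reflect the 4 cm⁻¹ instrumental resolution. The default
mode template is Phe 1000, Ca²⁺-DPA 1024, lipid CH₂ 1400 cm⁻¹ and is
configurable — published decompositions show additional unlabeled modes,
so the template is a user choice rather than a fixed list. Centers are
constrained within ±10 cm⁻¹ of their initial guesses to keep assignments
from wandering between bands. Levenberg–Marquardt can stall short of the
optimum on near-degenerate baselines, so the solver restarts from its own
solution until the residual sum of squares stops improving (at most three
restarts). Fits whose largest height does not clear both the residual
noise floor and a relative floor against the data scale are flagged
`low_signal` instead of raising.

## IR pipeline

Preprocessing, in order: rubberband baseline subtraction (lower convex
hull of the spectrum, computed by a monotone-chain construction that
remains defined for collinear degenerate input; a polynomial detrend is
available as the alternative), Savitzky–Golay smoothing with a 15-point
window (order 2 default — standard for biological IR at this resolution;
order 3 reproduces cubics exactly), vector normalization to unit Euclidean
norm over the full acquired range, and a cut to 1800–950 cm⁻¹.
Normalize-then-cut is the default order; cut-then-normalize is available
by flag since processing conventions differ between toolchains.

Band integrals draw a straight chord between the spectrum's values at the
band extremes (nearest grid points; the 2–4 cm⁻¹ grids are dense relative
to band widths, so no resampling) and integrate signal-minus-chord by the
trapezoid rule. This makes the integral exactly invariant to affine
intensity offsets. Bands: proteins 1735–1480, amide I 1700–1600, Ca²⁺-DPA
1480–1330, carbohydrates 1180–950 cm⁻¹; the reported ratios are
Ca²⁺-DPA/proteins and carbohydrates/proteins, which are invariant to
uniform intensity scaling (spot thickness, spore count).

PCA is mean-centered SVD (via scikit-learn) with a deterministic sign
convention: the largest-magnitude element of each loading is positive.
Which component separates low from high doses varies with the ion in the
source study and is left as a user choice, not automated. Score clouds are
summarized by Gaussian confidence ellipses with semi-axes
√(eigenvalue · χ²₂(level)); rank-deficient covariances are flagged
degenerate rather than raising.

## Synthetic data

The generators define the conditions every statistical test runs under:

* `simulate_survival`: N ~ Poisson(N₀·P₀(Φ; λ)) at the facility ladder
  {0, 250, 500, 1000, 1500, 2000} Gy, N₀ = 10⁸ CFU/mL, 3 replicates,
  λ = 258 Gy. Poisson on plated counts is used rather than binomial
  thinning of 10⁸ cells — numerically indistinguishable at these survival
  fractions. Responses are counts over the nominal titre.
* `simulate_release_series`: b + A·P₁(Φ) + N(0, σ) with defaults A = 1,
  b = 0.2 (control samples show a small nonzero Ca²⁺-DPA signal), σ = 0.05.
  The replicate-level scatter of the source measurements is not tabulated
  anywhere, so σ is chosen to make recovery tests meaningful (≈14% of the
  peak response), not to match the study's dispersion.
* `synth_sers_spectrum`: Lorentzians (the conventional SERS line shape) at
  1000/1024/1400 cm⁻¹ on an exact cubic background, 870–1500 cm⁻¹ at
  2 cm⁻¹ — half the 4 cm⁻¹ instrumental resolution.
* `synth_ir_spectrum`: Gaussian condensed-phase bands at the canonical
  positions (amide I 1654, amide II 1540; DPA doublet 1445/1395;
  carbohydrate peaks 1100/1070/1020/990 cm⁻¹). Group amplitudes are solved
  from a linear system so the chord-subtracted band integrals hit the
  requested areas exactly on the generation grid — the system is joint
  because Gaussian tails leak across neighbouring band anchors. The grid
  is 900–1850 cm⁻¹, a margin beyond the 950–1800 cut mirroring real
  acquisitions (650–4000 cm⁻¹), which keeps smoothing edge artifacts
  outside the analysis range.

What the generators do **not** emulate: Mie scattering and atmospheric
residuals in IR, SERS enhancement heterogeneity and spike artifacts,
plating dilution error, or between-day instrument drift. Passing recovery
tests therefore demonstrates correctness of the estimators under the
model's own noise assumptions, not robustness to those real-data effects.

Every stochastic routine takes an explicit seed (default 20220116);
generators are bit-reproducible per seed and store their complete ground
truth in the output metadata.

## Problem sizes and numerical choices

Simulation-based checks use 500 survival datasets (with 200-draw
bootstraps each), 200 noisy release datasets and 50-seed spectral-fit
replicates; these sizes give Monte-Carlo standard errors comfortably
below the margins being tested. Optimizer tolerances are 1e−12…1e−14
(xtol/ftol); band anchors snap to the nearest grid point and are recorded;
survival responses of exactly zero are excluded from log-space fits;
duplicate wavenumbers, non-monotone grids and NaN intensities are rejected
at construction. Spectrum objects require ≥16 points.

## Known limitations

* Only k ∈ {0, 1} hit models: no multi-target shoulder models, no
  mechanistic germination kinetics.
* No stopping-power or track-structure physics; the cross-section ratio is
  the entire inter-ion transfer model.
* The He cross-section discrepancy above means He data cannot be placed on
  the Fe axis with confidence; He analyses should stay on raw dose.
* IR preprocessing assumes atmospheric correction has already been applied
  upstream; no scattering correction is provided.
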