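# Methods

## Exchange model

The saturation-transfer experiment is modelled as two-site exchange between
an observed pool (Pi(i) or PCr) and γ-ATP under continuous saturation of the
latter. The observed longitudinal signal fraction is

    S(τ)/S₀ = k_f·T_app·e^(−τ/T_app) + T_app/T1,   1/T_app = 1/T1 + k_f,

equivalently R_∞ + (1 − R_∞)·e^(−τ/T_app) with R_∞ = 1/(1 + k_f·T1). The
package deliberately carries **two independent implementations** of this
relation — the generator uses the steady-state/transient decomposition
(`synthetic_data.decay_fraction`), the fitting side the direct form
(`exchange_kinetics.saturation_model`) — plus a third, numerical route: a
two-pool Bloch–McConnell longitudinal ODE with the saturated pool clamped
(`bloch_mcconnell_decay`). Tests require agreement of all three to 1e-6
relative over k_f ∈ [0, 1] s⁻¹, T1 ∈ [1, 7] s, τ ∈ [0, 10] s, so round-trip
checks never validate a formula against itself.

Assumptions: complete, instantaneous saturation of γ-ATP (the generator's
γ-ATP amplitude decays with a 50 ms onset constant, effectively instant on
the τ grid); no direct RF bleed onto Pi/PCr (adiabatic selective pulses);
mono-exponential longitudinal relaxation; full recovery between scans
(TR 12 s, 60 s inter-scan pause).

### Fitting

`fit_kf` estimates (k_f, S₀) by unweighted bounded least squares
(k_f ∈ [0, 2] s⁻¹) with T1 clamped — 3.1 s for Pi(i), 5.1 s for PCr by
default. Weighted fits are available but off by default, since per-point
errors enter reports only descriptively. `fit_kf_float_t1` adds T1 within
[1, 7] s from five starts; with seven noisy points the joint fit is weakly
identified — in simulation at per-point scatter σ ≈ 0.08 roughly a third of
fits pin T1 at a bound and nearly all carry T1 standard errors above 0.5 s —
which is why the fixed-T1 analysis is the default. `fit_group_mean` averages
subject curves pointwise on a common τ grid and fits the mean
(mean-then-fit); because the model is nonlinear in k_f this differs from the
mean of individual fits, and cohort runs report both.

Intracellular pH uses the phosphate titration relation
pH = 6.66 + log₁₀((δ − 3.08)/(5.57 − δ)) on the fitted Pi(i) shift, valid on
(3.08, 5.57) ppm. Note this relation evaluated at the canonical ~4.9 ppm
shift yields pH ≈ 7.09; reported in-vivo cohort values near 7.5 would
require a different shift reference, so pH is reported but never used as a
validation target.

## Synthetic data generator

Each scan is a complex FID: one damped complex exponential per resonance
(amplitude A, shift δ ppm at 49.9 MHz, T2* = 1/(π·FWHM)), a broad 500 Hz
component standing in for the phospholipid baseline, frequency-domain
0th/1st-order phase errors, and i.i.d. complex Gaussian noise. Defaults:
2048 points, 3000 Hz bandwidth, peaks PME 6.8 / Pi(e) 5.2 / Pi(i) 4.9 /
PDE 2.9 / PCr 0 / γ,α,β-ATP −2.5, −7.5, −16 ppm with PCr:Pi(i) amplitude
≈ 4.5:1. Under a saturation condition, Pi(i) and PCr amplitudes are scaled
by the decay fraction at the condition's τ; the +15 ppm control and the
+2.5 ppm selectivity check leave all peaks untouched (the broad baseline is
identical across conditions, mirroring equal phospholipid suppression).

Study conditions fixed once: per-point noise sd 0.025 (spectral Pi(i) SNR far
above detection threshold; normalised-area scatter ≈ 2%, so the Pi(i) drop is
small but obvious at long τ), per-session phase errors N(0, 0.15) rad and
N(0, 0.02) rad/ppm, subject-level pre-treatment rates N(0.2, 0.05) s⁻¹, and a
paired treatment effect N(+0.1, 0.03) s⁻¹ (post = pre + effect). The paired
design reflects the within-subject nature of the measurement; an unpaired
mode exists. The generator does **not** model B1 inhomogeneity, motion,
frequency drift, RF bleed, or non-Lorentzian in-vivo lineshapes — passing
round-trip tests therefore demonstrates correctness of the analysis chain
under the stated forward model, not robustness to every in-vivo artefact.

## Spectral processing

Filter → FT → phase → baseline: apodisation (default 5 Hz Gaussian;
exponential available, the dialect is recorded in provenance), FFT with the
first point halved (trapezoid rule; suppresses the half-sample baseline
offset), ppm axis = Hz / 49.9 MHz with PCr at 0, axis decreasing
left-to-right. Every step appends to an append-only provenance record;
`replay` reproduces a spectrum bit-identically from the raw FID.

Automatic phasing is a two-stage estimator standing in for the manual
phasing a spectroscopist would do. Stage 1 fits a complex Lorentzian with
free phase plus a complex quadratic baseline locally around each isolated
magnitude peak; the per-peak phases are regressed against ppm (weights:
peak area attenuated by the phase-estimate variance, with iterative outlier
rejection). With ≥3 isolated peaks spanning >5 ppm the regression is
accepted directly (noiseless recovery ≲ 0.01 rad; at default noise, phase
error at the Pi region ≈ 0.02 rad sd). Degenerate spectra fall back to
Nelder–Mead minimisation of the squared negative part of the
median-detrended real spectrum, with a small φ1 ridge. Spectra with no peak
above 5× the edge-noise floor are flagged and left unphased.

Baseline removal fits a fourth-order polynomial to the real part outside
±0.5 ppm exclusion windows around the assigned peaks and subtracts it
everywhere. Windows are (low, high) closed ppm intervals throughout.

## Peak fitting

The 4–6 ppm window is fitted by Levenberg–Marquardt (lmfit) with two
Lorentzians (Gaussian optional) — chemical shift, height and FWHM free,
centers bounded to the window, FWHM ∈ (0.01, 1) ppm, heights ≥ 0 — plus a
refit quartic baseline inside the window. Pi(i) is the component with the
lower fitted shift, initialised at 4.9/5.2 ppm. Areas are analytic
(Lorentzian h·π·FWHM/2; Gaussian h·FWHM·√(π/4ln2)). Windows whose signal
span is below 3× a first-difference noise estimate are flagged; collapsed
doublets trigger a flagged single-peak fallback. Saturation curves normalise
per-condition areas to the +15 ppm control; point errors combine the two
fits' area uncertainties (parameter covariance when available, residual RMS
otherwise) in quadrature.

The noiseless end-to-end round trip recovers k_f to ≲0.05% relative. The
residual floor (~5e-4 relative at k_f = 0.25) is model mismatch inherent to
the procedure itself — pure Lorentzians plus a quartic fitted to
Gaussian-filtered discrete-FT lineshapes — not an implementation artefact.

## Cohort statistics

Wilcoxon signed-rank: zero differences (|d| ≤ 1e-12) dropped, midranks on
|d|, exact two-tailed p by full enumeration of the 2ⁿ sign patterns
(meet-in-the-middle subset sums, n ≤ 25), asymptotic Z with tie-corrected
variance and no continuity correction, computed from the smaller rank sum
(hence Z ≤ 0; an all-positive n = 7 sample gives Z = −2.366, p = 2/128).
Kendall tau-b: O(n²) pair counts with tie corrections; exact permutation p
(full n! enumeration) for n ≤ 8, tie-aware asymptotic p otherwise.
Normality screening: Kolmogorov–Smirnov D against a normal with estimated
parameters, p from a seeded Monte-Carlo null with parameters re-estimated
per replicate (Lilliefors-style), add-one estimator. No multiple-testing
correction is applied anywhere.

## Photon transport

Standard MCML mechanics in plane-parallel layers: pencil beam at normal
incidence, specular loss at the top interface, step length −ln ξ/(μa+μs),
absorption deposited as w·μa/(μa+μs) per interaction, Henyey–Greenstein
deflection, unpolarised Fresnel reflection/refraction with total internal
reflection at index-mismatched boundaries. Because the exponential free
path is memoryless, a fresh step is drawn after each boundary crossing,
which is statistically exact. Termination: packets below weight 1e-4
deposit their residual in the current layer, so
reflectance + transmittance + Σ absorbed = 1 to float precision on every
run (Russian roulette conserves weight only in expectation, with realised
imbalance ~1e-6 at 10⁵ photons); the attribution bias is bounded by the
1e-4 threshold, far below Monte-Carlo noise. Standard errors come from
splitting photons into 10 independently seeded batches. The engine
reproduces published benchmarks: finite slab (albedo 0.9, optical depth 2,
g = 0.75, matched boundaries) Rd = 0.0977 / T = 0.660 vs 0.09739 / 0.66096,
and a semi-infinite isotropic medium with n = 1.5 giving total reflectance
0.2593 vs 0.2600.

### Head model and chromophores

Default stack: melanised epidermis 0.01 cm, scalp dermis 0.39 cm, skull
0.7 cm, CSF 0.2 cm, semi-infinite grey matter. Melanin is confined to the
epidermal sublayer (its melanosome volume fraction is the model's "melanin
fraction", 0.04 pale … 0.43 dark); a 0.4 cm scalp uniformly loaded with
melanosome absorption would extinguish red light entirely, contradicting
observed transcranial transmission. μa(λ) composes linearly from a shipped
CSV of chromophore spectra — whole-blood Hb/HbO₂ (Prahl-style anchors),
water (Hale & Querry anchors), the Jacques melanosome power law
519·(λ/500)⁻³·⁴⁸, and smooth **synthetic approximations** of the cytochrome
c / cytochrome c oxidase bands (~695 nm haem iron–Met80, broad ~830 nm
copper centre) — plus a flat per-layer background. The CSV is editable and
its header documents the provenance; absolute dosimetry numbers are
coefficient-dependent and only robust, ratio- or bound-type statements are
asserted in tests. Scattering follows μs'(λ) = a·(λ/500)⁻ᵇ per layer; the
default model uses the transport-equivalent isotropic representation
(g = 0, μs = μs'), which by the similarity relation leaves layer-resolved
fractions unchanged within Monte-Carlo noise while sampling ~10× fewer
collisions; anisotropic layers are fully supported. The grey-matter CCO
concentration is set so its share of grey-matter μa at 670 nm is ~7%,
consistent with the small in-vivo NIRS contribution of cytochrome.

Reported dosimetry quantities are normalised to light *entering the head*
(incident minus specular reflection): the fraction reaching grey matter
(first-crossing weight), the fraction absorbed in grey matter, and the
cytochrome share thereof (grey-matter absorption × μa_CCO/μa_GM, i.e.
attribution by absorption share, not separate chromophore tracking).

## Numerical choices and degenerate inputs

k_f bounds [0, 2] s⁻¹ (negative trends clamp to 0 and flag); T1 float
bounds [1, 7] s; degenerate equal bounds reduce to the fixed fit. Fits that
fail to converge or pin a parameter are flagged, never silently accepted.
The ppm axis is strictly monotonic by construction; saturation curves
require ≥3 distinct τ. Photon counts < 1, melanin fractions outside [0, 1]
and wavelengths outside the chromophore tables are hard errors (no
extrapolation). All randomness — generator, Monte-Carlo, KS null — flows
from explicit integer seeds; fixed seeds give byte-identical cohort bundles
and bit-identical tallies.

## Problem sizes

Validation uses desk-scale sizes chosen as sufficient for the stated
tolerances: 200 replicate curve fits for recovery statistics, 5-seed
7-subject phantom cohorts for the end-to-end power check, 10⁵ photons per
wavelength on a 25 nm grid for dosimetry (tally standard errors ≲2% where it
matters), and 2000-replicate Monte-Carlo nulls for the normality screen.

## Limitations

No B1/voxel/motion modelling; no inversion-transfer variant; no absolute
flux in mM/s (needs absolute [Pi]); no nuclear Overhauser corrections; no
voxelised anatomy, bio-heat transfer, time-resolved transport, or hair-fibre
scattering. Pi(e) is held constant under saturation (no exchange pathway
modelled). The cytochrome spectra are constructed approximations adequate
for band positions and ratios, not absolute cross-sections.
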