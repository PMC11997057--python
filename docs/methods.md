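# Methods

## Two-site exchange model and fitting

The exchange module treats prolyl cis–trans isomerization as a two-site
first-order exchange between a cis state (population p_c) and a trans state
(population p_t), with rate constants k_ct (cis→trans) and k_tc (trans→cis).
At equilibrium, detailed balance gives p_c = k_tc/k_ex and p_t = k_ct/k_ex
with k_ex = k_ct + k_tc. During an EXSY mixing period, magnetization
transfer between the sites yields a cross/diagonal volume ratio

    R(t) = {1 − e^{−k_ex t}} k_tc / {k_ct + k_tc e^{−k_ex t}},

which rises monotonically from 0 to the plateau k_tc/k_ct. Auto-relaxation
is assumed equal for both conformers, so the common decay factor e^{−R1 t}
cancels exactly in the ratio; this is the key assumption that lets the ratio
be fitted without knowing R1. Unequal relaxation rates, cis→cis peaks, and
full Bloch–McConnell fitting are out of scope.

**Fitting.** `fit_exchange` minimizes Σ wᵢ (R(tᵢ) − rᵢ)² by
Levenberg–Marquardt (MINPACK `leastsq`) over (log k_ct, log k_tc); the log
parameterization enforces positivity without constraints. Weights are
wᵢ = 1/σᵢ² when every ratio error is finite and positive (the default
"auto" mode), and 1 otherwise. Convergence tolerances are
ftol = xtol = 1e-12 with at most 5000 function evaluations — tight enough
that noiseless model-generated data are recovered to better than 1e-6
relative error across rates in 0.5–50 s⁻¹. The default initial guess is
k_ct⁰ = k_tc⁰ = 1/median(t), which is scale-free and always in range; if
that start fails to converge, a second start derived from the initial slope
(≈ k_tc) and plateau (≈ k_tc/k_ct) of the data is tried. Non-convergence is
reported via `converged=False`, never silently.

**Uncertainties.** Standard errors come from the covariance of the
estimate, transformed from log-rate to rate scale by the delta method;
se(k_ex) uses the full summed covariance. For weighted fits the supplied
errors are treated as absolute (no reduced-χ² rescaling) — this is what
makes the ±1 se intervals calibrated when the error bars are themselves
propagated from the generating noise level. For unweighted fits the
covariance is rescaled by the reduced χ². A parametric-bootstrap
alternative (`se_method="monte_carlo"` or `monte_carlo_errors`) refits
Gaussian draws around the fitted curve; both routes are offered because a
published uncertainty may originate from either, and covariance is the
default.

**Error propagation.** The ratio error is computed in the algebraically
equivalent finite form sqrt[(dCT/T)² + (CT·dT/T²)²], identical to the
textbook sqrt[(dT/T)² + (dCT/CT)²]·CT/T whenever CT > 0 but finite
(reducing to dCT/T) at CT = 0, so the shortest mixing time never produces
an undefined error bar.

**Peak volumes.** `extract_peak_volume` fits one elliptical 2D Gaussian
plus a flat baseline inside a user window and reports the analytic volume
2π·A·σ₁·σ₂ with a delta-method error from the fit covariance. It assumes
one dominant peak per window; overlapping peaks should be windowed apart.

## Native-MS quantification

Observed m/z of [M + nH]ⁿ⁺ is (M + n·1.00728)/n. Peptide masses are
monoisotopic (pyteomics residue table + water), plus 79.96633 Da per
phosphosite. Peak picking finds local maxima above min_snr × a robust noise
scale and refines centroids by 3-point parabolic interpolation; intensity is
the interpolated apex height (peak height, not area — appropriate for
well-resolved native charge states; heights in a fixed-width lineshape are
proportional to areas). The noise scale is the 84.1st-minus-50th intensity
percentile, which equals the baseline standard deviation for Gaussian noise
and remains correct when the baseline is clipped at zero, where a plain MAD
collapses. A prominence gate equal to the height threshold rejects spurious
secondary maxima that noise carves into the flank of a real peak; without
it, a split apex is counted twice and biases that charge state upward.

Assignment matches each picked peak to the nearest theoretical
(species, charge) position within tol_mz (default 1.5 m/z, charges 5–15 for
an ~18 kDa protein); ties break toward lower charge, ties across species
attach an ambiguity warning, and unmatched peaks are reported separately.
Phospho and non-phospho complexes differ by ~8 m/z at 10+, above the default
tolerance, so they are treated as resolvable. Quantification then applies
[x]_eq = Σₙ I(xⁿ⁺)/n and the shared-denominator percent-bound formula.
No baseline subtraction is performed; isotopic structure, envelope
deconvolution and Kd estimation are out of scope.

## CTCF and survival

CTCF = Σ_region I − |region| × mean(I over background). The default
background is the complement of all nuclei eroded by 5 pixels, emulating
manual background readings taken clear of cells; any explicit background
mask can be supplied instead. CTCF is exactly offset-invariant and linear,
and may be negative for regions dimmer than background (reported as-is).
Segmentation is Otsu + hole filling + connected components with a minimum
area filter — adequate for well-separated nuclei; touching nuclei are not
split (no watershed). The γH2AX gate keeps, in untreated mode, only nuclei
whose gate-channel CTCF reaches a threshold (default: 90th percentile of a
negative-control set, since no published threshold exists); irradiated mode
keeps all nuclei.

Survival normalization is
100 × (colonies_treated/seeded_treated)/(colonies_untreated/seeded_untreated);
the untreated point is exactly 100 %.

## Synthetic generators

All generators take an integer seed and are byte-reproducible; each writes a
`SyntheticTruth` sidecar with its full parameter set.

- **EXSY**: I_tt = A·p_t(p_t + p_c e^{−k_ex t})e^{−R1 t},
  I_ct = A·p_t·p_c(1 − e^{−k_ex t})e^{−R1 t}, so the ratio is the exchange
  law exactly for any R1. Noise is multiplicative Gaussian with coefficient
  of variation noise_cv (how NMR volume errors are typically reported);
  sigma columns carry noise_cv × the noiseless volume. Defaults: the 13
  mixing times 12.5–600 ms, R1 = 1 s⁻¹, noise_cv = 2 %.
- **MS**: per (species, charge) a Gaussian peak at the theoretical m/z with
  height abundance·scale·wₙ·n (envelope weights wₙ summing to 1), so
  Σₙ height/n equals abundance·scale exactly; additive Gaussian baseline
  noise, clipped at zero. Defaults: 18243 Da protein, envelope 6–9+ peaked
  at 7+, SDPVTPK ± 1 phosphate ligands, 0.25 m/z grid over 500–6000.
- **Images**: two channels — DNA disks and marker foci (Gaussian spots
  confined to nuclei) over a flat background. noise_sd > 0 applies Poisson
  shot noise plus Gaussian read noise; noise_sd = 0 is exactly noiseless so
  that CTCF recovery against the recorded per-nucleus integrated marker
  signal is a sharp test. Nuclei are placed by rejection sampling with a
  separation margin; impossible requests fail with a clear error.
- **Survival**: colonies ~ Binomial(cells_seeded, plating_efficiency ×
  survival(dose)), defaults 10⁴ cells and 50 % plating efficiency.

What the generators do **not** emulate: realistic spectrometer lineshapes
and phase artifacts, correlated NMR noise, electrospray adducts and salt
clusters, cell-to-cell expression variability, touching or irregular
nuclei, and illumination gradients. Passing recovery tests therefore
demonstrate correctness of the estimators under their stated models, not
robustness to every artifact of real data.

## Problem sizes and numerical choices

Recovery test sizes were chosen to make the checks statistically sharp yet
quick: 50 random rate pairs for the noiseless round trip, 200 noise
replicates for bias/coverage (a 2 % CV puts the k_ex sampling SD near 0.25
s⁻¹, so 200 replicates resolve a 1 % bias), 20 abundance vectors for MS
recovery at a minimum peak SNR of 50, 100 random images for the CTCF
invariances, and 10⁴ seeded cells for survival (binomial SE ≈ 0.5–1
percentage point). Degenerate inputs fail loudly: fewer than 3 ratio
points, zero diagonal volumes (named by mixing time), zero untreated
colonies, overlapping region/background masks, all-zero lineshape windows
(flagged with NaN volume error).
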