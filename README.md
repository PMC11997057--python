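# prolyquant

Quantitative analyses for studies of peptidyl-prolyl cis–trans isomerization
and the cellular assays that usually accompany them. The package bundles four
self-contained analysis surfaces, each paired with a seed-deterministic
synthetic-data generator with known ground truth, so every estimator can be
validated by parameter recovery:

1. **EXSY exchange kinetics** (`prolyquant.exchange`). In a 2D ¹H-¹H
   EXchange SpectroscopY experiment, slow exchange between the cis and trans
   prolyl conformers produces off-diagonal cross-peaks whose build-up with
   mixing time t encodes the rate constants. For two-site exchange with
   cis→trans rate k_ct and trans→cis rate k_tc, the cross/diagonal volume
   ratio follows

       I_ct / I_tt = {1 − exp[−(k_ct + k_tc) t]} · k_tc
                     / {k_ct + k_tc · exp[−(k_ct + k_tc) t]}

   independent of the shared auto-relaxation rate (it cancels in the ratio).
   Levenberg–Marquardt fitting of this curve over a mixing-time series yields
   k_ct, k_tc and the total exchange rate k_ex = k_ct + k_tc with standard
   errors; ratio error bars propagate from volume errors as
   d(CT/T) = sqrt[(dT/T)² + (dCT/CT)²] · CT/T. A simple 2D-Gaussian
   lineshape fitter extracts peak volumes from spectral grids.

2. **Native-MS binding quantification** (`prolyquant.nativems`). Under
   non-denaturing electrospray, free protein P and protein:peptide complexes
   PL appear as charge-state envelopes. The equilibrium abundance of a
   species is its charge-normalized summed peak intensity,
   [x]_eq = Σₙ I(xⁿ⁺)/n, and the percentage of protein bound in a complex is
   100·[PL]_eq/([P]_eq + Σ[PL]_eq), with the shared denominator handling
   two-ligand competition.

3. **CTCF imaging quantification** (`prolyquant.imaging`). Nuclei are
   segmented from a DNA-stain channel (Otsu threshold, hole filling,
   connected components); per-nucleus corrected total cell fluorescence is
   CTCF = integrated density − area × mean background fluorescence, with an
   optional γH2AX-staining gate for untreated cells.

4. **Clonogenic survival** (also in `prolyquant.imaging`). Colony counts are
   normalized to percent survival against the matched untreated plating
   efficiency.

## Worked example

Simulate a 13-point EXSY mixing series (12.5–600 ms) at k_ct = 8.0 s⁻¹,
k_tc = 4.65 s⁻¹ with 2 % multiplicative volume noise, then fit it:

```bash
prolyquant simulate exsy --seed 1 --k-ct 8.0 --k-tc 4.65 --noise-cv 0.02 --out sim
prolyquant fit-exsy sim/exsy_series.csv --out fit
cat fit/exsy_fit.tsv
```

```
sample                k_ct        k_tc        k_ex         se_k_ct  se_k_tc  se_k_ex  residual_ss  n_points  converged
sim/exsy_series.csv   8.06792172  4.629988697 12.69791042  0.1795   0.0696   0.2425   9.43         13        True
```

The fitted total exchange rate k_ex = 12.70 ± 0.24 s⁻¹ recovers the
generating truth of 12.65 s⁻¹ within one standard error; `sim/truth.json`
records the exact generating parameters. The other subcommands follow the
same simulate → analyze pattern: `simulate ms` / `quantify-ms`,
`simulate image` / `quantify-foci`, `simulate survival` / `survival`, and
`report --config run.toml` drives a configured pipeline end to end.

Library use mirrors the CLI:

```python
from prolyquant import synthetic
from prolyquant.exchange import build_ratio_series, fit_exchange

series, truth = synthetic.gen_exsy_series(k_ct=8.0, k_tc=4.65, noise_cv=0.02, seed=1)
fit = fit_exchange(build_ratio_series(series), weighted=True)
print(fit.k_ex, fit.se_k_ex)   # 12.70 0.24
```

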