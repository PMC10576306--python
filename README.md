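# specvar

Variance partitioning of leaf reflectance spectra measured with a
leaf-clip field spectroradiometer.

## The problem

Leaf optical properties (400–2500 nm) carry signatures of pigments (VIS),
leaf structure (NIR), and water / dry matter (SWIR), and so can reveal
genetic differences between plants — but only once measurement artefacts,
background effects and environmental variance are separated from the
genetic signal. `specvar` implements that separation for the standard
leaf-clip protocol, in which each sample is measured with 20 scans under
four conditions: the bare white reference (WR), the leaf on the white
reference (WRL), the bare black reference (BR), and the leaf on the black
reference (BRL).

It is written for plant phenomics and quantitative-genetics groups who
collect leaf-clip spectra across genotypes, environments, measurement
times and batches and want a reproducible, scripted path from raw scans to
per-wavelength inference.

## What it computes

**Calculated reflectance.** With condition means R_c (mean of scans 2–5;
the first scan is always dropped for signal stabilization),

    CR = (R_WR · R_BRL − R_BR · R_WRL) / (R_WR − R_BR)

which is exact under a single-pass transmission model (WRL = R + T²·B_w,
BRL = R + T²·B_b): CR recovers the true leaf reflectance R for any pair of
distinct backgrounds.

**Measurement uncertainty.** The scan-to-scan standard deviations STD_c
propagate to first order through the CR formula,

    AU² = (BR·(WRL−BRL)/(WR−BR)²)²·(STD_WR/√N)² + (BR/(WR−BR))²·(STD_WRL/√N)²
        + (WR·(WRL−BRL)/(WR−BR)²)²·(STD_BR/√N)² + (WR/(WR−BR))²·(STD_BRL/√N)²

with relative uncertainty RU = AU / CR.

**Outlier screening.** Three reproducible steps: a red-edge shape check
(leaf-shaped scans recorded as references and vice versa), Local Outlier
Factor scores per measurement condition within each experiment, and a
post-reflectance bounds + robust-deviation rule with an explicit manual
exclusion list. Removal policy: one flagged scan in a condition drops the
scan, two or more drop the sample.

**Statistics per wavelength.** Coefficient-of-variation spectra with
bootstrap sample-size equalization, covariance PCA with explained variance
and wavelength contributions, one-way ANOVA with η², OLS, and
random-intercept linear mixed models (REML) with marginal / conditional R².
P-values across the 2101 analysis wavelengths are adjusted with the
Benjamini–Yekutieli step-up procedure (valid under arbitrary dependence),
and maximal runs of adjusted-significant wavelengths are reported as
spectral regions.

**Synthetic experiments.** A first-class generator builds raw scan sets
with known ground truth — leaf-like templates, dual backgrounds, genotype
effect spectra, plant/batch/time variance components, scan noise, and
labelled contaminants — so every stage of the pipeline is verifiable.

## Worked example

Simulate a two-group experiment (reference genotype vs. natural variants
carrying a +0.02 reflectance effect over 450–550 nm), screen it, compute
reflectance, and test for group differences at every wavelength:

```python
import numpy as np
from specvar import DesignSpec, simulate_experiment, screen, compute_reflectance
from specvar.synthetic_data import window_effect
from specvar.models import fit_anova_spectrum

effect = window_effect("genotype_group", "PL", 0.02, 450, 550)
design = DesignSpec(seed=1, groups={"REF_UTWT": 20, "PL": 20})
scans, truth = simulate_experiment(design, effects=(effect,))
print(f"simulated {len(scans.sample_ids)} samples, {scans.n_scans} raw scans")

result = screen(scans)
print(f"screen kept {len(result.scanset.sample_ids)} samples ({len(result.flags)} flags)")

rs = compute_reflectance(result.scanset)
print(f"calculated reflectance on {rs.cr.shape[1]} wavelengths, "
      f"median RU = {np.nanmedian(np.abs(rs.ru))*100:.2f}%")

res = fit_anova_spectrum(rs, "genotype_group", eta_ci=False)
for r in res.significant_regions(alpha=0.05):
    print(f"significant region: {r.start_nm}-{r.end_nm} nm "
          f"(min adjusted p = {r.min_p_adj:.1e})")
```

Output:

```
simulated 40 samples, 800 raw scans
screen kept 40 samples (0 flags)
calculated reflectance on 2101 wavelengths, median RU = 0.08%
significant region: 450-550 nm (min adjusted p = 4.5e-04)
```

The screen flags nothing on clean data; the median relative measurement
uncertainty sits below 0.1%, far below the biological variance; and the
BY-adjusted per-wavelength ANOVA localizes the injected genetic effect to
exactly its 450–550 nm support.

A command-line interface wraps the same stages:

```sh
specvar simulate --seed 42 --groups REF_UTWT:10,PL:10 --out synth/
specvar screen --scans synth/scans.csv --meta synth/metadata.csv --out screened/
specvar reflectance --scans screened/scans.csv --meta synth/metadata.csv --out reflectance.csv
specvar model --reflectance reflectance.csv --meta synth/metadata.csv \
    --kind anova --factor genotype_group --out model/
specvar run --config run.yaml     # full pipeline with manifest
```

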