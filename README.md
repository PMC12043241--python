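# imputedim

Simulation pipeline for studying how missing-data imputation interacts with
the **unidimensionality** of test data. It answers a question psychometricians
face whenever respondents skip items on a Likert-type scale: *if I fill the
holes with a standard imputation method, does my instrument still look
unidimensional — and how distorted are the filled-in values?*

The package implements the full factorial design of a Monte-Carlo study of
this question:

1. **Generate** a complete n × k matrix of 5-category responses from
   Samejima's graded response model (GRM): abilities θ ~ N(0, 1),
   discriminations a_j ~ N(1.8, 0.5), four ordered N(0, 1) thresholds per
   item, cumulative category curves
   P\*\_c(θ) = 1 / (1 + exp(−D·a_j(θ − b_jc))).
2. **Mask** cells completely at random (MCAR) at nominal rates from 1% to
   50%, verify the MCAR assumption per rate with **Little's χ² test**, and
   drop rates that fail it (p ≤ 0.05).
3. **Impute** each retained incomplete matrix three ways:
   - **CIM** (corrected item mean): x̂_ij = (PM_i / mean of item means over
     the respondent's observed items) · IM_j,
   - **EM**: maximum-likelihood (μ, Σ) of a joint normal via
     expectation-maximization, then conditional means E[x_mis | x_obs],
   - **MI**: Bayesian multiple imputation by data augmentation
     (Jeffreys prior, m completed datasets, consensus by per-cell mean),
   each rounded to the nearest integer and clipped to 1..5.
4. **Score** every (method × rate) cell: the distribution of
   |original − imputed| over masked cells ("distortion"), Cronbach's α,
   corrected item-total correlations (CITC), the eigenvalues λ1, λ2, λ3 of
   the inter-item correlation matrix with the ratios λ1/λ2 and
   (λ1−λ2)/(λ2−λ3), explained variance of the Kaiser-retained components,
   and communalities.

## Worked example

```python
import numpy as np
import imputedim as im

bank = im.sample_item_bank(k=50, n=2000, seed=7)      # a ~ N(1.8, 0.5)
complete = im.generate_responses(bank, seed=7)
print("alpha:", round(im.cronbach_alpha(complete), 4))

inc = im.apply_mcar(complete, rate=0.30, seed=7)
print("observed rate:", round(inc.observed_rate, 4))
res = im.little_mcar_test(inc)
print(f"little: chi2={res.chi2:.1f} df={res.df} p={res.p_value:.3f}")

result = im.em_impute(inc)
match = 100 * np.mean(result.completed.values[inc.mask] == complete.values[inc.mask])
print("EM exact-match %:", round(match, 2))

bat = im.battery_for(result.completed)
print(f"battery: alpha={bat.alpha:.4f} lambda1={bat.eigenvalues[0]:.2f} "
      f"ratio12={bat.ratio_12:.2f} var1={bat.cum_variance[0]:.2f}% citc={bat.citc_mean:.3f}")
```

prints

```
alpha: 0.9823
observed rate: 0.2996
little: chi2=70042.0 df=69992 p=0.446
EM exact-match %: 48.52
battery: alpha=0.9866 lambda1=31.64 ratio12=19.69 var1=63.29% citc=0.780
```

Reading: the complete data are strongly unidimensional (α = 0.982, first
component 63% of variance). After deleting 30% of cells at random and
imputing with EM, about half the imputed cells hit the original category
exactly, and every unidimensionality indicator *rises* slightly
(α 0.987, λ1 31.6) — conditional-mean imputation smooths responses toward
the common factor, so heavy imputation makes a scale look *more*
unidimensional than it is.

The same pipeline runs end to end via `run_study`:

```python
from imputedim import StudyConfig, run_study
report = run_study(StudyConfig(n=500, k=20, rates=(0.1, 0.3), m=5,
                               mi_iterations=100, mi_burn_in=50, seed=0))
report.write("study_out/")   # table1_mcar.tsv ... appendix3_communalities.tsv
```

or from the shell:

```bash
imputedim run --config configs/ci.yaml --out-dir study_out
imputedim generate --n 2000 --k 50 --seed 7 --out matrix.csv
imputedim mask --in matrix.csv --rate 0.3 --out incomplete.csv
imputedim test-mcar --in incomplete.csv
imputedim impute --method em --in incomplete.csv --out completed.csv
```

`configs/paper.yaml` holds the full study profile (5000 × 50, 22 nominal
rates, MI with m = 100 and 1000 iterations); `configs/ci.yaml` is a small
profile that finishes in seconds.

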