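# radialmvmr

Radial multivariable Mendelian randomization (MVMR) from two-sample GWAS
summary statistics: joint estimation of the direct causal effects of several
exposures on an outcome, exposure-specific heterogeneity decomposition,
per-SNP pleiotropy-outlier detection with iterative pruning, conditional
instrument-strength diagnostics, and the paired unadjusted/adjusted radial
plots that make a multivariable analysis visualisable. A built-in
individual-level simulation engine generates the verification studies
without any external data.

**Who it is for.** Genetic epidemiologists running summary-data MR with
harmonised per-SNP associations (one row per SNP: β and SE for each
exposure, β and SE for the outcome) who want multivariable estimates that
come with per-SNP diagnostics rather than a bare coefficient table.

## The estimator

For SNP *j* and exposures *k* = 1..K, with exposure associations γ̂ₖⱼ and
outcome association Γ̂ⱼ (SE σ̂_Yⱼ), the radial MVMR model is the
no-intercept regression

    Γ̂ⱼ/σ̂_Yⱼ = Σₖ β_IVWk · (γ̂ₖⱼ/σ̂_Yⱼ) + εⱼ ,

whose coefficients are the direct effects — equivalently an
inverse-variance-weighted regression of Γ̂ⱼ on the γ̂ₖⱼ with first-order
weights wₖⱼ = γ̂²ₖⱼ/σ̂²_Yⱼ. Subtracting the fitted contribution of the other
exposures from each point's ordinate gives *adjusted* radial points whose
squared vertical distance from the exposure's fitted line through the origin
is exactly the SNP's contribution Qₖⱼ to the exposure-specific Cochran
statistic Qₖ = Σⱼ Qₖⱼ. SNPs with a Qₖⱼ p-value below α (default 0.05, χ²₁)
for any exposure are flagged as potentially pleiotropic; iterative pruning
removes them and refits until none remain. Instrument strength is reported
as Q-based conditional F-statistics. See `docs/methods.md` for conventions,
calibration and limitations.

## Worked example

Generate one dataset from the stock verification design — 240 SNPs in 8
association groups, three exposures with true direct effects
β = (1, 0.2, −0.5), 30 SNPs carrying a direct (pleiotropic) outcome effect,
N = 200,000 per sample — then fit, flag and prune:

```python
from radialmvmr import (SimConfig, generate_individual_data, fit_radial_mvmr,
                        detect_outliers, prune_iterative)

ds = generate_individual_data(SimConfig.simulation_one(seed=1)).dataset
fit = fit_radial_mvmr(ds)
print(fit.summary().round(3).to_string(index=False))

flagged = detect_outliers(fit, alpha=0.05)
print(f"{len(flagged)} outliers, e.g. {flagged[:5]}")

trace = prune_iterative(ds, alpha=0.05)
print(trace.final_fit.summary().round(3).to_string(index=False))
```

```
exposure  estimate    se  p_value       Q  Q_p_value  conditional_F  n_snps
      X1     0.927 0.056    0.000 309.151      0.001        122.369     240
      X2     0.175 0.060    0.003 309.151      0.001        110.034     240
      X3    -0.466 0.054    0.000 309.151      0.001        131.793     240
16 outliers, e.g. ['rs224', 'rs219', 'rs235', 'rs230', 'rs26']
exposure  estimate    se  p_value       Q  Q_p_value  conditional_F  n_snps
      X1     0.931 0.049      0.0 196.342      0.873        131.133     223
      X2     0.200 0.054      0.0 196.342      0.873        112.764     223
      X3    -0.469 0.050      0.0 196.342      0.873        126.098     223
```

Reading it: the unpruned estimates are pulled off the truth by the
direct-effect SNPs (rs211–rs240); the heterogeneity statistic Q = 309 on
237 degrees of freedom (p = 0.001) says the per-SNP estimates disagree more
than chance allows. Most flagged SNPs (rs224, rs219, …) are from the
direct-effect group. After pruning, Q drops to its null range (p = 0.87),
the estimates move toward (1, 0.2, −0.5) — how far they land from it in any
single realization is set by the sampling noise visible in the SEs — and
conditional F ≈ 110–130 confirms the retained instruments are strong.
Averaged over 100 such realizations the pruned estimates are
(1.00, 0.21, −0.50).

The same pipeline runs from the shell on any harmonised TSV
(columns `snp, beta.<exposure>, se.<exposure>, ..., beta.outcome, se.outcome`):

```sh
radialmvmr simulate --seed 1 --out sim/
radialmvmr fit   --input sim/dataset.tsv --out fit/
radialmvmr prune --input sim/dataset.tsv --out pruned/
radialmvmr plot  --input sim/dataset.tsv --out plots/   # paired radial plots
radialmvmr study --reps 100 --pleiotropy-mode unbalanced --seed 2 --out study/
```

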