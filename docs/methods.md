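# Methods

## The model

Two-sample summary Mendelian randomization treats per-SNP GWAS association
estimates as data. For SNP j, exposure-association estimates γ̂_kj (standard
error σ̂_xkj) for each of K exposures and an outcome-association estimate Γ̂_j
(standard error σ̂_Yj) yield the Wald ratio β̂_kj = Γ̂_j/γ̂_kj. With first-order
weights w_kj = γ̂²_kj/σ̂²_Yj (which ignore uncertainty in γ̂ — the NO
Measurement Error, NOME, assumption), the radial (Galbraith) transformation
turns inverse-variance weighting into a no-intercept regression:

    Γ̂_j/σ̂_Yj = Σ_k β_IVWk · (γ̂_kj/σ̂_Yj) + ε_j .

The fitted coefficients are the direct effects of the K exposures, identical
to a weighted (1/σ̂²_Yj) regression of Γ̂_j on the γ̂_kj — the standard
multivariable IVW estimator. We carry the *signed* square-root weight
γ̂_kj/σ̂_Yj inside the regression; plots display |γ̂_kj|/σ̂_Yj on the x-axis
with the point reflected through the origin when γ̂_kj < 0, so y/x always
equals the Wald ratio. The fit requires J ≥ K+1 SNPs and a full-column-rank
association matrix; rank deficiency is reported with the collinear
exposures named.

### Adjusted ratio estimates and heterogeneity decomposition

For a reference exposure k, subtracting the fitted contribution of the other
exposures, Σ_{m≠k} β̂_IVWm γ̂_mj/σ̂_Yj, from the ordinate gives the *adjusted*
radial point. Its vertical distance to the line through the origin with slope
β̂_IVWk is the SNP's square-root contribution to the exposure-specific
heterogeneity statistic:

    Q_k = Σ_j Q_kj ,  Q_kj = (adjusted residual)²_j .

Under the signed-root convention the adjusted residual is algebraically the
common regression residual e_j for every reference exposure, so all Q_k
coincide with the radial residual sum of squares and the per-SNP outlier
test reduces to a test on e²_j. We keep the per-exposure API because the
adjusted ordinates and plots *are* exposure-specific; only the residual
distances coincide. (The alternative, unsigned-root reading of the
adjustment makes residuals explode for valid SNPs whose association signs
differ across exposures, and breaks the point-to-line identity, so it was
rejected.) Q_k is referred to χ² with J−K degrees of freedom (the residual
degrees of freedom of the regression); each Q_kj to χ²₁.

### Standard errors

The SE of β̂_IVWk is the model-based weighted-least-squares SE with the
residual standard deviation floored at 1: a fixed-effect SE when the data
are under-dispersed and a multiplicative random-effects SE when
over-dispersed. P-values are two-sided normal.

### Outlier detection and pruning

A SNP is flagged when its Q_kj p-value falls below a threshold (default
α = 0.05, no multiple-testing correction; a Bonferroni option exists but is
off by default) for *any* exposure. Iterative pruning removes flagged SNPs
and refits — recomputing the adjustment terms with the refreshed estimates,
since the adjustment is only as good as the current direct-effect estimates
— until no SNP is flagged, a maximum iteration count is reached, or removal
would leave fewer than K+1 SNPs (the floor is enforced with a warning, not
an error). Note the operating characteristics: under a correctly specified
homoskedastic model the per-SNP test has a ~5% false-positive rate, so on
clean data pruning still removes roughly 5% of SNPs; this removal is
independent of the SNP associations and does not bias the refit.

### Conditional instrument strength

For each exposure k we regress γ̂_kj/σ̂_xkj on the other exposures'
γ̂_mj/σ̂_xkj without intercept and form Q_xk, the weighted residual sum of
squares; the conditional F-statistic is F_k = Q_xk/(J−K+1). For K=1 this is
the mean univariable F-statistic (1/J)Σγ̂²_j/σ̂²_xj. The denominator
convention follows the companion multivariable-MR instrument-strength
methodology; the literature does not fix it uniquely, which is why the
package's F values should be read to ~10%.

## The simulation engine

`SimConfig`/`generate_individual_data` implement an individual-level
generating process: genotypes G_j ~ Binomial(2, MAF) under Hardy–Weinberg
with MAF ~ U(0.1, 0.4); exposures X_k = Σ_j γ_kj G_j + q_k U + ε_Xk with a
shared standard-normal confounder U; outcome Y = Σ_k β_k X_k + Σ_j α_j G_j +
q_Y U + ε_Y. Summary statistics come from single-SNP regressions computed in
K+1 mutually independent samples (one per exposure GWAS, one for the
outcome), so exposure and outcome errors are uncorrelated — the two-sample
setting. All randomness derives from one integer seed via spawned
generator streams; outputs are bit-for-bit reproducible.

Stock designs (K = 3, β = (1, 0.2, −0.5)):

* **Single-dataset study** — 8 groups of 30 SNPs: groups 1–7 instrument
  every nonempty exposure subset with effects N(0, 10) resampled until
  |γ| ≥ 2; group 8 is three subgroups of 10, each associated with one
  exposure and carrying a direct outcome effect α ~ N(10, 5) resampled
  until |α| ≥ 2 (overwhelmingly positive, i.e. directional). α is *not*
  sign-aligned with γ here, so the induced estimate bias is real in every
  realization but has random sign and averages out across seeds.
* **Sensitivity study** — groups 1–7 only (210 SNPs); a configurable
  fraction of SNPs receives a direct effect of the same magnitude
  distribution whose sign is random ("balanced") or aligned with the SNP's
  effect on a uniformly chosen associated exposure ("unbalanced" /
  directional — this alignment is what makes the bias systematic and
  exposure-symmetric, growing with the pleiotropic fraction).

Exposures are correlated through multivariate-normal residuals with
pairwise correlations (0.5, −0.5, 0.25), spanning a ±0.5 range in the
realized exposures; cross-exposure structural effects (X_m → X_k) are
supported in principle but default to zero.

### Calibration of the unstated scales

The residual scales are free parameters of the design; we fixed them once
from the instrument-strength and outlier-detectability operating points the
verification studies are meant to exhibit, and they are not tuned
thereafter:

* **Exposure residual SD = 142** (plus confounder effect 30): gives each
  exposure a total variance ≈ 26,000 of which the ~130 instruments explain
  ≈ 20% — and hence conditional F ≈ 115 at N = 200,000 (F scales with
  genetic variance × N / Var(X)).
* **Outcome residual SD = 1300** (plus confounder effect 30): puts the
  per-SNP outcome SE near σ̂_Yj ≈ 5 at N = 200,000, so the per-SNP χ²₁ test
  at α = 0.05 detects direct effects above ≈ 10 — the median of the
  N(10, 5) direct-effect distribution — and roughly three-quarters of the
  direct-effect group is flaggable in a typical realization.

### What the generator does and does not emulate

It emulates group-structured instruments, confounding, correlated
exposures, directional and balanced pleiotropy, weak-to-strong instruments,
and honest two-sample summary noise. It does not include linkage
disequilibrium between SNPs, case-control (binary) outcomes, sample
overlap, or allele-harmonisation artefacts; passing tests say nothing about
those features of real data.

Two consequences of the honest two-sample noise are worth stating because
they differ from what an idealised reading of the verification studies
might suggest:

* The radial residual variance is bounded below by 1 (in units of σ̂²_Yj):
  Var(e_j) = 1 + Σ_k β²_k Var(X_k)/Var(Y) for valid SNPs. Heterogeneity
  statistics on clean data therefore sit near their χ² degrees of freedom
  (e.g. Q ≈ 210–260 for 210 valid SNPs), and ~5% of valid SNPs are flagged
  as outliers at α = 0.05 in any realization. Reported Q values far below
  the degrees of freedom would require overlapping samples or deflated
  summary noise and cannot occur under this design.
* First-order weights ignore the uncertainty in γ̂ (NOME), which produces a
  small attenuation of each estimate of order β/F̄: about 1% at conditional
  F ≈ 70, undetectable at F ≳ 120. Mean-recovery checks must allow for
  this; exact unbiasedness holds only in the strong-instrument limit.

## Problem sizes used in the shipped analyses

The acceptance recomputation (`scripts/acceptance.py`) uses 100 replicates
of the single-dataset study at N = 200,000 (instrument strength and
outlier detectability depend on N, so this study runs at full size) and
100 replicates per cell of the sensitivity study at N = 25,000 (the
reported quantities there are bias-type means, which are insensitive to N;
at this N the detection threshold is high and pruning is nearly inert,
which the high-prevalence results make visible). The test suite uses the
same designs at reduced replicate counts with correspondingly widened,
pre-stated tolerances.

## Numerical choices

* Radial fits solve the normal equations of the (signed) weighted design;
  collinearity is detected via matrix rank with the involved exposures
  identified from the smallest singular vector.
* SNPs with γ̂_kj = 0 for every exposure are dropped before fitting (logged);
  a SNP with γ̂_kj = 0 for some exposures only contributes zero weight for
  those exposures and is retained.
* Zero-association SNPs are likewise excluded from univariable ratio fits
  (undefined Wald ratio), with a warning.
* Ties in outlier ordering are broken stably by SNP order; flagged lists
  are sorted by minimum p-value across exposures.
* Genotype matrices are held in float32 for memory economy; all summary
  statistics and fits are float64. TSV output preserves full double
  precision (round-trip parsing on read).

## Known limitations

* Exposure-specific Q statistics coincide numerically under the signed-root
  convention (see above); implementations using unsigned roots report
  slightly different per-exposure Q values whose derivation does not
  satisfy the point-to-line residual identity.
* First-order weights only; modified second-order weights are a natural
  extension hook but are not implemented.
* The conditional-F degrees-of-freedom convention (J−K+1) is one of several
  in circulation.
* No support for correlated (LD) instruments, binary-outcome bias
  corrections, or overlapping estimation samples.
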