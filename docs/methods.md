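# Methods

## The problem

A GWAS meta-analysis that includes a restricted cohort often cannot be
released in full; the released file is re-meta-analysed without that
cohort ("down-sampled"). The audit implemented here quantifies what the
removal cost: how much association signal was lost, whether the
multivariate genetic architecture (a latent factor over several indicator
phenotypes) is preserved, and how much downstream utility (SNP discovery
power, biological annotation patterns, polygenic prediction) degrades.

## LD Score regression core

For SNP j with LD score l_j, sample size N and M SNPs, the expected
association chi-square under a polygenic model is

    E[chi2_j] = 1 + N*a + N * h2 * l_j / M,

so a weighted regression of chi2 on N*l/M with a free intercept separates
polygenic signal (slope = h2, observed scale) from uniform inflation
(intercept = 1 + N*a; confounding or residual stratification). The
bivariate analogue regresses z1_j*z2_j on sqrt(N1*N2)*l_j/M; the slope is
the genetic covariance, the free intercept absorbs sample-overlap
effects, and rg = gcov / sqrt(h2_1 * h2_2).

Estimator details:

- **Two-step weights.** An unweighted pass seeds predicted means; the
  weighted pass uses w_j = 1/max(l_j, 1) * 1/(2*pred_j^2) (heteroskedastic
  variance of a chi-square plus LD over-counting), with predictions
  floored at 0.1. The cross-trait weight denominator is
  pred1_j*pred2_j + predc_j^2. Both univariate and bivariate weights are
  built from the *unweighted-pass* predictions, which makes rg(x, x) = 1
  exact to machine precision rather than only approximately.
- **Outlier truncation.** SNPs with chi2 > max(80, 0.001*N) are dropped
  before regression (standard practice; configurable).
- **Block jackknife.** SEs come from a delete-one-block jackknife over
  200 contiguous SNP blocks (file order; genomic positions are carried
  but unused). Weights are held fixed across replicates — they are part
  of the estimator, not the data. The rg jackknife re-forms the ratio
  from delete-one-block estimates of all three regressions over the same
  blocks.
- **lambda_GC** uses the 1-df chi-square median fixed at 0.4549364 (7
  digits) for bit-stable results across scipy versions.
- rg is reported unclipped; |rg| > 1 raises a flag rather than an error.
  The attenuation ratio is NaN with a warning when mean chi2 <= 1.
- Unbiasedness of the h2 estimator under its own model is verified by
  simulation (50 traits at M = 20,000, N = 50,000, h2 = 0.2; mean bias
  within 3*SD/sqrt(50)).

## Single-factor genomic SEM

`genetic_covariance` fills S (heritabilities on the diagonal, genetic
covariances off it) over one shared SNP set, and obtains the sampling
covariance V of vech(S) from the joint block jackknife.

`fit_single_factor` fits sigma(theta) = lambda*lambda' + diag(psi) to the
standardized S by diagonally weighted least squares (W = diag(V_std)^-1),
factor variance fixed at 1, residuals bounded at zero (a bound hit is a
Heywood case: flagged, not fatal). Choices worth recording:

- **Fixed-diagonal standardization.** S is standardized with the
  full-sample diagonal, and V is transformed with the same fixed scaling.
  Re-standardizing within each jackknife replicate would pin every
  replicate's diagonal at exactly 1, leaving the diagonal moments with
  zero sampling variance and an undefined DWLS weight; with a fixed
  scaling the diagonal moments keep their variance and the model retains
  its full df = T(T+1)/2 - 2T.
- **DWLS over full-V WLS** mirrors the common default in genomic SEM and
  avoids inverting a noisy T(T+1)/2-dimensional jackknife matrix. The
  full V still enters the parameter SEs through the WLS sandwich
  (A^-1 * J'W V W J * A^-1, A = J'WJ).
- **Model chi-square.** The DWLS discrepancy itself is not asymptotically
  chi-square, so the reported statistic is the residual-based form
  T = r' [(I-P) V (I-P)']^+ r with P the WLS projection onto the model
  tangent space — asymptotically chi-square on df, and exactly 0 for
  exact-fit input. CFI uses the independence baseline (free diagonal,
  zero off-diagonals) with a 1e-12 floor on its excess; SRMR is the RMS
  of standardized residual moments; AIC = chi2 + 2*(2T). "Good fit" is
  CFI > 0.9 and SRMR < 0.08.
- **Optimization.** L-BFGS-B with the analytic gradient, loadings
  initialized from the leading eigenvector of standardized S, ftol 1e-15.
  The loading vector is sign-canonicalized (largest-magnitude loading
  positive).
- **Factor GWAS.** The SNP-trait genetic covariance vector (on the
  standardized genetic scale, z_jt/sqrt(N_t*h2_t), SE 1/sqrt(N_t*h2_t))
  is regressed on the fitted loadings by GLS with
  Omega = diag(se^2 + psi_t/M) — sampling variance plus the per-SNP share
  of the trait-specific residual genetic variance (negligible in
  practice, and omitted when M is unknown). The effective N attached to
  the factor GWAS is 1/se^2 per SNP. Null-SNP z-statistics are verified
  to be standard normal by simulation.

## Concordance checks

- Sign concordance uses the exact binomial test, one-sided against
  concordance < p0 = 0.99 — discordance is the only failure mode of
  interest, and a 100 % null would be rejected by a single discordant
  SNP. Zero effects count as discordant (conservative; exact zeros are
  measure-zero in practice). `design_power` computes the exact power of
  this test: 150 independent SNPs give >= 80 % power (in fact 0.874)
  against a true concordance of 95 %.
- Outlier flags use the normal 95 % interval beta +/- 1.96*se of the
  full-data estimate (large-sample framing); flagged rows can be written
  into the released file as an OUTLIER column.
- The coefficient regression runs on absolute values by default (slope
  < 1 indicates attenuation of down-sampled coefficients); a signed
  option is exposed since either convention is defensible.
- Greedy clumping takes the remaining SNP with smallest p and removes
  everything with r2 >= 0.1 to it; ties in p break by snp_id so results
  are order-independent. Verified against an exhaustive-enumeration
  oracle on instances of up to 12 SNPs.

## Detection power

Power = 1 - F(c; df=1, lambda = N*r2) via the non-central chi-square CDF,
with the exact df=1 identity Phi(sqrt(lambda)-sqrt(c)) +
Phi(-sqrt(lambda)-sqrt(c)) as an independent cross-check (agreement to
1e-9 enforced in tests). r2 = Z^2/N, no winner's-curse correction (none
is applied in the audit protocol this implements). Default alpha 5e-8.

## Polygenic-score evaluation

Incremental R2 = R2(covariates + standardized score) - R2(covariates);
ordinary R2 for continuous outcomes, Nagelkerke pseudo-R2 (McFadden by
flag) relative to the intercept-only model for binary outcomes; listwise
deletion with counts logged. CIs are percentile bootstrap over
individuals, default 1000 resamples, seed mandatory.

One calibration subtlety: the raw in-sample incremental R2 is
non-negative in every bootstrap resample, so its percentile CI can never
cover 0 — for any implementation — and is therefore uninformative about a
null score. The `adjusted=True` variant (difference of adjusted R2) is
centered near zero under the null and its bootstrap CI covers 0 at close
to the nominal rate; the calibration tests use it, while the default
remains the raw measure used in PGS reporting. Comparisons between two
score panels use z = (|coef_down| - |coef_full|)/sqrt(se_d^2 + se_f^2),
so negative values mean attenuation.

The pattern-comparison "t-tests" (Steps 4-5) are large-sample z-tests on
differences with independent SEs: jackknife SEs have large effective df,
and ignoring the positive dependence between full and down-sampled
estimates (shared samples) overstates the SE of the difference, which is
conservative for flagging changes.

## Synthetic data: what it emulates and what it does not

Generators are deterministic per seed (`numpy.random.default_rng`).

- **LD scores**: l2 = 0.25 + Gamma(1.5, 0.5) — right-skewed, mean 1, so
  the panel M equals the SNP count and the generator's h2 parameter is
  the LDSC estimand exactly.
- **Summary-statistic pairs**: per-SNP standardized effects
  b_j ~ N(0, h2*l_j/M) (genetic variance proportional to l_j, making the
  regression exactly well-specified); per cohort k an estimate
  b_j + delta_jk + e_jk with e_jk ~ N(0, 1/EffN_k); inverse-variance
  meta-analysis over all (full) or retained (down) cohorts; a shared
  confound term sets the intercept. Cohort heterogeneity delta_jk ~
  N(0, tau^2*l_j/M) is deliberately LD-proportional: a constant-variance
  cohort effect would load on the LDSC intercept and leave the estimated
  cross-version rg at 1; the LD-proportional form is genuine cohort-
  specific genetic signal and drives rg(full, down) below 1, which is the
  regime the audit exists for. `pair_truth` gives the implied
  heritabilities and cross-version rg in closed form; `tau_for_rg`
  inverts it.
- **Defaults** (the audited regime at desk scale): M = 20,000 SNPs, two
  balanced case-control cohorts of 290,000 (retained) and 260,000
  (restricted, dropped), shared h2 = 0.08, tau = 0.122 — yielding a 47 %
  EffN cut, full-file mean chi2 near 3.2, and true cross-version
  rg ≈ 0.966.
- **Factor panels**: trait effects sqrt(h2_t)*(lambda_t*f_j +
  sqrt(1-lambda_t^2)*u_jt) with f, u_t ~ N(0, l_j/M): heritability h2_t,
  pairwise rg = lambda_t*lambda_u.
- **PGS cohorts**: Binomial(2, maf) dosages (maf ~ U(0.05, 0.5)), fixed
  weights, covariates (age, sex, 10 synthetic PCs) explaining 10 % of the
  continuous outcome, score contribution set to the target incremental
  R2, binary outcome by liability threshold at 30 % prevalence.

Not emulated: LD between SNPs in the summary-statistic generators (the
LD scores alone carry tagging; clumping is exercised on a separate
block-LD generator), realistic joint MAF/LD structure, imputation noise,
ancestry stratification, and winner's curse. Passing tests therefore
demonstrate estimator and test correctness under the stated polygenic
model, not robustness to real-data pathologies such as mis-specified LD
panels or population structure.

## Numerical conventions and degenerate inputs

- P-values read as 0 are floored at 1e-300 (keeps -log10 finite,
  preserves ranks); alleles are uppercased and must be A/C/G/T;
  strand-ambiguous SNPs (A/T, C/G) are dropped by default during
  harmonization since strand cannot be resolved without allele
  frequencies; irreconcilable allele pairs are dropped and logged, never
  silently kept; z is recomputed from beta/se when inconsistent beyond
  1e-6 relative tolerance (logged).
- Pseudoinverses in the residual-based chi-square use rcond = 1e-10;
  DWLS weights floor diag(V) at 1e-12.
- Problem sizes in the test suite (20,000-SNP panels, 50,000-300,000
  sample sizes, 50-seed replications, 400-1000 bootstrap resamples) were
  chosen so every estimator's sampling error is small against the effects
  being tested while the whole suite remains a desk-scale computation.

## Known limitations

- No liability-scale conversion and no partitioned/stratified LD Score
  regression; heritabilities are observed-scale throughout.
- The single-factor model is the only structure fitted — the audit's
  question is stability of a given solution, not model search.
- Step 4 compares externally produced gene-property estimate tables; the
  gene-property analysis itself (MAGMA/FUMA) is out of scope, as are
  PGS weight estimation (PRS-CS) and reference-panel LD computation.
- Dependence between full and down-sampled estimates is ignored in
  difference tests (conservative, see above).
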