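# gwasaudit

A toolkit for auditing whether **down-sampled GWAS summary statistics** —
files re-released after removing a restricted cohort (e.g. a proprietary
biobank) from a meta-analysis — are still comparable to their full-data
originals. Consortia that must strip restricted data before public release
can run this audit and ship the report with the down-sampled files; users
of such files can judge how much genetic signal was lost and whether
downstream analyses (factor models, gene-property scans, genetic
correlations, polygenic scores) remain representative.

The audit has six steps:

1. **Univariate signal loss.** Five key indicators per file — effective
   sample size *EffN* = Σₖ 4·Vₖ(1−Vₖ)·Nₖ over cohorts (cases proportion
   Vₖ), observed-scale SNP heritability h², mean χ², genomic inflation
   λ_GC = median(χ²)/0.4549364, and the attenuation/stratification-bias
   ratio (intercept − 1)/(mean χ² − 1) — all from an in-package LD Score
   regression, E[χ²ⱼ] = 1 + N·a + N·h²·lⱼ/M, with delete-one-block
   jackknife SEs. Plus three coefficient-concordance checks on
   near-independent SNPs: an exact one-sided binomial sign test against a
   99 % concordance null, 95 %-CI outlier flags (written back into the
   released file as an OUTLIER column), and OLS of |β_down| on |β_full|
   testing intercept 0 / slope 1.
2. **Factor stability.** A genetic covariance matrix S (with joint
   jackknife sampling covariance V) across the indicator traits; a
   confirmatory single-factor model fitted to the standardized S by
   diagonally weighted least squares with unit-variance identification;
   CFI/SRMR "good fit" thresholds (CFI > 0.9, SRMR < 0.08); per-parameter
   z-tests between the full and down-sampled solutions.
3. **Factor-level power.** Per-SNP effects on the latent factor by GLS on
   the loading vector; signal-loss indicators for the factor GWAS; and
   detection power 1 − F(c; df=1, λ=N·r²) at the genome-wide critical
   value c ≈ 29.7, evaluated at the median squared standardized
   coefficient r² = Z²/N of genome-wide significant SNPs and at reference
   effect sizes (r² = 0.003–0.005 %).
4. **Gene-property patterns** and 5. **genetic-correlation patterns**:
   Spearman rank correlations, per-item difference z-tests, and CI-overlap
   tables over externally produced estimate vectors.
6. **Polygenic scores.** Incremental R²/pseudo-R² of a PGS over an
   age + sex + 10-PC baseline with percentile-bootstrap CIs (1000
   resamples), and standardized differences of |coefficients| between the
   down-sampled and original score.

Every input the audit needs can be simulated with known ground truth
(`gwasaudit.simulate`), including full/down file pairs whose cross-version
genetic correlation is controlled by a cohort-heterogeneity parameter.

## Worked example

Simulate a full/down-sampled pair under the default study conditions (two
balanced case-control cohorts, 550k/290k effective N, heterogeneity tuned
to a true cross-version r_g ≈ 0.966) and compute the Step-1 indicators:

```python
import gwasaudit as ga

panel = ga.simulate_ld_scores(20_000, seed=1)
cfg = ga.SimConfig(seed=0)
full, down, truth = ga.simulate_sumstats_pair(cfg, panel)

retained = [c for c in cfg.cohorts if c.label not in cfg.drop_cohorts]
ki_full, ki_down, deltas = ga.key_indicators_pair(full, down, cfg.cohorts, retained, panel)
rg = ga.bivariate_ldsc(full, down, panel)
```

This prints (formatted):

```
EffN        full=   550000  down=   290000  Δ=-47.3%
h2          full=0.092 (0.003)  down=0.099 (0.004)
mean chi2   full=3.407  down=2.385  Δ=-30.0%
lambda_GC   full=3.005  down=2.225  Δ=-26.0%
rg(full, down) = 0.964 (SE 0.005)   [true 0.964]
```

Reading: removing the restricted cohort cut the effective sample size by
47 % and the mean χ² by 30 % — a real loss of signal — while the
heritability estimates are stable and the estimated genetic correlation
between the versions (0.964, significantly below 1) correctly flags that
the two files do not tag identical genetic effects, so the full six-step
audit is warranted.

The same audit runs from the shell:

```
audit run --config audit.yaml --out report/          # six-step report (JSON + markdown)
audit power --n-full 1492093 --n-down 1045957 --r2 3.8e-5
audit concordance --full full.tsv --down down.tsv --ld ld.tsv
audit simulate pair --out sim/                       # synthetic inputs + truth.json
```

`audit power` above reports a 17.8-percentage-point loss of detection
power at r² = 3.8×10⁻⁵ — the power cost of analysing the down-sampled
factor GWAS instead of the full one.

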