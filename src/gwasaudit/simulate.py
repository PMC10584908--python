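r"""Synthetic inputs with known ground truth for every step of the audit.

The summary-statistic generators draw per-SNP standardized effects with
variance proportional to the SNP's LD score, b_j ~ N(0, h2 * l_j / M), so
the LD Score regression E[chi2_j] = 1 + N*a + N*h2*l_j/M is exactly
well-specified and recovery tests are clean. Cohort heterogeneity enters
as cohort-specific genetic effects delta_jk ~ N(0, tau^2 * l_j / M): an
LD-proportional component, so it loads on the regression slope (genetic
signal) rather than the intercept, and drives the genetic correlation
between the full and down-sampled twins below 1 — the regime in which
down-sampled files must be audited. LD between SNPs is not simulated in
the summary-statistic generators (the LD scores alone carry the tagging
structure); clumping is exercised on the separate block-LD generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import LDScorePanel
from .sumstats import CohortSpec, SumStats, effective_sample_size

__all__ = [
    "SimConfig",
    "simulate_ld_scores",
    "simulate_sumstats_pair",
    "simulate_factor_traits",
    "simulate_ld_blocks",
    "simulate_pgs_cohort",
    "sumstats_from_pvalues",
    "pair_truth",
    "tau_for_rg",
]


# Default cohort structure: two balanced case-control cohorts whose
# retained/restricted split reproduces the ~47% effective-sample-size cut
# of the motivating use case at desk scale; with h2 = 0.08 and M = 20,000
# the full file's expected mean chi-square is ~3.2.
def _default_cohorts() -> list[CohortSpec]:
    return [CohortSpec("retained", 0.5, 290_000),
            CohortSpec("restricted", 0.5, 260_000)]


@dataclass
class SimConfig:
    """Study conditions for the summary-statistic generators.

    ``heterogeneity`` (tau) is the SD multiplier of cohort-specific
    genetic effects on the same per-SNP scale as the shared effects; the
    default 0.122 puts the true full/down genetic correlation at ~0.966
    under the default cohorts (see :func:`pair_truth`).
    """

    m_snps: int = 20_000
    n_traits: int = 1
    h2: float | list = 0.08
    intercept: float | list = 1.0
    cohorts: list = field(default_factory=_default_cohorts)
    drop_cohorts: tuple = ("restricted",)
    heterogeneity: float = 0.122
    loadings: list | None = None
    trait_n: float | list = 50_000
    rg_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity tau must be >= 0")
        h2s = np.atleast_1d(np.asarray(self.h2, float))
        if ((h2s < 0) | (h2s > 1)).any():
            raise ValueError("h2 must lie in [0, 1]")
        if self.loadings is not None and (np.abs(np.asarray(self.loadings)) > 1).any():
            raise ValueError("|loadings| must be <= 1")
        if self.rg_matrix is not None:
            R = np.asarray(self.rg_matrix, float)
            if (not np.allclose(R, R.T)) or (not np.allclose(np.diag(R), 1.0)):
                raise ValueError("rg_matrix must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("rg_matrix must be positive semidefinite")


def simulate_ld_scores(m_snps: int, seed: int) -> LDScorePanel:
    """A right-skewed LD-score panel: l2 = 0.25 + Gamma(shape 1.5, scale
    0.5), mean 1 so the panel's M equals the SNP count and total simulated
    heritability matches the h2 parameter. Deterministic per seed."""
    if m_snps < 1000:
        raise ValueError("m_snps must be >= 1000")
    rng = np.random.default_rng(seed)
    l2 = 0.25 + rng.gamma(shape=1.5, scale=0.5, size=m_snps)
    table = pd.DataFrame({"snp_id": [f"rs{i+1}" for i in range(m_snps)], "l2": l2})
    return LDScorePanel(table, m_total=m_snps)


def _meta_weights(cohorts: list[CohortSpec]) -> np.ndarray:
    effn = np.array([effective_sample_size([c]) for c in cohorts])
    return effn / effn.sum()


def pair_truth(cfg: SimConfig) -> dict:
    """Analytic ground truth for :func:`simulate_sumstats_pair`.

    The meta-analyzed genetic effect of each file is the shared effect
    plus the EffN-weighted average of cohort-specific effects, so the
    slope-scale heritabilities and the full/down genetic correlation
    follow in closed form from tau and the cohort weights.
    """
    h2 = float(np.atleast_1d(np.asarray(cfg.h2, float))[0])
    tau2 = cfg.heterogeneity ** 2
    w_full = _meta_weights(cfg.cohorts)
    retained = [c for c in cfg.cohorts if c.label not in cfg.drop_cohorts]
    if not retained:
        raise ValueError("all cohorts dropped")
    w_down_full_order = np.array([w for c, w in zip(cfg.cohorts, _meta_weights(cfg.cohorts))
                                  if c.label not in cfg.drop_cohorts])
    w_down = _meta_weights(retained)
    h2_full = h2 + tau2 * float((w_full ** 2).sum())
    h2_down = h2 + tau2 * float((w_down ** 2).sum())
    ret_idx = [i for i, c in enumerate(cfg.cohorts) if c.label not in cfg.drop_cohorts]
    cov = h2 + tau2 * float((w_full[ret_idx] * w_down).sum())
    return {
        "h2_shared": h2,
        "tau": cfg.heterogeneity,
        "h2_full": h2_full,
        "h2_down": h2_down,
        "rg_full_down": cov / np.sqrt(h2_full * h2_down),
        "eff_n_full": effective_sample_size(cfg.cohorts),
        "eff_n_down": effective_sample_size(retained),
    }


def tau_for_rg(cfg: SimConfig, target_rg: float) -> float:
    """The tau at which the true full/down genetic correlation equals
    ``target_rg`` under cfg's cohort structure."""
    if not 0 < target_rg < 1:
        raise ValueError("target_rg must be in (0, 1)")

    def gap(tau):
        c = SimConfig(**{**cfg.__dict__, "heterogeneity": float(tau)})
        return pair_truth(c)["rg_full_down"] - target_rg

    return float(optimize.brentq(gap, 1e-6, 5.0))


def _assemble_sumstats(z, n_col, eff_n, m):
    se = 1.0 / np.sqrt(eff_n)
    beta = z * se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    return SumStats(pd.DataFrame({
        "snp_id": [f"rs{i+1}" for i in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1),
        "a1": "A", "a2": "G",
        "beta": beta, "se": se, "z": z, "p": p,
        "n": float(n_col), "eff_n": float(eff_n),
    }))


def simulate_sumstats_pair(cfg: SimConfig, panel: LDScorePanel):
    """A full/down-sampled pair of meta-analyzed GWAS files.

    Per SNP j: shared standardized effect b_j ~ N(0, h2*l_j/M); per cohort
    k an estimate b_j + delta_jk + e_jk with delta_jk ~ N(0, tau^2*l_j/M)
    and e_jk ~ N(0, 1/EffN_k); inverse-variance meta-analysis over all
    cohorts (full) and retained cohorts (down). A confounding effect
    shared by both files sets the LDSC intercept to cfg.intercept for the
    full file. Returns (full, down, truth).
    """
    m, M = len(panel), panel.m_total
    rng = np.random.default_rng(cfg.seed)
    l2 = panel.table["l2"].to_numpy(float)
    per_snp = l2 / M
    h2 = float(np.atleast_1d(np.asarray(cfg.h2, float))[0])
    intercept = float(np.atleast_1d(np.asarray(cfg.intercept, float))[0])
    tau = cfg.heterogeneity

    truth = pair_truth(cfg)
    effn_k = np.array([effective_sample_size([c]) for c in cfg.cohorts])
    retained = np.array([c.label not in cfg.drop_cohorts for c in cfg.cohorts])
    if not retained.any():
        raise ValueError("all cohorts dropped")

    b = rng.normal(0.0, np.sqrt(h2 * per_snp))
    delta = rng.normal(0.0, 1.0, size=(m, len(cfg.cohorts))) * np.sqrt(tau ** 2 * per_snp)[:, None]
    err = rng.normal(0.0, 1.0, size=(m, len(cfg.cohorts))) / np.sqrt(effn_k)[None, :]
    beta_hat = b[:, None] + delta + err

    a = (intercept - 1.0) / truth["eff_n_full"]
    confound = rng.normal(0.0, np.sqrt(max(a, 0.0)), size=m) if a > 0 else np.zeros(m)

    def _meta(mask):
        w = effn_k[mask] / effn_k[mask].sum()
        beta_meta = beta_hat[:, mask] @ w + confound
        effn = effn_k[mask].sum()
        n_tot = sum(c.n for c, keep in zip(cfg.cohorts, mask) if keep)
        z = beta_meta * np.sqrt(effn)
        return _assemble_sumstats(z, n_tot, effn, m)

    full = _meta(np.ones(len(cfg.cohorts), bool))
    down = _meta(retained)
    truth.update({"b": b, "intercept_full": intercept,
                  "intercept_down": 1.0 + a * truth["eff_n_down"],
                  "seed": cfg.seed})
    return full, down, truth


def simulate_factor_traits(cfg: SimConfig, panel: LDScorePanel):
    """T traits sharing a single genetic factor.

    Trait t's per-SNP effect is sqrt(h2_t)*(lambda_t*f_j +
    sqrt(1-lambda_t^2)*u_jt) with f and u_t independent N(0, l_j/M), so
    trait t has (slope-scale) heritability h2_t and every pairwise genetic
    correlation is lambda_t*lambda_u. Returns (list of SumStats, truth).
    """
    if cfg.loadings is None:
        raise ValueError("cfg.loadings required")
    lam = np.asarray(cfg.loadings, float)
    T = lam.size
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(cfg.h2, float)), (T,))
    n_t = np.broadcast_to(np.atleast_1d(np.asarray(cfg.trait_n, float)), (T,))
    m, M = len(panel), panel.m_total
    rng = np.random.default_rng(cfg.seed)
    sd = np.sqrt(panel.table["l2"].to_numpy(float) / M)

    f = rng.normal(0.0, sd)
    traits = []
    for t in range(T):
        u = rng.normal(0.0, sd)
        b_t = np.sqrt(h2[t]) * (lam[t] * f + np.sqrt(1.0 - lam[t] ** 2) * u)
        z = np.sqrt(n_t[t]) * b_t + rng.normal(0.0, 1.0, size=m)
        traits.append(_assemble_sumstats(z, n_t[t], n_t[t], m))
    truth = {"loadings": lam, "h2": np.asarray(h2), "n": np.asarray(n_t),
             "rg_matrix": np.outer(lam, lam) - np.diag(lam ** 2) + np.eye(T),
             "seed": cfg.seed}
    return traits, truth


def simulate_ld_blocks(n_blocks: int, block_size: int, r: float):
    """Block-diagonal LD r2 matrix (within-block r2 = ``r``, off-block 0)
    with deterministic p-values whose per-block minima are unique.
    Returns (ld DataFrame, p-value Series), both keyed by snp_id."""
    if not 0 <= r < 1:
        raise ValueError("within-block r2 must lie in [0, 1)")
    ids = [f"b{b+1}_s{s+1}" for b in range(n_blocks) for s in range(block_size)]
    m = n_blocks * block_size
    mat = np.zeros((m, m))
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        mat[sl, sl] = r
    np.fill_diagonal(mat, 1.0)
    ld = pd.DataFrame(mat, index=ids, columns=ids)
    # p-values increase within and across blocks: block minima are the
    # first SNP of each block and are strictly ordered
    pvals = pd.Series([1e-10 * (1 + b * block_size + s)
                       for b in range(n_blocks) for s in range(block_size)],
                      index=ids, name="p")
    return ld, pvals


def sumstats_from_pvalues(pvals: pd.Series, n: float = 100_000) -> SumStats:
    """Wrap a p-value series as a minimal summary-statistic table (z from
    the two-sided normal quantile, all effects positive)."""
    p = pvals.to_numpy(float)
    z = stats.norm.isf(p / 2.0)
    return SumStats(pd.DataFrame({
        "snp_id": pvals.index.astype(str), "chrom": "1",
        "pos": np.arange(1, len(p) + 1), "a1": "A", "a2": "G",
        "z": z, "beta": z / np.sqrt(n), "se": 1.0 / np.sqrt(n),
        "p": p, "n": float(n),
    }))


@dataclass
class PgsCohortTruth:
    target_incr_r2: float
    cov_r2: float
    prevalence: float
    realized_score_var: float


def simulate_pgs_cohort(n_ind: int, m_snps: int, target_incr_r2: float, seed: int):
    """An individual-level cohort for polygenic-score evaluation.

    Dosages are Binomial(2, maf_j) with maf ~ U(0.05, 0.5); weights are
    fixed N(0,1) draws; covariates are age, sex, and ten synthetic genetic
    PCs jointly explaining 10% of the continuous outcome's variance; the
    standardized true score contributes ``target_incr_r2``, so the
    population incremental R2 over the covariate baseline equals the
    target. A binary outcome is derived by thresholding the same liability
    at 30% prevalence. Deterministic per seed.
    """
    from .pgs import PgsCohort  # local import to avoid a cycle

    if not 0 <= target_incr_r2 < 1:
        raise ValueError("target_incr_r2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, size=m_snps)
    dosages = rng.binomial(2, maf, size=(n_ind, m_snps)).astype(float)
    weights = rng.normal(0.0, 1.0, size=m_snps)
    raw = dosages @ weights
    s = (raw - raw.mean()) / raw.std()

    age = rng.normal(45.0, 10.0, size=n_ind)
    sex = rng.integers(0, 2, size=n_ind).astype(float)
    pcs = rng.normal(0.0, 1.0, size=(n_ind, 10))
    cov_r2 = 0.10
    covs = np.column_stack([(age - age.mean()) / age.std(),
                            (sex - sex.mean()) / max(sex.std(), 1e-12), pcs])
    gamma = np.full(covs.shape[1], np.sqrt(cov_r2 / covs.shape[1]))
    noise_sd = np.sqrt(max(1.0 - cov_r2 - target_incr_r2, 1e-12))
    liability = covs @ gamma + np.sqrt(target_incr_r2) * s + rng.normal(0.0, noise_sd, size=n_ind)

    prevalence = 0.30
    binary = (liability >= np.quantile(liability, 1.0 - prevalence)).astype(float)
    ids = [f"id{i+1}" for i in range(n_ind)]
    phenotypes = pd.DataFrame({"continuous": liability, "binary": binary}, index=ids)
    covariates = pd.DataFrame(
        np.column_stack([age, sex, pcs]), index=ids,
        columns=["age", "sex"] + [f"pc{i+1}" for i in range(10)])
    snp_ids = [f"rs{i+1}" for i in range(m_snps)]
    cohort = PgsCohort(dosages=dosages, weights=weights, snp_ids=snp_ids,
                       phenotypes=phenotypes, covariates=covariates, ids=ids)
    truth = PgsCohortTruth(target_incr_r2=target_incr_r2, cov_r2=cov_r2,
                           prevalence=prevalence, realized_score_var=float(raw.var()))
    return cohort, truth
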