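"""Coefficient-concordance checks between full and down-sampled GWAS,
plus the greedy LD clumping that defines lead SNPs.

The three checks, applied to near-independent SNPs (lead SNPs after
clumping at LD r-squared < 0.1, or any user-chosen subset):

1. sign concordance, with an exact one-sided binomial test against a null
   concordance of 99% (100% is too strict — one discordant SNP rejects);
2. outlier inspection — down-sampled coefficients outside the 95% CI of
   their full-data counterparts, flagged for dissemination;
3. OLS of the down-sampled coefficients on the full-data coefficients
   (absolute values by default), testing intercept = 0 and slope = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import SumStats, SumStatsError

__all__ = [
    "LeadSnpSet",
    "ConcordanceReport",
    "ld_clump",
    "sign_concordance",
    "design_power",
    "outlier_flags",
    "coefficient_regression",
    "run_concordance",
]


@dataclass
class LeadSnpSet:
    """Ordered lead markers: pairwise LD r2 below ``r2_thresh``, every
    member genome-wide significant at ``p_thresh``."""

    snp_ids: list
    p_thresh: float
    r2_thresh: float

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class ConcordanceReport:
    n_snps: int
    prop_concordant: float
    binom_p: float
    p0: float
    n_outliers: int
    outlier_fraction: float
    reg_intercept: float
    reg_slope: float
    reg_adj_r2: float
    p_intercept_zero: float
    p_slope_one: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _validate_ld(ld: pd.DataFrame) -> pd.DataFrame:
    if ld.shape[0] != ld.shape[1]:
        raise ValueError("LD matrix must be square")
    if list(ld.index) != list(ld.columns):
        raise ValueError("LD matrix row/column labels disagree")
    vals = ld.to_numpy(float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    return ld


def ld_clump(ss: SumStats, ld: pd.DataFrame, p_thresh: float = 5e-8,
             r2_thresh: float = 0.1) -> LeadSnpSet:
    """Greedy p-value clumping: repeatedly take the remaining SNP with the
    smallest p-value and discard every SNP in LD (r2 >= ``r2_thresh``)
    with it. Ties in p are broken by snp_id lexicographic order so the
    result is independent of input row order.
    """
    _validate_ld(ld)
    t = ss.table
    cand = t.loc[t["p"].to_numpy(float) < p_thresh, ["snp_id", "p"]]
    if cand.empty:
        return LeadSnpSet([], p_thresh, r2_thresh)
    missing = set(cand["snp_id"]) - set(ld.index)
    if missing:
        raise ValueError(f"LD matrix missing candidate SNPs: {sorted(missing)[:5]}")
    cand = cand.sort_values(["p", "snp_id"], kind="mergesort")
    remaining = list(cand["snp_id"])
    leads: list[str] = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead)
        r2 = ld.loc[lead]
        remaining = [s for s in remaining if r2[s] < r2_thresh]
    return LeadSnpSet(leads, p_thresh, r2_thresh)


def _effect_signs(ss: SumStats, subset) -> np.ndarray:
    t = ss.table.set_index("snp_id").loc[list(subset)]
    beta = t["beta"].to_numpy(float)
    if np.isfinite(beta).all():
        return np.sign(beta)
    return np.sign(t["z"].to_numpy(float))


def sign_concordance(full: SumStats, down: SumStats, subset,
                     p0: float = 0.99) -> tuple[float, float]:
    """Proportion of subset SNPs with the same effect direction in both
    files, and the exact one-sided binomial p-value for the alternative
    that true concordance is below ``p0``. Zero effects count as
    discordant (conservative)."""
    subset = list(subset)
    if not subset:
        raise SumStatsError("empty SNP subset for sign concordance")
    sf = _effect_signs(full, subset)
    sd = _effect_signs(down, subset)
    success = (sf * sd) > 0
    k, n = int(success.sum()), len(subset)
    pval = stats.binomtest(k, n, p0, alternative="less").pvalue
    return k / n, float(pval)


def design_power(n: int, p0: float = 0.99, p_true: float = 0.95,
                 alpha: float = 0.05) -> float:
    """Exact power of the one-sided binomial concordance test.

    The rejection region is {X <= k*} with k* the largest count whose
    null CDF is at most alpha; power is the CDF of k* under the true
    concordance p_true. 150 independent SNPs give >= 80% power against a
    true concordance of 95% under the 99% null.
    """
    if not (0 < p_true < p0 < 1):
        raise ValueError("need 0 < p_true < p0 < 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(0, n + 1)
    cdf0 = stats.binom.cdf(k, n, p0)
    admissible = k[cdf0 <= alpha]
    if admissible.size == 0:
        warnings.warn("no rejection region exists at this n and alpha; power is 0")
        return 0.0
    k_star = int(admissible.max())
    return float(stats.binom.cdf(k_star, n, p_true))


def outlier_flags(full: SumStats, down: SumStats, level: float = 0.95):
    """Flag SNPs whose down-sampled beta lies outside the full-data
    ``level`` CI (beta +/- q*se, q the two-sided normal quantile).
    Tables must already be row-aligned. Returns (flags, count); flags can
    be attached to ``down.table['outlier']`` for dissemination."""
    bf = full.table["beta"].to_numpy(float)
    sef = full.table["se"].to_numpy(float)
    bd = down.table["beta"].to_numpy(float)
    if not (np.isfinite(bf).all() and np.isfinite(sef).all()):
        raise SumStatsError("full-data beta/se required for outlier evaluation")
    if len(full.table) != len(down.table):
        raise SumStatsError("tables must be row-aligned (see harmonize_pair)")
    q = stats.norm.ppf((1.0 + level) / 2.0)
    flags = ((bd < bf - q * sef) | (bd > bf + q * sef)).astype(int)
    return flags, int(flags.sum())


def coefficient_regression(full: SumStats, down: SumStats, subset,
                           absolute: bool = True):
    """OLS of down-sampled betas on full-data betas over ``subset``.

    Returns (intercept, slope, adj_r2, p_intercept_zero, p_slope_one)
    with Wald p-values for H0: intercept = 0 and H0: slope = 1. Absolute
    values by default; a slope below one indicates attenuation of the
    down-sampled coefficients.
    """
    subset = list(subset)
    if len(subset) < 3:
        raise SumStatsError("need at least 3 SNPs for the coefficient regression")
    xf = full.table.set_index("snp_id").loc[subset, "beta"].to_numpy(float)
    yd = down.table.set_index("snp_id").loc[subset, "beta"].to_numpy(float)
    if absolute:
        xf, yd = np.abs(xf), np.abs(yd)
    if np.ptp(xf) == 0:
        raise SumStatsError("zero variance in full-data betas: regression degenerate")
    res = sm.OLS(yd, sm.add_constant(xf)).fit()
    p_slope_one = float(res.t_test("x1 = 1").pvalue)
    return (float(res.params[0]), float(res.params[1]), float(res.rsquared_adj),
            float(res.pvalues[0]), p_slope_one)


def run_concordance(full: SumStats, down: SumStats, subset,
                    p0: float = 0.99, level: float = 0.95,
                    absolute: bool = True) -> ConcordanceReport:
    """All three checks on one aligned pair and SNP subset."""
    prop, binom_p = sign_concordance(full, down, subset, p0=p0)
    fsub, dsub = full.subset(subset), down.subset(subset)
    flags, n_out = outlier_flags(fsub, dsub, level=level)
    ic, sl, ar2, p_i, p_s = coefficient_regression(full, down, subset, absolute=absolute)
    return ConcordanceReport(
        n_snps=len(list(subset)), prop_concordant=prop, binom_p=binom_p, p0=p0,
        n_outliers=n_out, outlier_fraction=n_out / max(1, len(flags)),
        reg_intercept=ic, reg_slope=sl, reg_adj_r2=ar2,
        p_intercept_zero=p_i, p_slope_one=p_s,
    )
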