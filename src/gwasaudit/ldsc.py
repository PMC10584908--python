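r"""LD Score regression core: the Step-1 key indicators and genetic correlations.

Under a polygenic model, the expected association chi-square of SNP j is

    E[chi2_j] = 1 + N*a + N * h2 * l_j / M

where l_j is the SNP's LD score, M the number of SNPs, h2 the SNP
heritability, and N*a an inflation term shared by all SNPs (confounding,
sample overlap). Regressing chi2 on N*l/M with a free intercept therefore
separates polygenic signal (slope = h2) from confounding (intercept = 1 +
N*a). The bivariate analogue regresses z1*z2 on sqrt(N1*N2)*l/M, with
slope the genetic covariance. Standard errors come from a delete-one-block
jackknife over contiguous SNP blocks.

The five key indicators reported per file are: effective sample size,
observed-scale h2, mean chi-square, the genomic inflation factor
lambda_GC = median(chi2) / 0.4549364, and the attenuation/stratification
bias ratio (intercept - 1) / (mean chi2 - 1) — the fraction of test-statistic
inflation not attributable to polygenic signal.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import CohortSpec, SumStats, SumStatsError, effective_sample_size, harmonize_pair

__all__ = [
    "LDScorePanel",
    "KeyIndicators",
    "GeneticCorrelationEstimate",
    "UnivariateLdscFit",
    "CHI2_MEDIAN_1DF",
    "read_ld_panel",
    "write_ld_panel",
    "chi2_stats",
    "attenuation_ratio",
    "univariate_ldsc",
    "bivariate_ldsc",
    "key_indicators",
    "key_indicators_pair",
]

# Median of the central chi-square distribution with 1 df, fixed to 7 digits
# so lambda_GC is bit-stable across scipy versions.
CHI2_MEDIAN_1DF = 0.4549364

DEFAULT_N_BLOCKS = 200


class LdscError(ValueError):
    pass


@dataclass
class LDScorePanel:
    """LD scores l_j >= 0 keyed by snp_id, plus the SNP count M used as the
    regression denominator (may exceed the number of scored SNPs)."""

    table: pd.DataFrame  # columns snp_id, l2
    m_total: int

    def __post_init__(self) -> None:
        t = self.table
        if not {"snp_id", "l2"} <= set(t.columns):
            raise LdscError("panel table needs snp_id and l2 columns")
        if (t["l2"].to_numpy(float) < 0).any():
            raise LdscError("negative LD scores")
        if self.m_total < len(t):
            raise LdscError("m_total smaller than number of scored SNPs")

    def __len__(self) -> int:
        return len(self.table)


def read_ld_panel(path, m_path=None) -> LDScorePanel:
    """Read a tab-delimited SNP/L2 panel; M comes from a one-integer sidecar
    file (default: ``<path>.M``), gzip-transparent."""
    opener = gzip.open(str(path), "rt") if str(path).endswith(".gz") else open(path)
    with opener as fh:
        t = pd.read_csv(fh, sep=r"\s+")
    t.columns = [c.upper() for c in t.columns]
    t = t.rename(columns={"SNP": "snp_id", "L2": "l2"})
    if m_path is None:
        m_path = str(path) + ".M"
    with open(m_path) as fh:
        m_total = int(float(fh.read().split()[0]))
    return LDScorePanel(t[["snp_id", "l2"]], m_total)


def write_ld_panel(panel: LDScorePanel, path) -> None:
    out = panel.table.rename(columns={"snp_id": "SNP", "l2": "L2"})
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")
    with open(str(path) + ".M", "w") as fh:
        fh.write(f"{panel.m_total}\n")


@dataclass
class KeyIndicators:
    """The five Step-1 signal metrics for one summary-statistic file."""

    eff_n: float
    h2: float
    h2_se: float
    mean_chi2: float
    lambda_gc: float
    intercept: float
    intercept_se: float
    ratio: float  # NaN when mean_chi2 <= 1

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("eff_n", "h2", "h2_se", "mean_chi2", "lambda_gc", "intercept", "intercept_se", "ratio")}


@dataclass
class GeneticCorrelationEstimate:
    rg: float
    se: float
    gcov: float
    gcov_int: float
    h2_1: float
    h2_2: float
    out_of_range: bool = False
    n_snps: int = 0


@dataclass
class UnivariateLdscFit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    n_snps: int
    n_blocks: int
    mean_chi2: float
    # delete-one-block estimates of (intercept, h2), for joint jackknives
    delete_values: np.ndarray = field(repr=False, default=None)


def chi2_stats(ss: SumStats) -> tuple[float, float]:
    """Mean chi-square and genomic inflation factor lambda_GC.

    lambda_GC is the median chi-square divided by the median of the central
    1-df chi-square distribution (0.4549364).
    """
    z = ss.table["z"].to_numpy(float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise SumStatsError("no finite z statistics")
    chi2 = z * z
    return float(chi2.mean()), float(np.median(chi2) / CHI2_MEDIAN_1DF)


def attenuation_ratio(intercept: float, mean_chi2: float) -> float:
    """(intercept - 1) / (mean chi2 - 1); NaN with a warning when the
    denominator is undefined (mean chi2 <= 1)."""
    if mean_chi2 <= 1.0:
        warnings.warn("attenuation ratio undefined for mean chi2 <= 1; returning NaN")
        return float("nan")
    return (intercept - 1.0) / (mean_chi2 - 1.0)


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Weighted regression of y on [1, x] with delete-one-block jackknife.

    Weights are held fixed across jackknife replicates (they are part of
    the estimator definition, not of the data). Returns the coefficient
    vector (intercept, slope), jackknife SEs, and the (n_blocks, 2) array
    of delete-one-block estimates.
    """
    m = x.size
    if n_blocks < 2:
        raise LdscError("n_blocks must be >= 2")
    n_blocks = min(n_blocks, m // 2)
    bounds = _block_bounds(m, n_blocks)
    # sufficient statistics per block: [sum w, sum wx, sum wx^2, sum wy, sum wxy]
    stats_full = np.zeros(5)
    stats_block = np.zeros((n_blocks, 5))
    comp = np.column_stack([w, w * x, w * x * x, w * y, w * x * y])
    for b in range(n_blocks):
        stats_block[b] = comp[bounds[b]:bounds[b + 1]].sum(axis=0)
    stats_full = stats_block.sum(axis=0)

    def _solve(s):
        sw, swx, swx2, swy, swxy = s
        xtx = np.array([[sw, swx], [swx, swx2]])
        xty = np.array([swy, swxy])
        det = sw * swx2 - swx * swx
        if det <= 0 or not np.isfinite(det):
            raise LdscError("degenerate design: zero LD-score variance")
        return np.linalg.solve(xtx, xty)

    coef = _solve(stats_full)
    deletes = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        deletes[b] = _solve(stats_full - stats_block[b])
    mean_del = deletes.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * ((deletes - mean_del) ** 2).sum(axis=0))
    return coef, se, deletes


def _merge_panel(ss: SumStats, panel: LDScorePanel) -> pd.DataFrame:
    merged = ss.table.merge(panel.table, on="snp_id", how="inner")
    if len(merged) < 200:
        raise LdscError(f"only {len(merged)} SNPs matched the LD-score panel (need >= 200)")
    return merged

def _truncate_chi2(chi2: np.ndarray, n_bar: float, chi2_max: float | None) -> np.ndarray:
    if chi2_max is None:
        chi2_max = max(80.0, 0.001 * n_bar)
    return chi2 <= chi2_max


def _ldsc_weights(l2: np.ndarray, pred: np.ndarray) -> np.ndarray:
    # heteroskedasticity + over-counting weights: Var(chi2_j) ~ 2 E[chi2_j]^2,
    # and 1/max(l,1) discounts SNPs whose signal is tagged many times
    pred = np.maximum(pred, 0.1)
    return 1.0 / (np.maximum(l2, 1.0) * 2.0 * pred * pred)


def _univariate_components(chi2: np.ndarray, n: np.ndarray, l2: np.ndarray,
                           m_total: int, n_blocks: int):
    """Two-step univariate regression: unweighted pass seeds the variance
    weights, weighted pass delivers the estimate. Returns (coef, se,
    delete-one-block estimates, unweighted-pass predictions) — the latter
    feed the cross-trait weights so that rg(x, x) is exactly 1."""
    x = n * l2 / m_total
    coef0, _, _ = _wls_jackknife(x, chi2, np.ones_like(x), 2)
    pred0 = np.maximum(coef0[0] + coef0[1] * x, 0.1)
    w = _ldsc_weights(l2, pred0)
    coef, se, deletes = _wls_jackknife(x, chi2, w, n_blocks)
    return coef, se, deletes, pred0


def univariate_ldsc(ss: SumStats, panel: LDScorePanel,
                    n_blocks: int = DEFAULT_N_BLOCKS,
                    chi2_max: float | None = None) -> UnivariateLdscFit:
    """Estimate observed-scale h2 and the LDSC intercept for one trait.

    Two-step estimator: an unweighted pass seeds h2 and the intercept for
    the LDSC variance weights, then the weighted regression of chi2 on
    N*l/M is solved with a free intercept. SNPs with chi2 above
    max(80, 0.001*N) are dropped first (standard outlier handling).
    """
    merged = _merge_panel(ss, panel)
    z = merged["z"].to_numpy(float)
    n = merged["n"].to_numpy(float)
    l2 = merged["l2"].to_numpy(float)
    chi2 = z * z
    n_bar = float(np.nanmean(n))
    keep = _truncate_chi2(chi2, n_bar, chi2_max)
    chi2, n, l2 = chi2[keep], n[keep], l2[keep]
    if chi2.size < 200:
        raise LdscError("fewer than 200 SNPs after chi2 truncation")

    coef, se, deletes, _ = _univariate_components(chi2, n, l2, panel.m_total, n_blocks)
    return UnivariateLdscFit(
        h2=float(coef[1]), h2_se=float(se[1]),
        intercept=float(coef[0]), intercept_se=float(se[0]),
        n_snps=int(chi2.size), n_blocks=min(n_blocks, chi2.size // 2),
        mean_chi2=float(chi2.mean()), delete_values=deletes,
    )


def _aligned_bivariate_arrays(ss1: SumStats, ss2: SumStats, panel: LDScorePanel,
                              chi2_max: float | None = None):
    """Harmonize the pair, intersect with the panel, truncate, and return
    the aligned arrays used by the three regressions of an rg estimate."""
    a1, a2, _ = harmonize_pair(ss1, ss2, ambiguous_policy="keep")
    merged = a1.table[["snp_id", "z", "n"]].rename(columns={"z": "z1", "n": "n1"})
    merged["z2"] = a2.table["z"].to_numpy(float)
    merged["n2"] = a2.table["n"].to_numpy(float)
    merged = merged.merge(panel.table, on="snp_id", how="inner")
    if len(merged) < 200:
        raise LdscError(f"only {len(merged)} harmonized SNPs matched the panel (need >= 200)")
    z1, z2 = merged["z1"].to_numpy(float), merged["z2"].to_numpy(float)
    n1, n2 = merged["n1"].to_numpy(float), merged["n2"].to_numpy(float)
    l2 = merged["l2"].to_numpy(float)
    keep = (_truncate_chi2(z1 * z1, float(np.nanmean(n1)), chi2_max)
            & _truncate_chi2(z2 * z2, float(np.nanmean(n2)), chi2_max))
    return z1[keep], z2[keep], n1[keep], n2[keep], l2[keep]


def bivariate_ldsc(ss1: SumStats, ss2: SumStats, panel: LDScorePanel,
                   n_blocks: int = DEFAULT_N_BLOCKS,
                   chi2_max: float | None = None) -> GeneticCorrelationEstimate:
    """Genetic correlation between two traits by cross-trait LD Score
    regression.

    z1*z2 is regressed on sqrt(N1*N2)*l/M with a free intercept (which
    absorbs phenotypic correlation in overlapping samples); the slope is
    the genetic covariance and rg = gcov / sqrt(h2_1 * h2_2). The jackknife
    SE of rg re-forms the ratio from delete-one-block estimates of all
    three regressions over the same SNP blocks. rg is reported unclipped;
    |rg| > 1 sets ``out_of_range``.
    """
    z1, z2, n1, n2, l2 = _aligned_bivariate_arrays(ss1, ss2, panel, chi2_max)
    if z1.size < 200:
        raise LdscError("fewer than 200 SNPs after chi2 truncation")
    M = panel.m_total

    coef1, _, del1, pred1 = _univariate_components(z1 * z1, n1, l2, M, n_blocks)
    coef2, _, del2, pred2 = _univariate_components(z2 * z2, n2, l2, M, n_blocks)
    if coef1[1] <= 0 or coef2[1] <= 0:
        warnings.warn("non-positive heritability estimate; rg undefined")
        return GeneticCorrelationEstimate(
            rg=float("nan"), se=float("nan"), gcov=float("nan"), gcov_int=float("nan"),
            h2_1=float(coef1[1]), h2_2=float(coef2[1]), out_of_range=False, n_snps=int(z1.size))

    xc = np.sqrt(n1 * n2) * l2 / M
    yc = z1 * z2
    coefc0, _, _ = _wls_jackknife(xc, yc, np.ones_like(xc), 2)
    predc = coefc0[0] + coefc0[1] * xc
    wc = 1.0 / (np.maximum(l2, 1.0) * (pred1 * pred2 + predc * predc))
    coefc, _, delc = _wls_jackknife(xc, yc, wc, n_blocks)

    gcov = float(coefc[1])
    rg = gcov / np.sqrt(coef1[1] * coef2[1])
    nb = min(del1.shape[0], del2.shape[0], delc.shape[0])
    h1_d = np.maximum(del1[:nb, 1], 1e-12)
    h2_d = np.maximum(del2[:nb, 1], 1e-12)
    rg_d = delc[:nb, 1] / np.sqrt(h1_d * h2_d)
    se = float(np.sqrt((nb - 1) / nb * ((rg_d - rg_d.mean()) ** 2).sum()))
    return GeneticCorrelationEstimate(
        rg=float(rg), se=se, gcov=gcov, gcov_int=float(coefc[0]),
        h2_1=float(coef1[1]), h2_2=float(coef2[1]),
        out_of_range=bool(abs(rg) > 1.0), n_snps=int(z1.size),
    )


def key_indicators(ss: SumStats, cohorts: list[CohortSpec] | None,
                   panel: LDScorePanel, n_blocks: int = DEFAULT_N_BLOCKS) -> KeyIndicators:
    """All five Step-1 indicators for one file. EffN comes from the cohort
    list when supplied, else from the per-SNP EFF_N column (max), else from
    the N column (continuous-trait convention)."""
    if cohorts:
        eff_n = effective_sample_size(cohorts)
    elif np.isfinite(ss.table["eff_n"].to_numpy(float)).any():
        eff_n = float(np.nanmax(ss.table["eff_n"].to_numpy(float)))
    else:
        eff_n = float(np.nanmax(ss.table["n"].to_numpy(float)))
    mean_chi2, lambda_gc = chi2_stats(ss)
    fit = univariate_ldsc(ss, panel, n_blocks=n_blocks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ratio = attenuation_ratio(fit.intercept, mean_chi2)
    return KeyIndicators(
        eff_n=eff_n, h2=fit.h2, h2_se=fit.h2_se, mean_chi2=mean_chi2,
        lambda_gc=lambda_gc, intercept=fit.intercept,
        intercept_se=fit.intercept_se, ratio=ratio,
    )


def key_indicators_pair(full: SumStats, down: SumStats,
                        cohorts_full: list[CohortSpec] | None,
                        cohorts_down: list[CohortSpec] | None,
                        panel: LDScorePanel,
                        n_blocks: int = DEFAULT_N_BLOCKS):
    """Key indicators for a full/down-sampled pair plus the delta report:
    percentage changes for EffN, mean chi2 and lambda_GC, absolute
    differences for h2 and the attenuation ratio."""
    ki_full = key_indicators(full, cohorts_full, panel, n_blocks)
    ki_down = key_indicators(down, cohorts_down, panel, n_blocks)

    def _pct(d, f):
        return (d - f) / f * 100.0 if f != 0 else float("nan")

    deltas = {
        "eff_n_pct": _pct(ki_down.eff_n, ki_full.eff_n),
        "mean_chi2_pct": _pct(ki_down.mean_chi2, ki_full.mean_chi2),
        "lambda_gc_pct": _pct(ki_down.lambda_gc, ki_full.lambda_gc),
        "h2_abs": ki_down.h2 - ki_full.h2,
        "ratio_abs": ki_down.ratio - ki_full.ratio,
    }
    return ki_full, ki_down, deltas
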