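r"""Single-factor genomic structural equation modeling on summary statistics.

Workflow: (1) estimate a genetic covariance matrix S across T traits
(heritabilities on the diagonal, genetic covariances off it) together with
the sampling covariance V of its T(T+1)/2 unique elements by a joint
delete-one-block jackknife; (2) fit a confirmatory one-factor model with
unit-variance identification to the standardized S by diagonally weighted
least squares (DWLS, W = diag(V)^-1), reporting loadings, residual
variances, a residual-based model chi-square, CFI, SRMR and AIC; (3)
estimate per-SNP effects on the latent factor by GLS of the SNP-trait
genetic covariance vector on the loading vector.

Standardization uses the full-sample diagonal of S as a fixed scaling, so
jackknife replicates of the standardized moments — including the diagonal
ones — retain sampling variance and the model keeps its full
df = T(T+1)/2 - 2T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldsc import (LDScorePanel, LdscError, _truncate_chi2, _univariate_components,
                   _wls_jackknife)
from .sumstats import SumStats, harmonize_pair

__all__ = [
    "GeneticCovariance",
    "FactorFit",
    "genetic_covariance",
    "fit_single_factor",
    "compare_factor_fits",
    "factor_gwas",
    "factor_gwas_sumstats",
    "snp_genetic_cov",
]

GOOD_FIT_CFI = 0.9
GOOD_FIT_SRMR = 0.08


@dataclass
class GeneticCovariance:
    """Genetic covariance matrix S over ``traits`` and jackknife sampling
    covariance V of vech(S) (lower-triangle order of ``np.tril_indices``)."""

    traits: list
    S: np.ndarray
    V: np.ndarray
    n_snps: int = 0
    n_blocks: int = 0
    nonpositive_diag: list = field(default_factory=list)

    def __post_init__(self) -> None:
        T = len(self.traits)
        nm = T * (T + 1) // 2
        self.S = np.asarray(self.S, float)
        self.V = np.asarray(self.V, float)
        if self.S.shape != (T, T):
            raise ValueError("S shape does not match trait count")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if self.V.shape != (nm, nm):
            raise ValueError(f"V must be {nm}x{nm}")
        self.nonpositive_diag = [self.traits[i] for i in range(T) if self.S[i, i] <= 0]


@dataclass
class FactorFit:
    """One-factor solution: standardized loadings, residual variances,
    and fit indices. ``good_fit`` applies the CFI > 0.9 and SRMR < 0.08
    thresholds."""

    traits: list
    loadings: np.ndarray
    loading_se: np.ndarray
    residuals: np.ndarray
    residual_se: np.ndarray
    chi2_model: float
    df: int
    cfi: float
    srmr: float
    aic: float
    converged: bool
    heywood: list = field(default_factory=list)

    @property
    def good_fit(self) -> bool:
        return bool(self.cfi > GOOD_FIT_CFI and self.srmr < GOOD_FIT_SRMR)

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "loadings": self.loadings.tolist(),
            "loading_se": self.loading_se.tolist(),
            "residuals": self.residuals.tolist(),
            "residual_se": self.residual_se.tolist(),
            "chi2_model": self.chi2_model, "df": self.df, "cfi": self.cfi,
            "srmr": self.srmr, "aic": self.aic, "good_fit": self.good_fit,
            "converged": self.converged, "heywood": list(self.heywood),
        }


def align_traits(traits: list[SumStats]) -> list[SumStats]:
    """Row-align a list of summary-statistic tables on their common SNPs,
    harmonizing alleles to the first trait's orientation."""
    common = set(traits[0].snp_ids)
    for t in traits[1:]:
        common &= set(t.snp_ids)
    order = [s for s in traits[0].snp_ids if s in common]
    ref = traits[0].subset(order)
    aligned = [ref]
    for t in traits[1:]:
        a_ref, a_t, _ = harmonize_pair(ref, t.subset(sorted(common)), ambiguous_policy="keep")
        aligned.append(a_t.subset(order))
    return aligned


def genetic_covariance(traits: list[SumStats], panel: LDScorePanel,
                       n_blocks: int = 200,
                       labels: list | None = None) -> GeneticCovariance:
    """S and V across T >= 3 traits by LD Score regression.

    Diagonal elements come from the univariate regression of chi2 on
    N*l/M, off-diagonal from the cross-trait regression of z_t*z_u on
    sqrt(N_t*N_u)*l/M, all over one shared SNP set so a single
    delete-one-block jackknife yields the joint sampling covariance V of
    vech(S).
    """
    T = len(traits)
    if T < 3:
        raise LdscError("need at least 3 traits")
    if labels is None:
        labels = [f"trait{i+1}" for i in range(T)]
    aligned = align_traits(traits)
    merged = aligned[0].table[["snp_id"]].merge(panel.table, on="snp_id", how="inner")
    keep_ids = merged["snp_id"]
    if len(keep_ids) < 200:
        raise LdscError("fewer than 200 shared SNPs matched the panel")
    aligned = [t.subset(keep_ids) for t in aligned]
    l2 = merged["l2"].to_numpy(float)
    M = panel.m_total
    Z = np.column_stack([t.table["z"].to_numpy(float) for t in aligned])
    N = np.column_stack([t.table["n"].to_numpy(float) for t in aligned])

    keep = np.ones(len(l2), bool)
    for t in range(T):
        keep &= _truncate_chi2(Z[:, t] ** 2, float(np.nanmean(N[:, t])), None)
    Z, N, l2 = Z[keep], N[keep], l2[keep]
    if Z.shape[0] < 200:
        raise LdscError("fewer than 200 SNPs after chi2 truncation")

    rows, cols = np.tril_indices(T)
    nm = len(rows)
    uni_coef = np.empty((T, 2))
    uni_del = {}
    preds = {}
    for t in range(T):
        coef, _, dels, pred0 = _univariate_components(Z[:, t] ** 2, N[:, t], l2, M, n_blocks)
        uni_coef[t] = coef
        uni_del[t] = dels
        preds[t] = pred0

    nb = uni_del[0].shape[0]
    S = np.zeros((T, T))
    deletes = np.empty((nb, nm))
    for k, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            S[i, i] = uni_coef[i][1]
            deletes[:, k] = uni_del[i][:, 1]
            continue
        x = np.sqrt(N[:, i] * N[:, j]) * l2 / M
        y = Z[:, i] * Z[:, j]
        c0, _, _ = _wls_jackknife(x, y, np.ones_like(x), 2)
        predc = c0[0] + c0[1] * x
        w = 1.0 / (np.maximum(l2, 1.0) * (preds[i] * preds[j] + predc * predc))
        coef, _, dels = _wls_jackknife(x, y, w, n_blocks)
        S[i, j] = S[j, i] = coef[1]
        deletes[:, k] = dels[:, 1]

    centered = deletes - deletes.mean(axis=0)
    V = (nb - 1) / nb * centered.T @ centered
    return GeneticCovariance(traits=list(labels), S=S, V=V,
                             n_snps=int(Z.shape[0]), n_blocks=nb)


def _vech(mat: np.ndarray) -> np.ndarray:
    r, c = np.tril_indices(mat.shape[0])
    return mat[r, c]


def _model_moments(lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    return _vech(np.outer(lam, lam) + np.diag(psi))


def _model_jacobian(lam: np.ndarray, T: int) -> np.ndarray:
    rows, cols = np.tril_indices(T)
    nm = len(rows)
    J = np.zeros((nm, 2 * T))
    for k, (i, j) in enumerate(zip(rows, cols)):
        J[k, i] += lam[j]
        J[k, j] += lam[i]
        if i == j:
            J[k, T + i] = 1.0
    return J


def _residual_chi2(r: np.ndarray, J: np.ndarray, W: np.ndarray, V: np.ndarray) -> float:
    """Browne residual-based test statistic: r' [(I-P) V (I-P)']^+ r with
    P the WLS projection onto the model tangent space. Asymptotically
    chi-square with (moments - parameters) df; exactly 0 at exact fit."""
    A = J.T @ (W[:, None] * J)
    P = J @ np.linalg.pinv(A) @ (J.T * W[None, :])
    U = np.eye(len(r)) - P
    sig = U @ V @ U.T
    return float(r @ np.linalg.pinv(sig, rcond=1e-10) @ r)


def fit_single_factor(gc: GeneticCovariance, max_iter: int = 500) -> FactorFit:
    """DWLS fit of a one-factor model with unit factor variance.

    The standardized moment vector s = vech(D^-1 S D^-1) (D the fixed
    full-sample diagonal scaling) is matched to sigma(theta) =
    vech(lambda lambda' + diag(psi)) under weights diag(V_std)^-1.
    Residual variances are bounded at zero; a bound hit is a Heywood case
    and is flagged rather than fatal. Loadings are sign-canonicalized so
    the largest-magnitude loading is positive. SEs come from the WLS
    sandwich with the full (standardized) V.
    """
    if gc.nonpositive_diag:
        raise LdscError(f"non-positive heritability for {gc.nonpositive_diag}; cannot standardize")
    T = len(gc.traits)
    d = np.sqrt(np.diag(gc.S))
    R = gc.S / np.outer(d, d)
    rows, cols = np.tril_indices(T)
    scale = 1.0 / (d[rows] * d[cols])
    V_std = gc.V * np.outer(scale, scale)
    s = _vech(R)
    w = 1.0 / np.maximum(np.diag(V_std), 1e-12)

    ev, evec = np.linalg.eigh(R)
    lam0 = np.clip(evec[:, -1] * np.sqrt(max(ev[-1], 1e-6)), -0.99, 0.99)
    if lam0.sum() < 0:
        lam0 = -lam0
    psi0 = np.maximum(1.0 - lam0 ** 2, 0.05)
    theta0 = np.concatenate([lam0, psi0])

    def objective(theta):
        lam, psi = theta[:T], theta[T:]
        r = s - _model_moments(lam, psi)
        J = _model_jacobian(lam, T)
        return float(r @ (w * r)), -2.0 * J.T @ (w * r)

    bounds = [(None, None)] * T + [(0.0, None)] * T
    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-10})
    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-6)
    if not converged and np.linalg.norm(res.jac) > 1e-3:
        raise LdscError(f"factor fit did not converge (gradient norm {np.linalg.norm(res.jac):.3g})")
    lam, psi = res.x[:T].copy(), res.x[T:].copy()
    if lam[np.argmax(np.abs(lam))] < 0:
        lam = -lam
    heywood = [gc.traits[i] for i in range(T) if psi[i] <= 1e-10]
    if heywood:
        warnings.warn(f"Heywood case: residual variance bounded at 0 for {heywood}")

    sigma = _model_moments(lam, psi)
    r = s - sigma
    J = _model_jacobian(lam, T)
    A = J.T @ (w[:, None] * J)
    A_inv = np.linalg.pinv(A)
    B = J.T @ (w[:, None] * V_std * w[None, :]) @ J
    cov_theta = A_inv @ B @ A_inv
    se = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))

    nm = len(s)
    df = nm - 2 * T
    chi2_model = _residual_chi2(r, J, w, V_std)
    # independence baseline: diagonal moments fitted freely, off-diagonals zero
    psi_base = np.diag(R).copy()
    r_base = s - _vech(np.diag(psi_base))
    J_base = np.zeros((nm, T))
    for k, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            J_base[k, i] = 1.0
    chi2_base = _residual_chi2(r_base, J_base, w, V_std)
    df_base = nm - T
    cfi = 1.0 - max(0.0, chi2_model - df) / max(chi2_base - df_base, 1e-12)
    srmr = float(np.sqrt(np.mean(r ** 2)))
    aic = chi2_model + 2.0 * (2 * T)
    return FactorFit(
        traits=list(gc.traits), loadings=lam, loading_se=se[:T],
        residuals=psi, residual_se=se[T:],
        chi2_model=chi2_model, df=df, cfi=min(cfi, 1.0), srmr=srmr, aic=aic,
        converged=converged, heywood=heywood,
    )


def compare_factor_fits(fit_a: FactorFit, fit_b: FactorFit,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-parameter standardized differences between two one-factor
    solutions on the same traits: z = (a-b)/sqrt(se_a^2+se_b^2), two-sided
    p, Bonferroni-adjusted significance flag over all parameters."""
    if list(fit_a.traits) != list(fit_b.traits):
        raise ValueError("factor fits are over different traits or orders")
    names = [f"loading:{t}" for t in fit_a.traits] + [f"residual:{t}" for t in fit_a.traits]
    a = np.concatenate([fit_a.loadings, fit_a.residuals])
    b = np.concatenate([fit_b.loadings, fit_b.residuals])
    se = np.sqrt(np.concatenate([fit_a.loading_se, fit_a.residual_se]) ** 2
                 + np.concatenate([fit_b.loading_se, fit_b.residual_se]) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (a - b) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "parameter": names, "a": a, "b": b, "se_a": np.concatenate([fit_a.loading_se, fit_a.residual_se]),
        "se_b": np.concatenate([fit_b.loading_se, fit_b.residual_se]),
        "z": z, "p": p, "significant": p < alpha / len(names),
    })


def snp_genetic_cov(traits: list[SumStats], gc: GeneticCovariance):
    """Per-SNP genetic covariances with the standardized traits.

    On the standardized genetic scale (trait genetic variance 1) the
    covariance of SNP j with trait t is z_jt / sqrt(N_t * h2_t), with
    sampling SE 1 / sqrt(N_t * h2_t). Traits must be row-aligned.
    """
    h2 = np.diag(gc.S)
    if (h2 <= 0).any():
        raise LdscError("non-positive heritability; cannot standardize SNP covariances")
    Z = np.column_stack([t.table["z"].to_numpy(float) for t in traits])
    N = np.column_stack([t.table["n"].to_numpy(float) for t in traits])
    denom = np.sqrt(N * h2[None, :])
    return Z / denom, 1.0 / denom


def factor_gwas(gc: GeneticCovariance, snp_cov: np.ndarray, snp_cov_se: np.ndarray,
                fit: FactorFit, snp_ids=None) -> pd.DataFrame:
    """Per-SNP effects on the latent factor.

    For each SNP the covariance vector g (one entry per trait) is
    regressed on the loading vector by GLS with weight matrix
    Omega = diag(se^2 + psi_t / M), combining the sampling variance of the
    SNP-trait covariance with the per-SNP share of the trait-specific
    residual genetic variance (psi_t spread over the M SNPs the genetic
    covariance was estimated from; omitted when M is unknown).
    beta = (lam' Omega^-1 lam)^-1 lam' Omega^-1 g with variance
    (lam' Omega^-1 lam)^-1.
    """
    if not fit.converged:
        raise LdscError("factor fit did not converge; refusing factor GWAS")
    snp_cov = np.atleast_2d(np.asarray(snp_cov, float))
    snp_cov_se = np.atleast_2d(np.asarray(snp_cov_se, float))
    T = len(fit.traits)
    if snp_cov.shape[1] != T or snp_cov_se.shape != snp_cov.shape:
        raise ValueError("snp_cov/snp_cov_se not aligned to trait order")
    lam = fit.loadings
    omega = snp_cov_se ** 2
    if gc.n_snps > 0:
        omega = omega + fit.residuals[None, :] / gc.n_snps
    bad = ~np.isfinite(omega) | (omega <= 0)
    beta = np.full(snp_cov.shape[0], np.nan)
    se = np.full(snp_cov.shape[0], np.nan)
    ok = ~bad.any(axis=1)
    inv = np.where(ok[:, None], 1.0 / np.where(omega > 0, omega, 1.0), np.nan)
    denom = (lam[None, :] ** 2 * inv).sum(axis=1)
    num = (lam[None, :] * inv * snp_cov).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(ok & (denom > 0), num / denom, np.nan)
        se = np.where(ok & (denom > 0), 1.0 / np.sqrt(denom), np.nan)
    z = beta / se
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    if snp_ids is None:
        snp_ids = [f"snp{i+1}" for i in range(snp_cov.shape[0])]
    return pd.DataFrame({"snp_id": list(snp_ids), "beta_factor": beta,
                         "se": se, "z": z, "p": p})


def factor_gwas_sumstats(traits: list[SumStats], gc: GeneticCovariance,
                         fit: FactorFit) -> SumStats:
    """Convenience: run the factor GWAS over aligned trait files and wrap
    the result as a summary-statistic table (effective N taken as 1/se^2,
    the sample size at which a standardized effect would attain that SE)."""
    aligned = align_traits(traits)
    cov, cov_se = snp_genetic_cov(aligned, gc)
    eff = factor_gwas(gc, cov, cov_se, fit, snp_ids=aligned[0].table["snp_id"])
    ref = aligned[0].table
    tbl = pd.DataFrame({
        "snp_id": eff["snp_id"], "chrom": ref["chrom"].to_numpy(),
        "pos": ref["pos"].to_numpy(),
        "a1": ref["a1"].to_numpy(), "a2": ref["a2"].to_numpy(),
        "beta": eff["beta_factor"], "se": eff["se"], "z": eff["z"], "p": eff["p"],
        "n": 1.0 / eff["se"] ** 2, "eff_n": 1.0 / eff["se"] ** 2,
    })
    tbl = tbl[np.isfinite(tbl["z"])]
    return SumStats(tbl.reset_index(drop=True))
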