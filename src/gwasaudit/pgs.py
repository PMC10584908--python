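r"""Polygenic-score evaluation: incremental R2 / pseudo-R2 over a
covariate baseline with percentile-bootstrap confidence intervals, and
standardized-difference comparison of two score panels.

The incremental R2 of a PGS for one outcome is R2(covariates + PGS) -
R2(covariates), with ordinary R2 for continuous outcomes and a pseudo-R2
(Nagelkerke by default, McFadden by flag) for binary outcomes, both
relative to the intercept-only model. Confidence intervals resample
individuals with the percentile method (default 1000 iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["PgsCohort", "PgsResult", "score_pgs", "incremental_r2", "compare_pgs"]


class PgsError(ValueError):
    pass


@dataclass
class PgsCohort:
    """Individual-level data: dosage matrix (individuals x SNPs, values in
    [0,2]), aligned per-SNP weights, phenotype and covariate frames keyed
    by individual id."""

    dosages: np.ndarray
    weights: np.ndarray
    snp_ids: list
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    ids: list

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        self.weights = np.asarray(self.weights, float)
        n, m = self.dosages.shape
        if self.weights.shape != (m,):
            raise PgsError("weights not aligned to dosage columns")
        if len(self.snp_ids) != m:
            raise PgsError("snp_ids not aligned to dosage columns")
        if len(self.phenotypes) != n or len(self.covariates) != n or len(self.ids) != n:
            raise PgsError("phenotype/covariate rows not aligned to dosage rows")
        if np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2:
            raise PgsError("dosages must lie in [0, 2]")


@dataclass
class PgsResult:
    outcome: str
    family: str
    incr_r2: float
    ci_lo: float
    ci_hi: float
    coef: float
    se: float
    n_used: int
    n_dropped: int = 0
    n_boot: int = 0
    seed: int | None = None
    adjusted: bool = False
    pseudo: str | None = None


def score_pgs(cohort: PgsCohort, standardize: bool = True) -> np.ndarray:
    """Per-individual score sum_j dosage_ij * weight_j, standardized to
    mean 0 / SD 1 by default (the scale used in regression)."""
    s = cohort.dosages @ cohort.weights
    if standardize:
        sd = s.std()
        if sd == 0:
            return s - s.mean()
        s = (s - s.mean()) / sd
    return s


def _linear_r2(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - resid @ resid / tss if tss > 0 else 0.0


def _adjust(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _logistic_loglik(X: np.ndarray, y: np.ndarray) -> float:
    model = sm.Logit(y, X)
    res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise PgsError("logistic fit did not converge (possible separation)")
    return float(res.llf)


def _pseudo_r2(ll_model: float, ll_null: float, n: int, kind: str) -> float:
    if kind == "mcfadden":
        return 1.0 - ll_model / ll_null
    cs = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    return cs / (1.0 - np.exp(2.0 * ll_null / n))


def _delta_r2(Xb, Xf, y, family, adjusted, pseudo):
    n = len(y)
    if family == "linear":
        r2b, r2f = _linear_r2(Xb, y), _linear_r2(Xf, y)
        if adjusted:
            r2b = _adjust(r2b, n, Xb.shape[1] - 1)
            r2f = _adjust(r2f, n, Xf.shape[1] - 1)
        return r2f - r2b
    ll_null = _logistic_loglik(np.ones((n, 1)), y)
    r2b = _pseudo_r2(_logistic_loglik(Xb, y), ll_null, n, pseudo)
    r2f = _pseudo_r2(_logistic_loglik(Xf, y), ll_null, n, pseudo)
    return r2f - r2b


def incremental_r2(cohort: PgsCohort, outcome: str, score: np.ndarray,
                   n_boot: int = 1000, seed: int = 0,
                   family: str | None = None, pseudo: str = "nagelkerke",
                   adjusted: bool = False) -> PgsResult:
    """Incremental R2/pseudo-R2 of a score over the covariate baseline.

    ``family`` is inferred from the outcome coding when None (binary for
    {0,1}-valued outcomes). ``adjusted=True`` uses incremental adjusted
    R2 for the linear family — a bias-corrected variant that is centered
    near zero for a null score, unlike the raw in-sample difference, which
    is non-negative by construction. Missing rows are listwise-deleted and
    counted. The percentile bootstrap resamples individuals (cases and
    controls jointly) with a fixed seed.
    """
    if outcome not in cohort.phenotypes.columns:
        raise PgsError(f"unknown outcome {outcome!r}")
    if pseudo not in ("nagelkerke", "mcfadden"):
        raise PgsError(f"unknown pseudo-R2 {pseudo!r}")
    y = cohort.phenotypes[outcome].to_numpy(float)
    C = cohort.covariates.to_numpy(float)
    score = np.asarray(score, float)
    keep = np.isfinite(y) & np.isfinite(score) & np.isfinite(C).all(axis=1)
    n_dropped = int((~keep).sum())
    y, C, s = y[keep], C[keep], score[keep]
    n = len(y)
    if n < C.shape[1] + 3:
        raise PgsError("too few complete cases")
    if family is None:
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    if family not in ("linear", "logistic"):
        raise PgsError(f"unknown family {family!r}")

    Xb = np.column_stack([np.ones(n), C])
    Xf = np.column_stack([Xb, s])
    try:
        point = _delta_r2(Xb, Xf, y, family, adjusted, pseudo)
    except (PgsError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"{outcome}: {exc}")
        return PgsResult(outcome, family, float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), n, n_dropped, 0, seed, adjusted,
                         pseudo if family == "logistic" else None)

    # PGS coefficient and SE from the covariates+score model
    if family == "linear":
        fit = sm.OLS(y, Xf).fit()
    else:
        fit = sm.Logit(y, Xf).fit(disp=0, maxiter=200)
    coef, se = float(fit.params[-1]), float(fit.bse[-1])

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boots[b] = _delta_r2(Xb[idx], Xf[idx], y[idx], family, adjusted, pseudo)
        except (PgsError, np.linalg.LinAlgError):
            boots[b] = np.nan
            n_failed += 1
    boots = boots[np.isfinite(boots)]
    if boots.size < max(10, n_boot // 2):
        raise PgsError(f"{outcome}: bootstrap failed in {n_failed}/{n_boot} resamples")
    ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5])
    return PgsResult(outcome, family, float(point), float(ci_lo), float(ci_hi),
                     coef, se, n, n_dropped, n_boot, seed, adjusted,
                     pseudo if family == "logistic" else None)


def compare_pgs(res_down: list[PgsResult], res_full: list[PgsResult]) -> pd.DataFrame:
    """Standardized differences between two PGS panels per outcome.

    z = (|coef_down| - |coef_full|) / sqrt(se_down^2 + se_full^2):
    absolute values are compared so a negative z means the down-sampled
    coefficient is attenuated. Also reports the incremental-R2 difference
    in percentage points; the summary attributes carry the rank
    correlation of the coefficient vectors.
    """
    by_out = {r.outcome: r for r in res_full}
    if sorted(by_out) != sorted(r.outcome for r in res_down):
        raise PgsError("outcome sets differ between the two panels")
    rows = []
    for rd in res_down:
        rf = by_out[rd.outcome]
        se = np.sqrt(rd.se ** 2 + rf.se ** 2)
        z = (abs(rd.coef) - abs(rf.coef)) / se if se > 0 else 0.0
        rows.append({
            "outcome": rd.outcome,
            "coef_down": rd.coef, "coef_full": rf.coef,
            "z": z, "p": 2.0 * stats.norm.sf(abs(z)),
            "incr_r2_down": rd.incr_r2, "incr_r2_full": rf.incr_r2,
            "delta_r2_pp": (rd.incr_r2 - rf.incr_r2) * 100.0,
        })
    out = pd.DataFrame(rows)
    if len(out) >= 3:
        out.attrs["coef_rank_correlation"] = float(
            stats.spearmanr(out["coef_down"], out["coef_full"]).statistic)
    return out
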