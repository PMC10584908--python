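"""Comparison of matched estimate vectors from full and down-sampled
analyses: gene-property results across tissues or developmental stages,
and genetic correlations with panels of other traits.

Comparability is judged three ways: Spearman rank correlation of the
point estimates (pattern preservation), per-item large-sample z-tests on
the differences (no individual estimate changed), and 95% CI overlap
(each down-sampled estimate falls inside its full-data interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EstimateVector",
    "read_estimates",
    "rank_correlation",
    "estimate_difference_tests",
    "ci_overlap_table",
]


@dataclass
class EstimateVector:
    """Labeled point estimates with optional SEs and 95% bounds
    (est +/- 1.96*se when derived from SEs)."""

    labels: list
    est: np.ndarray
    se: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.est = np.asarray(self.est, float)
        n = len(self.labels)
        if self.est.shape != (n,):
            raise ValueError("labels and estimates differ in length")
        if self.se is not None:
            self.se = np.asarray(self.se, float)
            if self.se.shape != (n,):
                raise ValueError("se length mismatch")
        if self.ci_lo is None and self.se is not None:
            self.ci_lo = self.est - 1.959963984540054 * self.se
            self.ci_hi = self.est + 1.959963984540054 * self.se
        for b in (self.ci_lo, self.ci_hi):
            if b is not None and np.asarray(b).shape != (n,):
                raise ValueError("CI bound length mismatch")
        if self.ci_lo is not None:
            self.ci_lo = np.asarray(self.ci_lo, float)
            self.ci_hi = np.asarray(self.ci_hi, float)
            if ((self.ci_lo > self.est) | (self.est > self.ci_hi)).any():
                raise ValueError("estimate outside its own CI")

    def __len__(self) -> int:
        return len(self.labels)


def read_estimates(path) -> EstimateVector:
    """TSV with label, est and either se or ci_lo/ci_hi columns — the
    shape of gene-property output tables and rg tables."""
    t = pd.read_csv(path, sep="\t")
    t.columns = [c.lower() for c in t.columns]
    if not {"label", "est"} <= set(t.columns):
        raise ValueError(f"{path}: need label and est columns")
    return EstimateVector(
        labels=t["label"].astype(str).tolist(),
        est=t["est"].to_numpy(float),
        se=t["se"].to_numpy(float) if "se" in t.columns else None,
        ci_lo=t["ci_lo"].to_numpy(float) if "ci_lo" in t.columns else None,
        ci_hi=t["ci_hi"].to_numpy(float) if "ci_hi" in t.columns else None,
    )


def _check_aligned(a: EstimateVector, b: EstimateVector) -> None:
    if list(a.labels) != list(b.labels):
        offenders = sorted(set(a.labels) ^ set(b.labels)) or ["(order differs)"]
        raise ValueError(f"estimate vectors not aligned; offending labels: {offenders[:10]}")


def rank_correlation(a: EstimateVector, b: EstimateVector) -> float:
    """Spearman rank correlation of the two point-estimate vectors
    (average ranks for ties)."""
    _check_aligned(a, b)
    if len(a) < 3:
        raise ValueError("need at least 3 matched estimates")
    return float(stats.spearmanr(a.est, b.est).statistic)


def estimate_difference_tests(a: EstimateVector, b: EstimateVector,
                              correction: str = "none",
                              alpha: float = 0.05) -> pd.DataFrame:
    """Per-item z = (a - b)/sqrt(se_a^2 + se_b^2) with two-sided normal
    p-values; significance flags after the chosen multiplicity correction.

    Treating the SEs as independent ignores the positive dependence of
    full and down-sampled estimates (shared samples), which overstates the
    SE of the difference and is therefore conservative for flagging.
    """
    _check_aligned(a, b)
    if a.se is None or b.se is None:
        raise ValueError("both vectors must carry standard errors")
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    se = np.sqrt(a.se ** 2 + b.se ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (a.est - b.est) / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    thresh = alpha / len(a) if correction == "bonferroni" else alpha
    return pd.DataFrame({"label": a.labels, "est_a": a.est, "est_b": b.est,
                         "z": z, "p": p, "significant": p < thresh})


def ci_overlap_table(a: EstimateVector, b: EstimateVector) -> tuple[pd.DataFrame, dict]:
    """Whether each of b's point estimates falls inside a's 95% CI, plus
    the interval-intersection variant, and summary fractions."""
    _check_aligned(a, b)
    if a.ci_lo is None:
        raise ValueError("vector a needs CIs (or SEs to derive them)")
    point_in = (b.est >= a.ci_lo) & (b.est <= a.ci_hi)
    table = pd.DataFrame({"label": a.labels, "est_a": a.est, "est_b": b.est,
                          "ci_lo_a": a.ci_lo, "ci_hi_a": a.ci_hi,
                          "point_within": point_in})
    summary = {"fraction_point_within": float(point_in.mean())}
    if b.ci_lo is not None:
        intersect = (b.ci_lo <= a.ci_hi) & (a.ci_lo <= b.ci_hi)
        table["intervals_intersect"] = intersect
        summary["fraction_intervals_intersect"] = float(intersect.mean())
    return table, summary
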