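"""Reading, validation, harmonization, and writing of GWAS summary statistics.

Summary statistics are the universal currency of the audit: every step
consumes per-SNP association records (effect allele, Z or BETA/SE, P, N).
Two dialects are supported: a generic header-named whitespace/tab table
(SNP, CHR, BP, A1, A2, BETA, SE, Z, P, N, EFF_N, OUTLIER) and the munged
LDSC ``.sumstats`` dialect (SNP, A1, A2, Z, N). Reads are gzip-transparent.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SumStats",
    "CohortSpec",
    "LoadReport",
    "HarmonizationLog",
    "read_sumstats",
    "write_sumstats",
    "effective_sample_size",
    "harmonize_pair",
]

# P-values read as exact zeros are floored here: keeps -log10 finite while
# preserving ranks.
P_FLOOR = 1e-300

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# canonical internal column order
_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "z", "p", "n", "eff_n", "outlier"]

_HEADER_MAP = {
    "SNP": "snp_id", "CHR": "chrom", "BP": "pos", "A1": "a1", "A2": "a2",
    "BETA": "beta", "SE": "se", "Z": "z", "P": "p", "N": "n",
    "EFF_N": "eff_n", "OUTLIER": "outlier",
}
_HEADER_OUT = {v: k for k, v in _HEADER_MAP.items()}


class SumStatsError(ValueError):
    """Malformed or insufficient summary-statistic input."""


@dataclass
class CohortSpec:
    """One cohort of a meta-analysis: case proportion ``v`` (None for
    continuous traits) and total sample size ``n``."""

    label: str
    v: float | None
    n: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SumStatsError(f"cohort {self.label!r}: n must be > 0, got {self.n}")
        if self.v is not None and not (0.0 < self.v < 1.0):
            raise SumStatsError(f"cohort {self.label!r}: v must be in (0,1), got {self.v}")


@dataclass
class LoadReport:
    """Bookkeeping from :func:`read_sumstats`."""

    path: str
    n_read: int
    n_kept: int
    n_dropped: int
    drop_reasons: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


@dataclass
class HarmonizationLog:
    n_full: int
    n_down: int
    n_common: int
    n_kept: int
    n_swapped: int
    n_strand_flipped: int
    n_ambiguous: int
    n_irreconcilable: int
    ambiguous_policy: str


@dataclass
class SumStats:
    """A validated table of per-SNP association records for one trait.

    ``table`` carries the canonical columns (snp_id, chrom, pos, a1, a2,
    beta, se, z, p, n, eff_n, outlier); absent fields are NaN. Invariants
    (unique snp_id, valid alleles, p in (0,1], z == beta/se where all
    present) are enforced at construction via :meth:`validate`.
    """

    table: pd.DataFrame
    report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.table = _canonicalize(self.table)
        self.validate()

    def validate(self) -> None:
        t = self.table
        if len(t) == 0:
            raise SumStatsError("empty summary-statistic table")
        if t["snp_id"].duplicated().any():
            dups = t.loc[t["snp_id"].duplicated(), "snp_id"].head(3).tolist()
            raise SumStatsError(f"duplicate snp_id values, e.g. {dups}")
        for col in ("a1", "a2"):
            bad = ~t[col].isin(VALID_ALLELES)
            if bad.any():
                raise SumStatsError(f"invalid alleles in {col}: {sorted(t.loc[bad, col].unique())[:5]}")
        if (t["a1"] == t["a2"]).any():
            raise SumStatsError("a1 == a2 for some rows")
        p = t["p"].to_numpy(float)
        ok = np.isnan(p) | ((p > 0) & (p <= 1))
        if not ok.all():
            raise SumStatsError("p-values outside (0, 1]")
        b, s, z = (t[c].to_numpy(float) for c in ("beta", "se", "z"))
        m = np.isfinite(b) & np.isfinite(s) & np.isfinite(z) & (s > 0)
        if m.any():
            dev = np.abs(z[m] - b[m] / s[m]) / np.maximum(1.0, np.abs(z[m]))
            if (dev > 1e-6).any():
                raise SumStatsError("z inconsistent with beta/se beyond 1e-6")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> pd.Series:
        return self.table["snp_id"]

    def subset(self, snp_ids) -> "SumStats":
        """Rows for the given markers, in the given order."""
        idx = self.table.set_index("snp_id").loc[list(snp_ids)].reset_index()
        return SumStats(idx)

    def mean_n(self) -> float:
        n = self.table["n"].to_numpy(float)
        return float(np.nanmean(n))


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("snp_id", "chrom") else np.nan
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
    for col in ("pos", "beta", "se", "z", "p", "n", "eff_n", "outlier"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[_COLUMNS].reset_index(drop=True)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sumstats(path, dialect: str = "generic") -> SumStats:
    """Read one summary-statistic file.

    ``dialect='generic'`` requires SNP/A1/A2 + (Z or BETA+SE) + P + N;
    ``dialect='ldsc'`` requires SNP/A1/A2/Z/N (P is derived from Z).
    Rows with unparseable mandatory numerics are dropped and counted in
    the attached :class:`LoadReport`; Z is (re)computed from BETA/SE when
    absent or inconsistent beyond 1e-6 relative tolerance.
    """
    if dialect not in ("generic", "ldsc"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=r"\s+", dtype=str)
    raw.columns = [c.upper() for c in raw.columns]

    required = {"SNP", "A1", "A2"}
    if dialect == "ldsc":
        required |= {"Z", "N"}
    else:
        required |= {"P", "N"}
        if "Z" not in raw.columns and not {"BETA", "SE"} <= set(raw.columns):
            raise SumStatsError(f"{path}: need Z or BETA+SE columns")
    for col in sorted(required):
        if col not in raw.columns:
            raise SumStatsError(f"{path}: missing mandatory column {col}")

    df = raw.rename(columns=_HEADER_MAP)
    df = _canonicalize(df)
    report = LoadReport(path=str(path), n_read=len(df), n_kept=0, n_dropped=0)

    b, s, z = (df[c].to_numpy(float) for c in ("beta", "se", "z"))
    have_bs = np.isfinite(b) & np.isfinite(s) & (s > 0)
    have_z = np.isfinite(z)
    # recompute Z from BETA/SE when missing or inconsistent; log the overrides
    ratio = np.where(have_bs, b / np.where(s > 0, s, np.nan), np.nan)
    inconsistent = have_bs & have_z & (np.abs(z - ratio) > 1e-6 * np.maximum(1.0, np.abs(z)))
    if inconsistent.any():
        report.notes.append(f"{int(inconsistent.sum())} rows: Z recomputed from BETA/SE (file value inconsistent)")
    use_ratio = have_bs & (~have_z | inconsistent)
    z = np.where(use_ratio, ratio, z)
    df["z"] = z

    if dialect == "ldsc" or df["p"].isna().all():
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"].to_numpy(float)))

    # floor p read as 0
    zero_p = df["p"].to_numpy(float) == 0.0
    if zero_p.any():
        df.loc[zero_p, "p"] = P_FLOOR
        report.notes.append(f"{int(zero_p.sum())} rows: p == 0 floored to {P_FLOOR:g}")

    def _drop(mask: np.ndarray, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + k
            df = df.loc[~mask].reset_index(drop=True)

    _drop(~np.isfinite(df["z"].to_numpy(float)), "missing or unparseable Z")
    _drop(~np.isfinite(df["p"].to_numpy(float)), "missing or unparseable P")
    p = df["p"].to_numpy(float)
    _drop((p <= 0) | (p > 1), "P outside (0,1]")
    _drop(~np.isfinite(df["n"].to_numpy(float)) | (df["n"].to_numpy(float) <= 0), "missing or non-positive N")
    _drop(~(df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES)).to_numpy(), "invalid alleles")
    _drop((df["a1"] == df["a2"]).to_numpy(), "a1 == a2")
    _drop(df["snp_id"].duplicated(keep="first").to_numpy(), "duplicate snp_id")

    report.n_dropped = sum(report.drop_reasons.values())
    report.n_kept = len(df)
    if len(df) == 0:
        raise SumStatsError(f"{path}: no valid rows after filtering")
    return SumStats(df, report=report)


def write_sumstats(ss: SumStats, path, include_flags: bool = False) -> None:
    """Write a tab-delimited generic-dialect file.

    With ``include_flags`` a final integer OUTLIER column in {0,1} is
    appended — the indicator disseminated alongside down-sampled files so
    users can filter SNPs whose coefficients deviate from the full-data
    estimates. Round-trip through :func:`read_sumstats` reproduces the
    table to print precision.
    """
    cols = ["snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "z", "p", "n", "eff_n"]
    out = ss.table[cols].copy()
    if include_flags:
        out["outlier"] = ss.table["outlier"].fillna(0).astype(int)
    out = out.dropna(axis=1, how="all")
    out.columns = [_HEADER_OUT[c] for c in out.columns]
    opener = gzip.open(str(path), "wt") if str(path).endswith(".gz") else open(path, "wt")
    with opener as fh:
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def effective_sample_size(cohorts: list[CohortSpec]) -> float:
    """Sum of per-cohort effective sample sizes.

    For a binary-trait cohort with case proportion V and total size N the
    effective size is 4·V·(1−V)·N — the size of the balanced (50% case)
    design with equal power. Continuous-trait cohorts (v=None) contribute
    their total N.
    """
    if not cohorts:
        raise SumStatsError("empty cohort list")
    total = 0.0
    for c in cohorts:
        if c.v is None:
            total += c.n
        else:
            total += 4.0 * c.v * (1.0 - c.v) * c.n
    return total


def _classify_alleles(fa1, fa2, da1, da2):
    """Return (keep, swap_sign, flip_strand) for one SNP, or None if the
    allele pairs cannot be reconciled."""
    if (da1, da2) == (fa1, fa2):
        return (True, False, False)
    if (da1, da2) == (fa2, fa1):
        return (True, True, False)
    ca1, ca2 = COMPLEMENT[da1], COMPLEMENT[da2]
    if (ca1, ca2) == (fa1, fa2):
        return (True, False, True)
    if (ca1, ca2) == (fa2, fa1):
        return (True, True, True)
    return None


def harmonize_pair(full: SumStats, down: SumStats, ambiguous_policy: str = "drop"):
    """Align a down-sampled table to its full-data twin.

    Intersects on snp_id; where the down-sampled file reports the swapped
    allele pair its beta and z are negated and the alleles swapped; strand
    flips are resolved by complementing. Strand-ambiguous SNPs (A/T, C/G)
    are dropped by default since strand cannot be resolved without allele
    frequencies. Irreconcilable allele pairs are dropped and logged, never
    silently kept. Returns ``(full_aligned, down_aligned, log)`` with both
    tables row-aligned on snp_id.
    """
    if ambiguous_policy not in ("drop", "keep"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    f = full.table.set_index("snp_id", drop=False)
    d = down.table.set_index("snp_id", drop=False)
    common = f.index.intersection(d.index)
    log = HarmonizationLog(
        n_full=len(f), n_down=len(d), n_common=len(common), n_kept=0,
        n_swapped=0, n_strand_flipped=0, n_ambiguous=0, n_irreconcilable=0,
        ambiguous_policy=ambiguous_policy,
    )
    keep_ids, swap_ids, flip_ids = [], [], []
    for sid in common:
        fa1, fa2 = f.at[sid, "a1"], f.at[sid, "a2"]
        da1, da2 = d.at[sid, "a1"], d.at[sid, "a2"]
        if (fa1, fa2) in AMBIGUOUS_PAIRS:
            log.n_ambiguous += 1
            if ambiguous_policy == "drop":
                continue
            # keep: only the non-strand interpretations are considered
            if (da1, da2) == (fa1, fa2):
                keep_ids.append(sid)
            elif (da1, da2) == (fa2, fa1):
                keep_ids.append(sid)
                swap_ids.append(sid)
            else:
                log.n_irreconcilable += 1
            continue
        cls = _classify_alleles(fa1, fa2, da1, da2)
        if cls is None:
            log.n_irreconcilable += 1
            continue
        _, swap, flip = cls
        keep_ids.append(sid)
        if swap:
            swap_ids.append(sid)
        if flip:
            flip_ids.append(sid)
    if not keep_ids:
        raise SumStatsError("no SNPs left after harmonization")
    log.n_kept = len(keep_ids)
    log.n_swapped = len(swap_ids)
    log.n_strand_flipped = len(flip_ids)

    f_al = f.loc[keep_ids].reset_index(drop=True)
    d_al = d.loc[keep_ids].reset_index(drop=True).copy()
    swap_mask = d_al["snp_id"].isin(swap_ids).to_numpy()
    flip_mask = d_al["snp_id"].isin(flip_ids).to_numpy()
    if flip_mask.any():
        d_al.loc[flip_mask, "a1"] = d_al.loc[flip_mask, "a1"].map(COMPLEMENT)
        d_al.loc[flip_mask, "a2"] = d_al.loc[flip_mask, "a2"].map(COMPLEMENT)
    if swap_mask.any():
        a1 = d_al.loc[swap_mask, "a1"].copy()
        d_al.loc[swap_mask, "a1"] = d_al.loc[swap_mask, "a2"].to_numpy()
        d_al.loc[swap_mask, "a2"] = a1.to_numpy()
        d_al.loc[swap_mask, "beta"] = -d_al.loc[swap_mask, "beta"]
        d_al.loc[swap_mask, "z"] = -d_al.loc[swap_mask, "z"]
    return SumStats(f_al), SumStats(d_al), log
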