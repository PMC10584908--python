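"""Orchestration of the six-step comparability audit over a configuration.

Step 1 — key-indicator deltas, full/down genetic correlation, and the
three coefficient-concordance checks on near-independent SNPs. Steps 2-3
(skippable for univariate audits) — single-factor model stability and
factor-level signal/power loss. Step 4 — gene-property estimate tables.
Step 5 — genetic-correlation patterns with other traits. Step 6 —
polygenic-score explanatory power. Each enabled step runs independently;
failures are recorded in the report without aborting later steps. The
markdown rendering is generated from the JSON payload, so the two views
can never disagree.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import ldsc, patterns, pgs, power
from .sumstats import CohortSpec, read_sumstats

__all__ = ["AuditConfig", "AuditReport", "run_audit"]


@dataclass
class AuditConfig:
    """Inputs and thresholds for one audit run. File paths are resolved
    relative to the config file's directory when loaded from YAML."""

    full: str | None = None
    down: str | None = None
    panel: str | None = None
    panel_m: str | None = None
    steps: tuple = (1, 2, 3, 4, 5, 6)
    cohorts_full: list = field(default_factory=list)   # (label, v, n) triples
    cohorts_down: list = field(default_factory=list)
    traits_full: list = field(default_factory=list)    # paths, step 2-3
    traits_down: list = field(default_factory=list)
    ld_matrix: str | None = None
    gene_property_full: str | None = None
    gene_property_down: str | None = None
    rg_table_full: str | None = None
    rg_table_down: str | None = None
    pgs_dosages: str | None = None
    pgs_phenotypes: str | None = None
    pgs_covariates: str | None = None
    pgs_weights_full: str | None = None
    pgs_weights_down: str | None = None
    pgs_outcomes: list = field(default_factory=list)
    p_thresh: float = 5e-8
    r2_thresh: float = 0.1
    p0: float = 0.99
    alpha: float = 0.05
    ci_level: float = 0.95
    n_boot: int = 1000
    n_blocks: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AuditConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("full", "down", "panel", "panel_m", "ld_matrix",
                     "gene_property_full", "gene_property_down",
                     "rg_table_full", "rg_table_down", "pgs_dosages",
                     "pgs_phenotypes", "pgs_covariates",
                     "pgs_weights_full", "pgs_weights_down"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, str((base / v) if not Path(v).is_absolute() else Path(v)))
        cfg.traits_full = [str(base / t) for t in cfg.traits_full]
        cfg.traits_down = [str(base / t) for t in cfg.traits_down]
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not set(self.steps) <= {1, 2, 3, 4, 5, 6}:
            raise ValueError("steps must be a subset of 1..6")
        if not (0 < self.p_thresh < 1 and 0 <= self.r2_thresh <= 1):
            raise ValueError("p_thresh/r2_thresh out of range")
        if not (0 < self.p0 < 1 and 0 < self.alpha < 1 and 0 < self.ci_level < 1):
            raise ValueError("p0/alpha/ci_level out of range")
        for name in ("full", "down", "panel", "ld_matrix"):
            v = getattr(self, name)
            if v is not None and not Path(v).exists():
                raise FileNotFoundError(f"{name}: {v}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


@dataclass
class AuditReport:
    data: dict

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(_jsonable(self.data), indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_markdown(self, path=None) -> str:
        d = _jsonable(self.data)
        lines = ["# Down-sampling comparability audit", ""]
        adv = d.get("advisory")
        if adv:
            lines += [f"**Advisory: {adv}**", ""]
        for k in sorted(d.get("steps", {}), key=int):
            step = d["steps"][k]
            lines.append(f"## Step {k}: {step.get('title', '')}")
            if "error" in step:
                lines += ["", f"*step failed: {step['error']}*", ""]
                continue
            if step.get("skipped"):
                lines += ["", "*skipped by configuration (univariate mode)*", ""]
                continue
            lines.append("")
            for key, val in step.items():
                if key in ("title", "skipped"):
                    continue
                lines.append(f"- **{key}**: {_md_value(val)}")
            lines.append("")
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _md_value(val) -> str:
    if isinstance(val, float):
        return f"{val:.6g}"
    if isinstance(val, dict):
        return "; ".join(f"{k}={_md_value(v)}" for k, v in val.items())
    if isinstance(val, list) and len(val) > 6:
        return f"[{len(val)} entries]"
    return str(val)


def _triples_to_cohorts(triples) -> list[CohortSpec] | None:
    if not triples:
        return None
    return [CohortSpec(str(t[0]), None if t[1] in (None, "NA") else float(t[1]), float(t[2]))
            for t in triples]


def run_audit(cfg: AuditConfig) -> AuditReport:
    """Run every enabled step, collecting results and failures per step."""
    cfg.validate()
    report: dict = {"config": {k: v for k, v in dataclasses.asdict(cfg).items()},
                    "steps": {}, "advisory": None, "hard_failures": 0}
    panel = None
    if cfg.panel:
        panel = ldsc.read_ld_panel(cfg.panel, cfg.panel_m)
    full = down = None
    pair = None
    if cfg.full and cfg.down:
        full = read_sumstats(cfg.full)
        down = read_sumstats(cfg.down)
        from .sumstats import harmonize_pair
        pair = harmonize_pair(full, down)

    for step in range(1, 7):
        if step not in cfg.steps:
            report["steps"][str(step)] = {"title": _TITLES[step], "skipped": True}
            continue
        try:
            report["steps"][str(step)] = _STEP_RUNNERS[step](cfg, panel, pair)
        except Exception as exc:  # recorded, not fatal
            report["steps"][str(step)] = {"title": _TITLES[step], "error": f"{type(exc).__name__}: {exc}"}
            report["hard_failures"] += 1

    s1 = report["steps"].get("1", {})
    rg = s1.get("rg_full_down")
    if rg and rg.get("rg") is not None and np.isfinite(rg["rg"]):
        excludes_one = rg["rg"] + 1.96 * rg["se"] < 1.0
        report["advisory"] = (
            "rg(full, down) < 1: evaluate comparability with the six-step audit"
            if excludes_one else "comparable: rg(full, down) consistent with 1")
    return AuditReport(report)


_TITLES = {
    1: "Loss of genetic signal in down-sampled univariate GWAS",
    2: "Stability of the single-factor solution",
    3: "Factor-level signal and SNP-detection power",
    4: "Gene-property estimate patterns",
    5: "Genetic correlations with other traits",
    6: "Polygenic-score explanatory power",
}


def _step1(cfg: AuditConfig, panel, pair) -> dict:
    if pair is None or panel is None:
        raise ValueError("step 1 needs full, down, and panel inputs")
    f_al, d_al, hlog = pair
    ki_f, ki_d, deltas = ldsc.key_indicators_pair(
        f_al, d_al, _triples_to_cohorts(cfg.cohorts_full),
        _triples_to_cohorts(cfg.cohorts_down), panel, n_blocks=cfg.n_blocks)
    rg = ldsc.bivariate_ldsc(f_al, d_al, panel, n_blocks=cfg.n_blocks)
    out = {
        "title": _TITLES[1],
        "harmonization": dataclasses.asdict(hlog),
        "key_indicators_full": ki_f.to_dict(),
        "key_indicators_down": ki_d.to_dict(),
        "deltas": deltas,
        "rg_full_down": {"rg": rg.rg, "se": rg.se, "gcov": rg.gcov, "n_snps": rg.n_snps},
    }
    subset = _lead_subset(cfg, f_al)
    if subset:
        out["concordance"] = conc.run_concordance(
            f_al, d_al, subset, p0=cfg.p0, level=cfg.ci_level).to_dict()
    else:
        out["concordance"] = {"note": f"no SNPs at p < {cfg.p_thresh:g}"}
    return out


def _lead_subset(cfg: AuditConfig, f_al) -> list:
    if cfg.ld_matrix:
        ld = pd.read_csv(cfg.ld_matrix, sep="\t", index_col=0)
        have = f_al.table["p"].to_numpy(float) < cfg.p_thresh
        ids = set(f_al.table.loc[have, "snp_id"]) & set(ld.index)
        sub = f_al.subset(sorted(ids)) if ids else None
        if sub is None:
            return []
        return conc.ld_clump(sub, ld.loc[sorted(ids), sorted(ids)],
                             cfg.p_thresh, cfg.r2_thresh).snp_ids
    t = f_al.table
    return t.loc[t["p"].to_numpy(float) < cfg.p_thresh, "snp_id"].tolist()


def _load_traits(paths):
    return [read_sumstats(p) for p in paths]


def _step2(cfg: AuditConfig, panel, pair) -> dict:
    from .factor import compare_factor_fits, fit_single_factor, genetic_covariance

    if not (cfg.traits_full and cfg.traits_down):
        raise ValueError("step 2 needs traits_full and traits_down file lists")
    gc_f = genetic_covariance(_load_traits(cfg.traits_full), panel, cfg.n_blocks)
    gc_d = genetic_covariance(_load_traits(cfg.traits_down), panel, cfg.n_blocks)
    fit_f = fit_single_factor(gc_f)
    fit_d = fit_single_factor(gc_d)
    comp = compare_factor_fits(fit_d, fit_f)
    return {"title": _TITLES[2], "fit_full": fit_f.to_dict(), "fit_down": fit_d.to_dict(),
            "comparison": comp, "any_parameter_different": bool(comp["significant"].any())}


def _step3(cfg: AuditConfig, panel, pair) -> dict:
    from .factor import factor_gwas_sumstats, fit_single_factor, genetic_covariance

    if cfg.traits_full and cfg.traits_down:
        gc_f = genetic_covariance(_load_traits(cfg.traits_full), panel, cfg.n_blocks)
        gc_d = genetic_covariance(_load_traits(cfg.traits_down), panel, cfg.n_blocks)
        ss_f = factor_gwas_sumstats(_load_traits(cfg.traits_full), gc_f, fit_single_factor(gc_f))
        ss_d = factor_gwas_sumstats(_load_traits(cfg.traits_down), gc_d, fit_single_factor(gc_d))
    elif pair is not None:
        ss_f, ss_d, _ = pair
    else:
        raise ValueError("step 3 needs either trait lists or a univariate pair")
    mean_f, lam_f = ldsc.chi2_stats(ss_f)
    mean_d, lam_d = ldsc.chi2_stats(ss_d)
    n_f = float(np.nanmax(ss_f.table["eff_n"].fillna(ss_f.table["n"])))
    n_d = float(np.nanmax(ss_d.table["eff_n"].fillna(ss_d.table["n"])))
    td = ss_d.table
    gws = td["p"].to_numpy(float) < cfg.p_thresh
    out = {
        "title": _TITLES[3],
        "eff_n": {"full": n_f, "down": n_d, "pct": (n_d - n_f) / n_f * 100.0},
        "mean_chi2": {"full": mean_f, "down": mean_d, "pct": (mean_d - mean_f) / mean_f * 100.0},
        "lambda_gc": {"full": lam_f, "down": lam_d, "pct": (lam_d - lam_f) / lam_f * 100.0},
    }
    if gws.any():
        r2_med = float(np.median(power.squared_std_coeff(
            td.loc[gws, "z"].to_numpy(float), td.loc[gws, "n"].to_numpy(float))))
        out["median_gws_r2"] = r2_med
        out["power_loss_pp_at_median_r2"] = power.power_difference(n_f, n_d, r2_med, cfg.alpha if cfg.alpha < 1e-4 else 5e-8)
    curve_f = power.power_curve(n_f)
    curve_d = power.power_curve(n_d)
    out["power_curve"] = [{"r2": r, "power_full": pf, "power_down": pd_,
                          "loss_pp": (pf - pd_) * 100.0}
                         for r, pf, pd_ in zip(curve_f["r2"], curve_f["power"], curve_d["power"])]
    return out


def _step4(cfg: AuditConfig, panel, pair) -> dict:
    if not (cfg.gene_property_full and cfg.gene_property_down):
        raise ValueError("step 4 needs gene-property estimate tables")
    a = patterns.read_estimates(cfg.gene_property_full)
    b = patterns.read_estimates(cfg.gene_property_down)
    out = {"title": _TITLES[4], "spearman": patterns.rank_correlation(a, b)}
    if a.se is not None and b.se is not None:
        tests = patterns.estimate_difference_tests(a, b, correction="bonferroni")
        out["n_significant_bonferroni"] = int(tests["significant"].sum())
    return out


def _step5(cfg: AuditConfig, panel, pair) -> dict:
    if not (cfg.rg_table_full and cfg.rg_table_down):
        raise ValueError("step 5 needs rg tables for full and down analyses")
    a = patterns.read_estimates(cfg.rg_table_full)
    b = patterns.read_estimates(cfg.rg_table_down)
    out = {"title": _TITLES[5], "spearman": patterns.rank_correlation(a, b)}
    if a.se is not None and b.se is not None:
        tests = patterns.estimate_difference_tests(a, b, correction="none")
        out["n_significant_uncorrected"] = int(tests["significant"].sum())
        _, overlap = patterns.ci_overlap_table(a, b)
        out.update(overlap)
    return out


def _step6(cfg: AuditConfig, panel, pair) -> dict:
    need = (cfg.pgs_dosages, cfg.pgs_phenotypes, cfg.pgs_covariates,
            cfg.pgs_weights_full, cfg.pgs_weights_down)
    if not all(need):
        raise ValueError("step 6 needs dosage, phenotype, covariate, and two weight files")
    dos = pd.read_csv(cfg.pgs_dosages, sep="\t", index_col=0)
    phe = pd.read_csv(cfg.pgs_phenotypes, sep="\t", index_col=0)
    cov = pd.read_csv(cfg.pgs_covariates, sep="\t", index_col=0)
    outcomes = cfg.pgs_outcomes or list(phe.columns)

    def _panel_results(weights_path):
        w = pd.read_csv(weights_path, sep="\t")
        w.columns = [c.upper() for c in w.columns]
        w = w.set_index("SNP")["WEIGHT"].reindex(dos.columns).fillna(0.0)
        cohort = pgs.PgsCohort(dos.to_numpy(float), w.to_numpy(float),
                               list(dos.columns), phe, cov, list(dos.index))
        s = pgs.score_pgs(cohort)
        return [pgs.incremental_r2(cohort, o, s, n_boot=cfg.n_boot, seed=cfg.seed)
                for o in outcomes]

    res_full = _panel_results(cfg.pgs_weights_full)
    res_down = _panel_results(cfg.pgs_weights_down)
    comp = pgs.compare_pgs(res_down, res_full)
    return {"title": _TITLES[6],
            "results_full": [dataclasses.asdict(r) for r in res_full],
            "results_down": [dataclasses.asdict(r) for r in res_down],
            "comparison": comp,
            "coef_rank_correlation": comp.attrs.get("coef_rank_correlation")}


_STEP_RUNNERS = {1: _step1, 2: _step2, 3: _step3, 4: _step4, 5: _step5, 6: _step6}
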