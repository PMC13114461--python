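"""End-to-end study workflow: ingest -> profile -> model selection ->
inference -> variance decomposition -> EB profiles -> power/MDES -> report.

The selection chain mirrors the study design: random-intercept vs
random-slope structure at the class level (ML likelihood-ratio tests), a
school-level random intercept test, pruning of non-significant fixed
interactions, and the within/between (contextual) decomposition of age,
each decided at alpha = 0.05.  The final model is refit by REML before
inference.  Every random stage records its seed; all outputs are tidy CSVs
plus one JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import inference as inf
from . import power as power_mod
from .lmm import (FitResult, ModelSpec, final_model_spec, fit,
                  information_criteria, lrt)
from .scores import (decompose_age, descriptive_table, ensure_percentile,
                     mastery_table, read_scores, validate_scores, write_scores,
                     zone_table)

log = logging.getLogger("motorprof")

#: fixed set used for the random-structure comparisons (combined age)
CHAIN_FIXED = ("intercept", "domain", "sex", "domain:sex", "age_c")
#: initial full fixed set, before pruning
FULL_FIXED = ("intercept", "domain", "sex", "domain:sex", "age_c",
              "age_c:sex", "domain:age_c", "domain:age_c:sex")


@dataclasses.dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` / ``synthetic`` must be set; ``synthetic``
    holds keyword overrides for the cohort generator defaults.
    """
    input_path: str | None = None
    synthetic: dict | None = None
    alpha: float = 0.05
    adjust_method: str = "westfall"
    power_terms: tuple[str, ...] = ()
    power_n_iter: int = 200
    power_n_grid: int = 12
    seed: int = 0
    outdir: str = "motorprof_run"

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_path / synthetic must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "power_terms" in raw:
            raw["power_terms"] = tuple(raw["power_terms"])
        return cls(**raw)


def _ml(spec: ModelSpec, table: pd.DataFrame, seed: int) -> FitResult:
    return fit(spec, table, method="ML", seed=seed)


def select_model(table: pd.DataFrame, alpha: float = 0.05,
                 seed: int = 0) -> dict:
    """Run the sequential ML model-selection chain.

    Returns a dict with every comparison (statistic, df, p, decision), the
    model-comparison table (AIC/BIC/logLik per random structure) and the
    selected final specification.
    """
    steps = []
    comparison_rows = []

    def record(name, fit_r, fit_f, keep_full_label, drop_label):
        stat, df, p = lrt(fit_r, fit_f)
        keep = p < alpha
        steps.append({"comparison": name, "statistic": stat, "df": df,
                      "p": p, "decision": keep_full_label if keep else drop_label})
        log.info("LRT %s: chi2(%d) = %.2f, p = %.4g -> %s", name, df, stat, p,
                 steps[-1]["decision"])
        return keep

    # --- random structure (combined-age fixed set) ---
    m1 = _ml(ModelSpec(CHAIN_FIXED, class_re="none"), table, seed)
    m2 = _ml(ModelSpec(CHAIN_FIXED, class_re="intercept"), table, seed)
    m3 = _ml(ModelSpec(CHAIN_FIXED, class_re="full"), table, seed)
    for label, m in (("model_1_student_only", m1),
                     ("model_2_class_intercept", m2),
                     ("model_3_class_slopes", m3)):
        aic, bic = information_criteria(m.loglik, m.n_params, m.n_obs)
        comparison_rows.append({"model": label, "n_params": m.n_params,
                                "AIC": aic, "BIC": bic, "logLik": m.loglik})
    keep_ci = record("1 vs 2 (class intercept)", m1, m2,
                     "keep class intercept", "drop class level")
    keep_slopes = record("2 vs 3 (class domain slopes)", m2, m3,
                         "keep class slopes", "intercept only")
    class_re = "full" if keep_slopes else ("intercept" if keep_ci else "none")
    chosen = {"full": m3, "intercept": m2, "none": m1}[class_re]

    # --- school-level random intercept ---
    m_school = _ml(ModelSpec(CHAIN_FIXED, class_re=class_re, school_re=True),
                   table, seed)
    keep_school = record("school intercept", chosen, m_school,
                         "keep school level", "drop school level")

    # --- fixed-effect pruning (ML, chosen random structure) ---
    m_full = _ml(ModelSpec(FULL_FIXED, class_re=class_re,
                           school_re=keep_school), table, seed)
    pruned1 = tuple(t for t in FULL_FIXED
                    if t not in ("domain:age_c:sex", "age_c:sex"))
    m_pruned1 = _ml(ModelSpec(pruned1, class_re=class_re,
                              school_re=keep_school), table, seed)
    keep_3way = record("three-way + age:sex", m_pruned1, m_full,
                       "keep interactions", "drop interactions")
    base = m_full if keep_3way else m_pruned1
    base_fixed = FULL_FIXED if keep_3way else pruned1
    pruned2 = tuple(t for t in base_fixed if t != "domain:age_c")
    m_pruned2 = _ml(ModelSpec(pruned2, class_re=class_re,
                              school_re=keep_school), table, seed)
    keep_dom_age = record("domain:age_c", m_pruned2, base,
                          "keep domain:age", "drop domain:age")
    current_fixed = base_fixed if keep_dom_age else pruned2

    # --- age decomposition (contextual-effects test): only well-formed once
    # no retained interaction still involves the combined age term ---
    age_in_interaction = any("age_c" in t.split(":") and t != "age_c"
                             for t in current_fixed)
    if "age_c" in current_fixed and not age_in_interaction:
        decomposed_fixed = tuple(
            ("age_within" if t == "age_c" else t) for t in current_fixed
        ) + ("age_between",)
        m_comb = _ml(ModelSpec(current_fixed, class_re=class_re,
                               school_re=keep_school), table, seed)
        m_dec = _ml(ModelSpec(decomposed_fixed, class_re=class_re,
                              school_re=keep_school), table, seed)
        keep_dec = record("age decomposition", m_comb, m_dec,
                          "adopt decomposed age", "keep combined age")
        final_fixed = decomposed_fixed if keep_dec else current_fixed
        aic_c, _ = information_criteria(m_comb.loglik, m_comb.n_params,
                                        m_comb.n_obs)
        aic_d, _ = information_criteria(m_dec.loglik, m_dec.n_params,
                                        m_dec.n_obs)
        steps[-1]["delta_aic"] = aic_d - aic_c
        final_ml = m_dec if keep_dec else m_comb
    else:
        final_fixed = current_fixed
        final_ml = _ml(ModelSpec(final_fixed, class_re=class_re,
                                 school_re=keep_school), table, seed)
    aic, bic = information_criteria(final_ml.loglik, final_ml.n_params,
                                    final_ml.n_obs)
    comparison_rows.append({"model": "final", "n_params": final_ml.n_params,
                            "AIC": aic, "BIC": bic, "logLik": final_ml.loglik})
    return {
        "steps": steps,
        "comparison_table": pd.DataFrame(comparison_rows),
        "final_spec": ModelSpec(final_fixed, class_re=class_re,
                                school_re=keep_school),
        "final_ml_fit": final_ml,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "fits").mkdir(exist_ok=True)
    report: dict = {"seed": config.seed, "alpha": config.alpha, "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"].append(name)

    try:
        # --- ingest ---
        stage("ingest")
        if config.input_path is not None:
            table = read_scores(config.input_path)
        else:
            params = cohort_mod.default_params(seed=config.seed)
            for key, val in (config.synthetic or {}).items():
                setattr(params, key, np.asarray(val, dtype=float)
                        if key.startswith("sigma_") and not np.isscalar(val)
                        else val)
            params.validate()
            table, truth = cohort_mod.generate_cohort(params, seed=config.seed)
            truth["class_effects"].to_csv(outdir / "tables" / "truth_class.csv",
                                          index=False)
            truth["student_effects"].to_csv(
                outdir / "tables" / "truth_student.csv", index=False)
            report["generator_params"] = params.to_dict()
        table = decompose_age(ensure_percentile(validate_scores(table)))
        write_scores(table, outdir / "tables" / "scores.csv")
        report["n_obs"] = int(len(table))
        report["n_children"] = int(table["child_id"].nunique())
        report["n_classes"] = int(table["class_id"].nunique())

        # --- descriptive profiling ---
        stage("profiles")
        descriptive_table(table, seed=config.seed).to_csv(
            outdir / "tables" / "descriptives.csv", index=False)
        zt = zone_table(table)
        zt.to_csv(outdir / "tables" / "zones.csv", index=False)
        mt = mastery_table(table)
        mt.to_csv(outdir / "tables" / "mastery.csv", index=False)
        amber = zt.loc[zt["zone"] == "amber", "n"].sum() / zt["n"].sum()
        red = zt.loc[zt["zone"] == "red", "n"].sum() / zt["n"].sum()
        report["zone_prevalence"] = {"amber": float(amber), "red": float(red)}
        report["mastery_all_three"] = float((mt["mastery"] == 3).mean())

        # --- model selection ---
        stage("model_selection")
        sel = select_model(table, alpha=config.alpha, seed=config.seed)
        sel["comparison_table"].to_csv(
            outdir / "tables" / "model_comparison.csv", index=False)
        report["selection"] = {"steps": sel["steps"],
                               "final_fixed": list(sel["final_spec"].fixed),
                               "class_re": sel["final_spec"].class_re,
                               "school_re": sel["final_spec"].school_re}

        # --- final REML fit ---
        stage("final_fit")
        final = fit(sel["final_spec"], table, method="REML", seed=config.seed)
        if not final.converged:
            log.warning("final REML fit flagged non-converged: %s",
                        final.optim_message)
        report["final_fit"] = final.to_dict()
        with open(outdir / "fits" / "final_reml.json", "w") as fh:
            json.dump(final.to_dict(), fh, indent=1)

        # --- inference ---
        stage("inference")
        wald_rows = []
        wald_by_term = {}
        for term in final.spec.fixed:
            if term == "intercept":
                continue
            w = inf.type3_wald(final, term)
            wald_by_term[term] = w
            wald_rows.append(w.to_dict())
        pd.DataFrame(wald_rows).to_csv(outdir / "tables" / "type3_tests.csv",
                                       index=False)
        report["type3"] = wald_rows

        emm = inf.emmeans(final, by=("domain",))
        emm.to_csv(outdir / "tables" / "emmeans_domain.csv", index=False)
        report["emmeans_domain"] = emm.to_dict("records")

        families = {"domain_pairwise": inf.domain_pairwise(final)}
        if "domain:sex" in final.spec.fixed:
            families["sex_within_domain"] = inf.sex_within_domain(final)
            for s in ("boy", "girl"):
                families[f"domain_pairwise_{s}"] = inf.domain_pairwise(final, s)
        contrast_rows = []
        for fam, contrasts in families.items():
            corr = inf.contrast_correlation(final, contrasts)
            inf.adjust_contrasts(contrasts, corr, method=config.adjust_method,
                                 seed=config.seed)
            for c in contrasts:
                contrast_rows.append({"family": fam, **c.to_dict()})
        pd.DataFrame(contrast_rows).to_csv(outdir / "tables" / "contrasts.csv",
                                           index=False)
        report["contrasts"] = contrast_rows

        # --- variance accounting ---
        stage("variance")
        r2m, r2c = inf.r2_nakagawa(final)
        report["r2"] = {"marginal": r2m, "conditional": r2c}
        null_spec = ModelSpec(("intercept",), class_re=final.spec.class_re,
                              school_re=final.spec.school_re)
        null_ml = fit(null_spec, table, method="ML", seed=config.seed)
        final_ml = sel["final_ml_fit"]
        stat, df, p = lrt(null_ml, final_ml)
        report["fixed_effects_lrt"] = {"statistic": stat, "df": df, "p": p}
        report["pseudo_r2"] = inf.pseudo_r2(final_ml.loglik, null_ml.loglik,
                                            final_ml.n_obs)
        if final.spec.class_re == "full":
            vd = inf.variance_decomposition(final)
            report["variance_decomposition"] = vd.to_dict()
            eb = inf.eb_estimates(final)
            eb.to_csv(outdir / "tables" / "eb_classes.csv", index=False)
            n_flag = int(eb["intercept_significant"].sum())
            report["eb_classes"] = {
                "n_flagged_intercept": n_flag,
                "n_classes": int(len(eb)),
                "intercept_range": [float(eb["intercept_blup"].min()),
                                    float(eb["intercept_blup"].max())],
            }

        report["diagnostics"] = inf.diagnostics(final)

        # --- power / MDES ---
        if config.power_terms:
            stage("power")
            report["power"] = {}
            for term in config.power_terms:
                grid = power_mod.default_grid(final, term,
                                              n_points=config.power_n_grid)
                curve = power_mod.power_curve(
                    final, term, grid, n_iter=config.power_n_iter,
                    alpha=config.alpha, seed=config.seed)
                entry = {"curve": curve.to_dict()}
                try:
                    m = power_mod.mdes(curve)
                    entry["mdes"] = m.to_dict()
                    entry["type_m"] = power_mod.type_m_flag(
                        wald_by_term[term], m, alpha=config.alpha)
                except ValueError as exc:
                    entry["mdes_error"] = str(exc)
                report["power"][term] = entry
                pd.DataFrame({"coefficient": curve.grid,
                              "power": curve.power,
                              "median_sig_eta": curve.median_sig_eta,
                              "n_failed": curve.n_failed}).to_csv(
                    outdir / "tables" / f"power_{term.replace(':', '_')}.csv",
                    index=False)
    except Exception as exc:
        report["error"] = {"stage": report["stages"][-1], "message": str(exc)}
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
        raise

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default)
    _write_summary(report, outdir / "summary.txt")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_summary(report: dict, path: Path) -> None:
    lines = [f"motorprof run (seed {report['seed']})",
             f"observations: {report.get('n_obs')} "
             f"({report.get('n_children')} children, "
             f"{report.get('n_classes')} classes)", ""]
    for s in report.get("selection", {}).get("steps", []):
        lines.append(f"LRT {s['comparison']}: chi2({s['df']}) = "
                     f"{s['statistic']:.2f}, p = {s['p']:.4f} -> {s['decision']}")
    if "r2" in report:
        lines.append("")
        lines.append(f"R2 marginal = {report['r2']['marginal']:.3f}, "
                     f"conditional = {report['r2']['conditional']:.3f}")
    vd = report.get("variance_decomposition")
    if vd:
        lines.append(f"VPC at grand mean = {vd['vpc_grand_mean']:.3f}")
        shares = ", ".join(f"{k} {100 * v:.1f}%" for k, v in vd["shares"].items())
        lines.append(f"variance shares: {shares}")
    eb = report.get("eb_classes")
    if eb:
        lines.append(f"EB-flagged classes (intercept): "
                     f"{eb['n_flagged_intercept']} of {eb['n_classes']}")
    path.write_text("\n".join(lines) + "\n")


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures",
                  n_classes: int = 4, class_size: int = 4) -> dict:
    """Write a tiny deterministic cohort for unit tests; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cohort_mod.default_params(seed=seed)
    params.n_classes_small = n_classes
    params.class_size_small = class_size
    params.n_classes_large = 0
    params.n_schools = max(n_classes // 2, 1)
    table, truth = cohort_mod.generate_cohort(params, seed=seed)
    scores_path = outdir / "scores.csv"
    write_scores(table, scores_path)
    truth_path = outdir / "truth_class.csv"
    truth["class_effects"].to_csv(truth_path, index=False)
    return {"scores": scores_path, "truth_class": truth_path,
            "n_rows": len(table)}
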