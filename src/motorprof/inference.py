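"""Inference on fitted two-level models.

Covers Type III Wald F tests with containment (inner-outer) denominator
degrees of freedom, partial eta squared with noncentral-F confidence
intervals, Cohen's d from model t statistics, estimated marginal means and
max-t (Westfall-style) adjusted contrasts, Nakagawa R2, Cox-Snell/Nagelkerke
pseudo-R2, the variance decomposition with the grand-mean variance partition
coefficient, empirical-Bayes (BLUP) class profiles, and residual
diagnostics (Breusch-Pagan, generalized VIF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .cohort import Z_DOMAIN
from .lmm import FitResult, ModelSpec, _DOMAIN_CODE, _SEX_CODE
from .scores import DOMAINS

_STUDENT_BASES = {"sex", "age_within", "age_c"}


def term_level(term: str) -> str:
    """Innermost grouping level at which a fixed term varies.

    Terms involving domain vary within student (observation level); sex and
    the within-class/grand-centered age parts vary between students within a
    class; the class mean age (and the intercept) vary only between classes.
    """
    parts = term.split(":")
    if "domain" in parts:
        return "observation"
    if any(p in _STUDENT_BASES for p in parts):
        return "student"
    return "class"


def _term_width(term: str) -> int:
    w = 1
    for p in term.split(":"):
        w *= 2 if p == "domain" else 1
    return w


def containment_df(spec: ModelSpec, n_obs: int, n_students: int,
                   n_classes: int, term: str) -> int:
    """Containment denominator df for ``term`` under the given layout.

    nlme-style inner-outer rule: each level's df is the number of units at
    that level minus the units one level up minus the fixed-effect columns
    estimated at that level (the intercept is not counted).
    """
    if term not in spec.fixed:
        raise ValueError(f"term {term!r} is not in the model")
    counts = {"observation": 0, "student": 0, "class": 0}
    for t in spec.fixed:
        if t == "intercept":
            continue
        counts[term_level(t)] += _term_width(t)
    level = term_level(term)
    if level == "observation":
        return n_obs - n_students - counts["observation"]
    if level == "student":
        return n_students - n_classes - counts["student"]
    return n_classes - 1 - counts["class"]


def partial_eta_sq(F: float, df_num: int, df_den: int,
                   level: float = 0.95) -> tuple[float, float, float]:
    """Partial eta squared with a noncentral-F confidence interval.

    eta2p = F*df_num / (F*df_num + df_den).  The CI inverts the noncentral-F
    CDF for the noncentrality parameter at the two-sided ``level`` (default
    95%) and maps bounds through lambda / (lambda + df_num + df_den + 1).
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    value = F * df_num / (F * df_num + df_den)
    alpha = 1.0 - level

    def eta_of(nc):
        return nc / (nc + df_num + df_den + 1)

    def cdf(nc):
        return stats.ncf.cdf(F, df_num, df_den, nc)

    # upper bound: cdf decreasing in nc
    if cdf(0.0) <= alpha / 2:
        hi = 0.0
    else:
        ub = 10.0
        while cdf(ub) > alpha / 2 and ub < 1e7:
            ub *= 2
        hi = optimize.brentq(lambda nc: cdf(nc) - alpha / 2, 0.0, ub)
    if cdf(0.0) <= 1 - alpha / 2:
        lo = 0.0
    else:
        ub = 10.0
        while cdf(ub) > 1 - alpha / 2 and ub < 1e7:
            ub *= 2
        lo = optimize.brentq(lambda nc: cdf(nc) - (1 - alpha / 2), 0.0, ub)
    return float(value), float(eta_of(lo)), float(eta_of(hi))


def cohens_d_from_t(t: float, df: int) -> float:
    """Cohen's d from a model t statistic: d = 2t / sqrt(df).

    Standardizes against the total multilevel variance pooled across levels.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    return 2.0 * t / np.sqrt(df)


@dataclass
class WaldTest:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq_p: float
    eta_ci_low: float
    eta_ci_high: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("term", "F", "df_num", "df_den", "p",
                 "eta_sq_p", "eta_ci_low", "eta_ci_high")}


def type3_wald(fit: FitResult, term: str) -> WaldTest:
    """Type III Wald F test of a sum-coded term with containment df."""
    cols = fit.bundle.term_cols.get(term)
    if cols is None:
        raise ValueError(f"term {term!r} is not in the fitted model")
    b = fit.beta[cols]
    C = fit.cov_beta[np.ix_(cols, cols)]
    q = len(cols)
    if np.linalg.cond(C) > 1e12:
        raise np.linalg.LinAlgError("singular contrast covariance")
    F = float(b @ np.linalg.solve(C, b) / q)
    df_den = containment_df(fit.spec, fit.n_obs, fit.n_students,
                            fit.n_classes, term)
    p = float(stats.f.sf(F, q, df_den))
    eta, lo, hi = partial_eta_sq(F, q, df_den)
    return WaldTest(term, F, q, df_den, p, eta, lo, hi)


# ---------------------------------------------------------------------------
# marginal means and contrasts

def _cell_values(term: str, domain: str | None, sex: str | None) -> np.ndarray:
    vals = np.array([1.0])
    for p in term.split(":"):
        if p == "intercept":
            v = np.array([1.0])
        elif p == "domain":
            v = np.array(_DOMAIN_CODE[domain])
        elif p == "sex":
            v = np.array([_SEX_CODE[sex]])
        else:                       # covariates held at their (centered) mean
            v = np.array([0.0])
        vals = np.outer(vals, v).ravel()
    return vals


def design_row(fit: FitResult, domain: str | None = None,
               sex: str | None = None) -> np.ndarray:
    """X row for a factor cell, averaging over unspecified factors and
    holding covariates at their centered means (i.e. zero)."""
    domains = DOMAINS if domain is None else (domain,)
    sexes = tuple(_SEX_CODE) if sex is None else (sex,)
    rows = []
    for d in domains:
        for s in sexes:
            row = np.zeros(fit.bundle.p)
            for term, cols in fit.bundle.term_cols.items():
                row[cols] = _cell_values(term, d, s)
            rows.append(row)
    return np.mean(rows, axis=0)


def emmeans(fit: FitResult, by: tuple[str, ...] = ("domain",)) -> pd.DataFrame:
    """Estimated marginal means over a factor grid.

    ``by`` may contain ``"domain"`` and/or ``"sex"``; omitted factors are
    averaged over with equal weights, covariates sit at their means.
    """
    for f_ in by:
        if f_ not in ("domain", "sex"):
            raise ValueError(f"cannot build a grid over {f_!r}")
    grid_domain = DOMAINS if "domain" in by else (None,)
    grid_sex = tuple(_SEX_CODE) if "sex" in by else (None,)
    rows = []
    for d in grid_domain:
        for s in grid_sex:
            r = design_row(fit, d, s)
            rec = {"estimate": float(r @ fit.beta),
                   "se": float(np.sqrt(r @ fit.cov_beta @ r))}
            if d is not None:
                rec["domain"] = d
            if s is not None:
                rec["sex"] = s
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class ContrastResult:
    label: str
    estimate: float
    se: float
    t: float
    df: int
    p_raw: float
    d: float
    p_adj: float | None = None
    row: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("label", "estimate", "se", "t", "df", "p_raw", "p_adj", "d")}


def _contrast_df(fit: FitResult, cell_a: dict, cell_b: dict) -> int:
    if cell_a.get("domain") != cell_b.get("domain"):
        term = "domain"
    elif cell_a.get("sex") != cell_b.get("sex"):
        term = "sex"
    else:
        raise ValueError("contrast cells are identical")
    return containment_df(fit.spec, fit.n_obs, fit.n_students,
                          fit.n_classes, term)


def cell_contrast(fit: FitResult, cell_a: dict, cell_b: dict,
                  label: str | None = None) -> ContrastResult:
    """Difference between two factor cells (each a dict with optional
    ``domain``/``sex`` keys; missing factors are averaged over)."""
    ra = design_row(fit, cell_a.get("domain"), cell_a.get("sex"))
    rb = design_row(fit, cell_b.get("domain"), cell_b.get("sex"))
    row = ra - rb
    est = float(row @ fit.beta)
    se = float(np.sqrt(row @ fit.cov_beta @ row))
    df = _contrast_df(fit, cell_a, cell_b)
    t = est / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ContrastResult(label or f"{cell_a} - {cell_b}", est, se, t, df, p,
                          cohens_d_from_t(t, df), row=row)


def domain_pairwise(fit: FitResult, sex: str | None = None) -> list[ContrastResult]:
    """Pairwise domain contrasts, optionally within one sex."""
    pairs = [("balance", "aiming_catching"),
             ("balance", "manual_dexterity"),
             ("aiming_catching", "manual_dexterity")]
    out = []
    for a, b in pairs:
        lab = f"{a} - {b}" + (f" | {sex}" if sex else "")
        out.append(cell_contrast(fit, {"domain": a, "sex": sex},
                                 {"domain": b, "sex": sex}, lab))
    return out


def sex_within_domain(fit: FitResult) -> list[ContrastResult]:
    """boy - girl within each domain, at mean age."""
    return [cell_contrast(fit, {"domain": d, "sex": "boy"},
                          {"domain": d, "sex": "girl"}, f"boy - girl | {d}")
            for d in DOMAINS]


def contrast_correlation(fit: FitResult,
                         contrasts: list[ContrastResult]) -> np.ndarray:
    """Correlation matrix of the contrast estimates under the fitted model."""
    L = np.array([c.row for c in contrasts])
    C = L @ fit.cov_beta @ L.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def adjust_contrasts(contrasts: list[ContrastResult], corr: np.ndarray,
                     method: str = "westfall", n_draws: int = 100_000,
                     seed: int = 0) -> list[ContrastResult]:
    """Familywise-adjusted p values for a family of contrasts.

    ``westfall``: single-step max-|t| under the joint multivariate t (Monte
    Carlo with ``n_draws`` seeded draws) combined with free step-down
    refinement; monotonicity (p_adj nondecreasing in rank, p_adj >= p_raw)
    is enforced.  ``bonferroni`` is available as a reference method.
    """
    k = len(contrasts)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError("correlation matrix does not match contrast count")
    if np.min(np.linalg.eigvalsh((corr + corr.T) / 2)) < -1e-8:
        raise ValueError("contrast correlation matrix is not PSD")
    if k == 1:
        contrasts[0].p_adj = contrasts[0].p_raw
        return contrasts
    if method == "bonferroni":
        for c in contrasts:
            c.p_adj = min(1.0, k * c.p_raw)
        return contrasts
    if method != "westfall":
        raise ValueError(f"unknown adjustment method {method!r}")

    df = min(c.df for c in contrasts)
    rng = np.random.default_rng(seed)
    jitter = 1e-10 * np.eye(k)
    Lchol = np.linalg.cholesky(corr + jitter)
    Z = rng.standard_normal((n_draws, k)) @ Lchol.T
    scale = np.sqrt(rng.chisquare(df, n_draws) / df)
    T = np.abs(Z / scale[:, None])

    order = np.argsort([-abs(c.t) for c in contrasts])
    p_adj = np.empty(k)
    running_max = 0.0
    for rank, idx in enumerate(order):
        remaining = order[rank:]
        tail = float(np.mean(T[:, remaining].max(axis=1)
                             >= abs(contrasts[idx].t)))
        running_max = max(running_max, tail)        # step-down monotonicity
        p_adj[idx] = max(running_max, contrasts[idx].p_raw)
    for c, p in zip(contrasts, p_adj):
        c.p_adj = float(min(p, 1.0))
    return contrasts


# ---------------------------------------------------------------------------
# variance accounting

def _row_z(fit: FitResult) -> np.ndarray:
    dom_idx = fit.bundle.df["domain"].map(
        {d: i for i, d in enumerate(DOMAINS)}).to_numpy()
    return Z_DOMAIN[dom_idx]


def r2_nakagawa(fit: FitResult) -> tuple[float, float]:
    """(marginal, conditional) R2 with the random-slope extension.

    The random-effect variance is averaged over observations as
    z' Sigma z with the per-observation random design z.
    """
    var_fixed = float(np.var(fit.bundle.X @ fit.beta))
    Z = _row_z(fit)
    if fit.sigma_class is None:
        var_class = 0.0
    elif fit.sigma_class.shape == (1, 1):
        var_class = float(fit.sigma_class[0, 0])
    else:
        var_class = float(np.mean(np.einsum("ni,ij,nj->n", Z,
                                            fit.sigma_class, Z)))
    var_student = float(np.mean(np.einsum("ni,ij,nj->n", Z,
                                          fit.sigma_student, Z)))
    var_school = fit.sigma_school or 0.0
    denom = var_fixed + var_class + var_student + var_school + fit.sigma_resid ** 2
    return (var_fixed / denom,
            (var_fixed + var_class + var_student + var_school) / denom)


def pseudo_r2_from_lrt(lrt_stat: float, n_obs: int,
                       loglik_null: float | None = None) -> dict:
    """Cox-Snell pseudo-R2 1 - exp(-LRT/n); Nagelkerke normalization when
    the null log-likelihood is supplied."""
    if lrt_stat < 0:
        raise ValueError("LRT statistic must be non-negative")
    cs = 1.0 - np.exp(-lrt_stat / n_obs)
    out = {"cox_snell": float(cs)}
    if loglik_null is not None:
        denom = 1.0 - np.exp(2.0 * loglik_null / n_obs)
        out["nagelkerke"] = float(cs / denom) if denom > 0 else np.nan
    return out


def pseudo_r2(loglik_full: float, loglik_null: float, n_obs: int) -> dict:
    """Pseudo-R2 of the fixed effects against a null model sharing the same
    random structure (both fitted by ML)."""
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("full model log-likelihood below the null model's")
    stat = max(2.0 * (loglik_full - loglik_null), 0.0)
    return pseudo_r2_from_lrt(stat, n_obs, loglik_null)


@dataclass
class VarianceDecomposition:
    shares: dict
    vpc_grand_mean: float
    corr_class: np.ndarray
    corr_student: np.ndarray

    def to_dict(self) -> dict:
        return {"shares": {k: float(v) for k, v in self.shares.items()},
                "vpc_grand_mean": float(self.vpc_grand_mean),
                "corr_class": np.asarray(self.corr_class).tolist(),
                "corr_student": np.asarray(self.corr_student).tolist()}


def variance_decomposition(fit: FitResult) -> VarianceDecomposition:
    """Shares of total variance per random source plus the grand-mean VPC.

    Total variance is the sum of the six random-effect variances and the
    residual variance; the VPC at the grand mean uses intercept variances
    only.  Shares are invariant to rescaling the response.
    """
    if fit.sigma_class is None or fit.sigma_class.shape != (3, 3):
        raise ValueError("variance decomposition needs the full class-level "
                         "random structure")
    dc = np.diag(fit.sigma_class)
    ds = np.diag(fit.sigma_student)
    s2 = fit.sigma_resid ** 2
    total = dc.sum() + ds.sum() + s2
    shares = {
        "class_intercept": dc[0] / total, "class_ac_slope": dc[1] / total,
        "class_bal_slope": dc[2] / total,
        "student_intercept": ds[0] / total, "student_ac_slope": ds[1] / total,
        "student_bal_slope": ds[2] / total, "residual": s2 / total,
    }
    vpc = dc[0] / (dc[0] + ds[0] + s2)

    def to_corr(S):
        d = np.sqrt(np.clip(np.diag(S), 1e-300, None))
        return S / np.outer(d, d)

    return VarianceDecomposition(shares, float(vpc),
                                 to_corr(fit.sigma_class),
                                 to_corr(fit.sigma_student))


# ---------------------------------------------------------------------------
# empirical Bayes class profiles

def eb_estimates(fit: FitResult, crit: float = 1.96) -> pd.DataFrame:
    """BLUPs of the class-level random effects with posterior SDs.

    For each class c, b_hat = Sigma_class Z_c' V_c^-1 (y_c - X_c beta_hat)
    with conditional covariance Sigma - Sigma Z' V^-1 Z Sigma.  A component
    is flagged significant when |blup| > crit * posterior SD; prediction
    intervals are blup +/- crit * posterior SD.  Rows are sorted by the
    intercept BLUP (caterpillar order).
    """
    if fit.sigma_class is None:
        raise ValueError("model has no class-level random structure")
    full = fit.sigma_class.shape == (3, 3)
    Sc = fit.sigma_class
    Ss = fit.sigma_student
    s2 = fit.sigma_resid ** 2
    S_stu = Z_DOMAIN @ Ss @ Z_DOMAIN.T
    resid = fit.bundle.y - fit.bundle.X @ fit.beta
    df = fit.bundle.df
    codes = df["class_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    bounds = np.r_[starts, len(df)]
    comp_names = (["intercept", "ac_slope", "bal_slope"] if full
                  else ["intercept"])
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = (e - s) // 3
        Zc = np.tile(Z_DOMAIN, (m, 1)) if full else np.ones((3 * m, 1))
        V = (Zc @ Sc @ Zc.T + np.kron(np.eye(m), S_stu)
             + s2 * np.eye(3 * m))
        W = Sc @ Zc.T @ np.linalg.inv(V)
        blup = W @ resid[s:e]
        post = Sc - W @ Zc @ Sc
        post_sd = np.sqrt(np.clip(np.diag(post), 0.0, None))
        rec = {"class_id": codes[s], "n_students": m}
        for i, name in enumerate(comp_names):
            rec[f"{name}_blup"] = float(blup[i])
            rec[f"{name}_post_sd"] = float(post_sd[i])
            rec[f"{name}_significant"] = bool(abs(blup[i]) > crit * post_sd[i])
            rec[f"{name}_pi_low"] = float(blup[i] - crit * post_sd[i])
            rec[f"{name}_pi_high"] = float(blup[i] + crit * post_sd[i])
        rows.append(rec)
    out = pd.DataFrame(rows).sort_values("intercept_blup").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# diagnostics

def conditional_residuals(fit: FitResult, standardize: bool = True) -> np.ndarray:
    """Estimated observation-level errors e = sigma^2 V^-1 (y - X beta).

    Unlike marginal residuals these do not carry the random effects, so
    after studentizing by their model-implied SDs (Var(e) = sigma^4 V^-1)
    they are homoscedastic under the fitted model even though the random
    slopes make the marginal variance domain-dependent.
    """
    resid = fit.bundle.y - fit.bundle.X @ fit.beta
    out = np.empty_like(resid)
    s2 = fit.sigma_resid ** 2
    S_stu = Z_DOMAIN @ fit.sigma_student @ Z_DOMAIN.T
    Sc = fit.sigma_class
    df = fit.bundle.df
    codes = df["class_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    bounds = np.r_[starts, len(df)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        m = (e - s) // 3
        V = np.kron(np.eye(m), S_stu) + s2 * np.eye(3 * m)
        if Sc is not None:
            Zc = (np.tile(Z_DOMAIN, (m, 1)) if Sc.shape == (3, 3)
                  else np.ones((3 * m, 1)))
            V += Zc @ Sc @ Zc.T
        Vi = np.linalg.inv(V)
        e_blk = s2 * (Vi @ resid[s:e])
        if standardize:
            sd = s2 * np.sqrt(np.clip(np.diag(Vi), 1e-300, None))
            e_blk = e_blk / sd
        out[s:e] = e_blk
    return out


def diagnostics(fit: FitResult) -> dict:
    """Breusch-Pagan homoscedasticity p value on conditional residuals and
    generalized VIFs per fixed term (with the gVIF^(1/(2 df)) rescaling)."""
    from statsmodels.stats.diagnostic import het_breuschpagan

    resid = conditional_residuals(fit)
    X = fit.bundle.X
    has_const = "intercept" in fit.bundle.term_cols
    exog = X if has_const else np.column_stack([np.ones(len(X)), X])
    lm, lm_p, _, _ = het_breuschpagan(resid, exog)

    gvif = {}
    noncon = [t for t in fit.bundle.term_cols if t != "intercept"]
    cols = [c for t in noncon for c in fit.bundle.term_cols[t]]
    Xi = X[:, cols]
    R = np.corrcoef(Xi, rowvar=False)
    if R.ndim == 0:
        R = np.array([[1.0]])
    det_all = np.linalg.det(R)
    pos = 0
    spans = {}
    for t in noncon:
        w = len(fit.bundle.term_cols[t])
        spans[t] = list(range(pos, pos + w))
        pos += w
    for t in noncon:
        own = spans[t]
        rest = [i for i in range(Xi.shape[1]) if i not in own]
        d1 = np.linalg.det(R[np.ix_(own, own)])
        d2 = np.linalg.det(R[np.ix_(rest, rest)]) if rest else 1.0
        g = d1 * d2 / det_all
        gvif[t] = {"gvif": float(g),
                   "gvif_scaled": float(g ** (1.0 / (2 * len(own))))}
    return {"breusch_pagan_lm": float(lm), "breusch_pagan_p": float(lm_p),
            "gvif": gvif}
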