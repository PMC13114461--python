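"""Two-level linear mixed model engine (REML/ML, Log-Cholesky).

The model for the standard score of student *s* in class *c* on domain row
*i* is

    y = X beta + Z b_c + Z b_s + eps

with a 3x3 general positive-definite covariance at each level over the
random-effect design z = (1, 1[aiming_catching], 1[balance]) (manual
dexterity as reference; any reference choice yields the same marginal
covariance), iid residual noise, and an optional school-level random
intercept on top.  Covariances are parametrized by the Log-Cholesky scheme
(lower Cholesky factor with log-transformed diagonal), scaled relative to
the residual variance; both beta and sigma^2 are profiled out of the
likelihood, so the optimizer only sees the (at most 13) covariance
parameters.

The marginal likelihood factorizes over classes (schools, when a
school-level intercept is present), and every class of the same size shares
the same marginal covariance block, so each likelihood evaluation needs one
Cholesky factorization per distinct class size.

REML uses the Harville error-contrast form, which includes the
+log|X'X|/2 term and is therefore invariant to invertible reparametrization
of the fixed-effect design; packages that omit the term differ from it by a
data-independent additive constant, which cancels from likelihood-ratio
statistics and information-criterion differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .cohort import Z_DOMAIN
from .scores import DOMAINS, validate_scores

_SEX_CODE = {"boy": 1.0, "girl": -1.0}

#: sum-coded domain columns (last level, balance, carries the -1 row)
_DOMAIN_CODE = {
    "manual_dexterity": (1.0, 0.0),
    "aiming_catching": (0.0, 1.0),
    "balance": (-1.0, -1.0),
}

KNOWN_TERMS = (
    "intercept", "domain", "sex", "domain:sex", "age_c", "age_within",
    "age_between", "domain:age_within", "domain:age_c", "age_c:sex",
    "domain:age_c:sex",
)


class DesignError(ValueError):
    """Raised for invalid model specifications or rank-deficient designs."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed terms and random structure of a candidate model.

    ``fixed`` is an ordered tuple of term names from :data:`KNOWN_TERMS`
    (factors are sum-coded to support Type III inference).  ``class_re`` is
    one of ``"none"``, ``"intercept"``, ``"full"`` (intercept + domain
    slopes); the student level always carries the full intercept + domain
    structure.  ``school_re`` adds a school-level random intercept.
    """
    fixed: tuple[str, ...]
    class_re: str = "full"
    school_re: bool = False

    def __post_init__(self):
        for t in self.fixed:
            if t not in KNOWN_TERMS:
                raise DesignError(f"unknown fixed term {t!r}")
        if self.class_re not in ("none", "intercept", "full"):
            raise DesignError(f"unknown class random structure {self.class_re!r}")
        for t in self.fixed:
            parts = t.split(":")
            if len(parts) > 1:
                for p in parts:
                    if p not in self.fixed:
                        raise DesignError(
                            f"interaction {t!r} requires its margin {p!r}")

    @property
    def n_theta(self) -> int:
        n = {"none": 0, "intercept": 1, "full": 6}[self.class_re] + 6
        return n + (1 if self.school_re else 0)


def final_model_spec(**kw) -> ModelSpec:
    """The parsimonious model: domain, sex, domain x sex, decomposed age."""
    return ModelSpec(fixed=("intercept", "domain", "sex", "domain:sex",
                            "age_within", "age_between"), **kw)


def _base_columns(term: str, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    if term == "intercept":
        return np.ones((n, 1)), ["intercept"]
    if term == "domain":
        cols = np.array([_DOMAIN_CODE[d] for d in df["domain"]])
        return cols, ["domain[manual_dexterity]", "domain[aiming_catching]"]
    if term == "sex":
        return df["sex"].map(_SEX_CODE).to_numpy()[:, None], ["sex[boy]"]
    if term == "age_c":
        a = df["age_years"].to_numpy(dtype=float)
        return (a - a.mean())[:, None], ["age_c"]
    if term == "age_within":
        return df["age_within"].to_numpy(dtype=float)[:, None], ["age_within"]
    if term == "age_between":
        a = df["age_between"].to_numpy(dtype=float)
        return (a - a.mean())[:, None], ["age_between"]
    raise DesignError(f"unknown base term {term!r}")


def _term_columns(term: str, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    parts = term.split(":")
    cols, labels = _base_columns(parts[0], df)
    for p in parts[1:]:
        c2, l2 = _base_columns(p, df)
        cols = np.einsum("ni,nj->nij", cols, c2).reshape(len(df), -1)
        labels = [f"{a}:{b}" for a in labels for b in l2]
    return cols, labels


@dataclass
class _Group:
    """Classes (or school blocks) sharing one marginal-covariance pattern."""
    pattern: tuple[int, ...]       # students per class within the block
    k: int                         # number of blocks with this pattern
    Yt: np.ndarray                 # (d, k) responses, one column per block
    Xflat: np.ndarray              # (d, k*p) designs, blocks side by side
    slices: list                   # row slices into the sorted table


@dataclass
class DesignBundle:
    """Prepared design for likelihood evaluation.

    Rows are sorted by school, class, child and canonical domain order, so
    every grouping block is a contiguous slice.
    """
    spec: ModelSpec
    df: pd.DataFrame
    X: np.ndarray
    y: np.ndarray
    labels: list[str]
    term_cols: dict[str, list[int]]
    groups: dict[tuple[int, ...], _Group]
    n_obs: int
    n_students: int
    n_classes: int
    n_schools: int
    logdet_xtx: float

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def set_y(self, y: np.ndarray) -> None:
        """Swap in a new response (same rows); used by the bootstrap."""
        y = np.asarray(y, dtype=float)
        if y.shape != self.y.shape:
            raise DesignError("replacement response has wrong length")
        self.y = y
        for g in self.groups.values():
            for j, sl in enumerate(g.slices):
                g.Yt[:, j] = y[sl]


def build_design(spec: ModelSpec, table: pd.DataFrame) -> DesignBundle:
    """Construct the fixed design X, grouping blocks and response vector."""
    df = validate_scores(table)
    needs_age = {"age_within", "age_between"} & set(spec.fixed)
    if needs_age and not {"age_within", "age_between"} <= set(df.columns):
        raise DesignError("spec uses decomposed age; run decompose_age first")

    blocks_X, labels, term_cols = [], [], {}
    for term in spec.fixed:
        cols, ls = _term_columns(term, df)
        term_cols[term] = list(range(len(labels), len(labels) + len(ls)))
        labels.extend(ls)
        blocks_X.append(cols)
    X = np.hstack(blocks_X)
    y = df["standard_score"].to_numpy(dtype=float)

    # rank check with column attribution via pivoted QR
    r_diag = np.abs(np.diag(linalg.qr(X, mode="r", pivoting=True)[0]))
    if r_diag.size and (r_diag.min() < 1e-8 * max(r_diag.max(), 1.0)):
        piv = linalg.qr(X, mode="r", pivoting=True)[1]
        rank = int((r_diag > 1e-8 * r_diag.max()).sum())
        aliased = [labels[j] for j in piv[rank:]]
        raise DesignError(f"rank-deficient fixed design; aliased columns: {aliased}")

    # contiguous class slices (3 rows per child, canonical domain order)
    class_slices: dict[str, slice] = {}
    school_classes: dict[str, list[str]] = {}
    codes = df["class_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    bounds = np.r_[starts, len(df)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        cid = codes[s]
        class_slices[cid] = slice(int(s), int(e))
        school_classes.setdefault(df["school_id"].iloc[s], []).append(cid)

    if spec.school_re:
        block_defs = [(tuple((class_slices[c].stop - class_slices[c].start) // 3
                             for c in cl),
                       slice(class_slices[cl[0]].start, class_slices[cl[-1]].stop))
                      for cl in school_classes.values()]
    else:
        block_defs = [((int((sl.stop - sl.start) // 3),), sl)
                      for sl in class_slices.values()]

    grouped: dict[tuple[int, ...], list[slice]] = {}
    for pattern, sl in block_defs:
        grouped.setdefault(pattern, []).append(sl)
    groups = {}
    for pattern, slices in grouped.items():
        d = 3 * sum(pattern)
        k = len(slices)
        Yt = np.empty((d, k))
        Xs = np.empty((d, k, X.shape[1]))
        for j, sl in enumerate(slices):
            Yt[:, j] = y[sl]
            Xs[:, j, :] = X[sl]
        groups[pattern] = _Group(pattern, k, Yt, Xs.reshape(d, -1), slices)

    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    return DesignBundle(
        spec=spec, df=df, X=X, y=y, labels=labels, term_cols=term_cols,
        groups=groups, n_obs=len(df), n_students=df["child_id"].nunique(),
        n_classes=df["class_id"].nunique(), n_schools=df["school_id"].nunique(),
        logdet_xtx=float(logdet_xtx),
    )


# ---------------------------------------------------------------------------
# Log-Cholesky parametrization (covariances relative to sigma^2)

_TRIL = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
_DIAG_POS = (0, 2, 5)


def unpack_chol(theta6: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor from a 6-vector with log-scale diagonal."""
    L = np.zeros((3, 3))
    for val, (i, j) in zip(theta6, _TRIL):
        L[i, j] = np.exp(val) if i == j else val
    return L


def pack_chol(cov: np.ndarray) -> np.ndarray:
    """Inverse of :func:`unpack_chol` applied to ``L L^T``."""
    L = np.linalg.cholesky(cov)
    return np.array([np.log(L[i, j]) if i == j else L[i, j]
                     for (i, j) in _TRIL])


def _unpack_theta(theta: np.ndarray, spec: ModelSpec):
    """Split theta into (relative) class, student and school components."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_theta,):
        raise DesignError(f"theta must have length {spec.n_theta}")
    pos = 0
    if spec.class_re == "full":
        Lc = unpack_chol(theta[:6])
        lam_c = Lc @ Lc.T
        pos = 6
    elif spec.class_re == "intercept":
        lam_c = np.exp(2.0 * theta[0])     # relative variance
        pos = 1
    else:
        lam_c = None
    Ls = unpack_chol(theta[pos:pos + 6])
    lam_s = Ls @ Ls.T
    pos += 6
    school = np.exp(2.0 * theta[pos]) if spec.school_re else None
    return lam_c, lam_s, school


def _assemble_v0(pattern, lam_c, lam_s, school_var, class_re) -> np.ndarray:
    S = Z_DOMAIN @ lam_s @ Z_DOMAIN.T
    blocks = []
    for m in pattern:
        d = 3 * m
        V = np.kron(np.eye(m), S)
        if class_re == "full":
            Zc = np.tile(Z_DOMAIN, (m, 1))
            V += Zc @ lam_c @ Zc.T
        elif class_re == "intercept":
            V += lam_c
        V[np.diag_indices(d)] += 1.0
        blocks.append(V)
    V0 = blocks[0] if len(blocks) == 1 else linalg.block_diag(*blocks)
    if school_var is not None:
        V0 = V0 + school_var
    return V0


def _profile(theta: np.ndarray, bundle: DesignBundle):
    """Profiled GLS pieces at one covariance parameter value.

    Returns (logdet V0, X'V0^-1 X, X'V0^-1 y, y'V0^-1 y, beta, rss).
    """
    lam_c, lam_s, school = _unpack_theta(theta, bundle.spec)
    p = bundle.p
    logdet = 0.0
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    for pattern, g in bundle.groups.items():
        V0 = _assemble_v0(pattern, lam_c, lam_s, school, bundle.spec.class_re)
        L = np.linalg.cholesky(V0)
        logdet += g.k * 2.0 * np.sum(np.log(np.diag(L)))
        sol = linalg.solve_triangular(
            L, np.concatenate([g.Yt, g.Xflat], axis=1),
            lower=True, check_finite=False)
        Wy = sol[:, :g.k]
        Wx = sol[:, g.k:].reshape(L.shape[0], g.k, p)
        yty += float(np.sum(Wy * Wy))
        xty += np.einsum("dk,dkp->p", Wy, Wx)
        xtx += np.einsum("dkp,dkq->pq", Wx, Wx, optimize=True)
    cf = linalg.cho_factor(xtx, lower=True, check_finite=False)
    beta = linalg.cho_solve(cf, xty, check_finite=False)
    rss = max(yty - float(beta @ xty), 1e-300)
    logdet_xtvx = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return logdet, xtx, xty, yty, beta, rss, logdet_xtvx


def loglik(theta: np.ndarray, bundle: DesignBundle, method: str = "REML") -> float:
    """Profiled marginal log-likelihood (beta and sigma^2 concentrated out)."""
    n, p = bundle.n_obs, bundle.p
    logdet, _, _, _, _, rss, logdet_xtvx = _profile(theta, bundle)
    if method.upper() == "ML":
        s2 = rss / n
        return -0.5 * (n * (np.log(2 * np.pi) + 1.0 + np.log(s2)) + logdet)
    if method.upper() == "REML":
        s2 = rss / (n - p)
        return -0.5 * ((n - p) * (np.log(2 * np.pi) + 1.0 + np.log(s2))
                       + logdet + logdet_xtvx - bundle.logdet_xtx)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class FitResult:
    """Estimated two-level mixed model."""
    spec: ModelSpec
    method: str
    beta: np.ndarray
    labels: list[str]
    cov_beta: np.ndarray
    sigma_class: np.ndarray | None     # absolute 3x3 (or 1x1 for intercept-only)
    sigma_student: np.ndarray
    sigma_school: float | None         # absolute variance
    sigma_resid: float
    loglik: float
    n_params: int
    converged: bool
    n_obs: int
    n_students: int
    n_classes: int
    n_schools: int
    theta: np.ndarray
    bundle: DesignBundle = field(repr=False)
    optim_message: str = ""

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def to_dict(self) -> dict:
        return {
            "fixed": list(self.spec.fixed), "class_re": self.spec.class_re,
            "school_re": self.spec.school_re, "method": self.method,
            "beta": dict(zip(self.labels, np.asarray(self.beta, dtype=float))),
            "se": dict(zip(self.labels, self.se().astype(float))),
            "sigma_class": None if self.sigma_class is None
                           else np.asarray(self.sigma_class).tolist(),
            "sigma_student": np.asarray(self.sigma_student).tolist(),
            "sigma_school": self.sigma_school,
            "sigma_resid": float(self.sigma_resid),
            "loglik": float(self.loglik), "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "n_obs": self.n_obs, "n_students": self.n_students,
            "n_classes": self.n_classes, "n_schools": self.n_schools,
            "theta": np.asarray(self.theta, dtype=float).tolist(),
        }


def _moment_start(bundle: DesignBundle) -> np.ndarray:
    """Moment-based starting point: crude variance-component guesses from
    OLS residuals, zero correlations."""
    X, y = bundle.X, bundle.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    df = bundle.df
    tot = max(np.var(r), 1e-8)
    by_student = pd.Series(r).groupby(df["child_id"].to_numpy()).mean()
    by_class = pd.Series(r).groupby(df["class_id"].to_numpy()).mean()
    v_stu = np.clip(np.var(by_student.to_numpy()), 1e-4 * tot, None)
    v_cls = np.clip(np.var(by_class.to_numpy()), 1e-4 * tot, None)
    s2 = max(tot - v_stu - v_cls, 0.05 * tot)
    log_sd_s = 0.5 * np.log(v_stu / s2)
    log_sd_c = 0.5 * np.log(v_cls / s2)
    theta = []
    if bundle.spec.class_re == "full":
        theta += [log_sd_c, 0.0, log_sd_c - 0.5, 0.0, 0.0, log_sd_c - 0.5]
    elif bundle.spec.class_re == "intercept":
        theta += [log_sd_c]
    theta += [log_sd_s, 0.0, log_sd_s - 0.5, 0.0, 0.0, log_sd_s - 0.5]
    if bundle.spec.school_re:
        theta += [log_sd_c - 1.0]
    return np.clip(np.array(theta), -4.0, 4.0)


def fit(spec: ModelSpec, table: pd.DataFrame, method: str = "REML",
        start_theta: np.ndarray | None = None, n_starts: int = 3,
        seed: int = 0, bundle: DesignBundle | None = None) -> FitResult:
    """Fit the model by quasi-Newton maximization of the profiled likelihood.

    Three documented starting points are tried by default (a moment-based
    guess from OLS residuals; zeros, i.e. unit relative covariances; the
    moment guess perturbed); ``n_starts=1`` keeps only the moment start,
    the policy used inside simulation loops.  ``start_theta`` replaces them
    with a single warm start.  Non-convergence is flagged on the result,
    never silent.
    """
    if bundle is None:
        bundle = build_design(spec, table)
    if spec.class_re != "none" and bundle.n_classes < 2:
        raise DesignError("class-level random structure needs >= 2 classes")
    n, p = bundle.n_obs, bundle.p

    if start_theta is not None:
        starts = [np.asarray(start_theta, dtype=float)]
    else:
        rng = np.random.default_rng(seed)
        m0 = _moment_start(bundle)
        starts = [m0, np.zeros(spec.n_theta),
                  m0 + 0.25 * rng.standard_normal(spec.n_theta)][:max(n_starts, 1)]

    def nll(th):
        try:
            return -loglik(th, bundle, method)
        except np.linalg.LinAlgError:
            return 1e12

    lo = np.full(spec.n_theta, -30.0)
    hi = np.full(spec.n_theta, 30.0)
    is_diag = _diag_mask(spec)
    lo[is_diag], hi[is_diag] = -8.0, 8.0
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"ftol": 1e-12, "gtol": 1e-6,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll = -best.fun
    converged = bool(best.success) and np.isfinite(ll)

    logdet, xtx, xty, yty, beta, rss, _ = _profile(theta, bundle)
    s2 = rss / (n - p) if method.upper() == "REML" else rss / n
    cov_beta = s2 * linalg.cho_solve(
        linalg.cho_factor(xtx, lower=True, check_finite=False),
        np.eye(p), check_finite=False)
    lam_c, lam_s, school = _unpack_theta(theta, spec)
    if spec.class_re == "full":
        sigma_class = s2 * lam_c
    elif spec.class_re == "intercept":
        sigma_class = s2 * np.array([[lam_c]])
    else:
        sigma_class = None
    return FitResult(
        spec=spec, method=method.upper(), beta=beta, labels=bundle.labels,
        cov_beta=cov_beta, sigma_class=sigma_class,
        sigma_student=s2 * lam_s,
        sigma_school=None if school is None else float(s2 * school),
        sigma_resid=float(np.sqrt(s2)), loglik=float(ll),
        n_params=p + spec.n_theta + 1, converged=converged,
        n_obs=n, n_students=bundle.n_students, n_classes=bundle.n_classes,
        n_schools=bundle.n_schools, theta=theta, bundle=bundle,
        optim_message=str(best.message),
    )


def _diag_mask(spec: ModelSpec) -> np.ndarray:
    mask = []
    if spec.class_re == "full":
        mask += [i in _DIAG_POS for i in range(6)]
    elif spec.class_re == "intercept":
        mask += [True]
    mask += [i in _DIAG_POS for i in range(6)]
    if spec.school_re:
        mask += [True]
    return np.array(mask)


def lrt(fit_restricted: FitResult, fit_full: FitResult):
    """Likelihood-ratio test of nested fits: (statistic, df, p).

    Model selection uses ML refits; REML fits are only comparable when the
    fixed designs coincide (random-structure tests), otherwise an error is
    raised.
    """
    if fit_restricted.method != fit_full.method:
        raise ValueError("cannot compare fits with different estimation methods")
    if fit_restricted.method == "REML" and \
            fit_restricted.labels != fit_full.labels:
        raise ValueError("REML likelihoods are not comparable across "
                         "different fixed designs; refit with ML")
    if fit_restricted.n_obs != fit_full.n_obs:
        raise ValueError("fits use different data")
    df = fit_full.n_params - fit_restricted.n_params
    if df < 0:
        raise ValueError("restricted model has more parameters than full")
    stat = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    p = 1.0 if df == 0 else float(stats.chi2.sf(max(stat, 0.0), df))
    return float(stat), int(df), p


def information_criteria(loglik_value: float, n_params: int, n_obs: int):
    """(AIC, BIC) from a log-likelihood and its parameter count."""
    aic = -2.0 * loglik_value + 2.0 * n_params
    bic = -2.0 * loglik_value + n_params * np.log(n_obs)
    return float(aic), float(bic)


def information_criteria_fit(f: FitResult):
    if not f.converged:
        raise ValueError("information criteria require a converged fit")
    return information_criteria(f.loglik, f.n_params, f.n_obs)
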