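"""Parametric-bootstrap power curves, MDES interpolation and Type-M flags.

For each candidate coefficient value of a fixed term, new responses are
simulated from the fitted model (class- and student-level random effects
drawn from their estimated 3x3 multivariate normals, residual noise added,
the term's coefficient replaced by the candidate value), the model is refit
and the Type III test recorded.  The rejection proportion over iterations
traces a power curve; the minimum detectable effect size at the target power
(default 80%) is linearly interpolated between the bracketing grid points,
on both the coefficient scale and the partial-eta-squared scale (median over
significant iterations).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .cohort import Z_DOMAIN
from .lmm import DesignBundle, FitResult, fit as fit_model
from .inference import WaldTest, containment_df, partial_eta_sq, type3_wald
from .scores import DOMAINS


def _beta_with_override(fit: FitResult, term: str, value) -> np.ndarray:
    cols = fit.bundle.term_cols.get(term)
    if cols is None:
        raise ValueError(f"term {term!r} is not in the fitted model")
    beta = fit.beta.copy()
    value = np.atleast_1d(np.asarray(value, dtype=float))
    if value.size == len(cols):
        beta[cols] = value
    elif value.size == 1:
        if len(cols) == 1:
            beta[cols] = value[0]
        else:
            ref = fit.beta[cols]
            norm = np.linalg.norm(ref)
            if norm == 0:
                raise ValueError(
                    f"scalar override of multi-column term {term!r} needs a "
                    "nonzero fitted coefficient to define a direction")
            beta[cols] = value[0] * ref / norm
    else:
        raise ValueError(f"override has wrong length for term {term!r}")
    return beta


def simulate_response(fit: FitResult, term: str | None = None,
                      override=None, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate a response vector on the fitted design.

    All parameters come from the fit except the named term's coefficient,
    which is replaced by ``override`` (a scalar for single-column terms; for
    multi-column terms either a vector or a scalar magnitude applied along
    the fitted coefficient direction).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    beta = fit.beta if term is None else _beta_with_override(fit, term, override)
    bundle = fit.bundle
    y = bundle.X @ beta
    df = bundle.df
    dom_idx = df["domain"].map({d: i for i, d in enumerate(DOMAINS)}).to_numpy()
    Zrows = Z_DOMAIN[dom_idx]

    if fit.sigma_school:
        codes = df["school_id"].to_numpy()
        _, inv = np.unique(codes, return_inverse=True)
        b = rng.normal(0.0, np.sqrt(fit.sigma_school), inv.max() + 1)
        y = y + b[inv]
    if fit.sigma_class is not None:
        codes = df["class_id"].to_numpy()
        uniq, inv = np.unique(codes, return_inverse=True)
        if fit.sigma_class.shape == (3, 3):
            b = rng.multivariate_normal(np.zeros(3), fit.sigma_class,
                                        size=len(uniq), method="eigh")
            y = y + np.einsum("ni,ni->n", Zrows, b[inv])
        else:
            b = rng.normal(0.0, np.sqrt(fit.sigma_class[0, 0]), len(uniq))
            y = y + b[inv]
    codes = df["child_id"].to_numpy()
    uniq, inv = np.unique(codes, return_inverse=True)
    b = rng.multivariate_normal(np.zeros(3), fit.sigma_student,
                                size=len(uniq), method="eigh")
    y = y + np.einsum("ni,ni->n", Zrows, b[inv])
    return y + rng.normal(0.0, fit.sigma_resid, len(y))


def _clone_bundle(bundle: DesignBundle) -> DesignBundle:
    clone = copy.copy(bundle)
    clone.y = bundle.y.copy()
    clone.groups = {k: copy.copy(g) for k, g in bundle.groups.items()}
    for g in clone.groups.values():
        g.Yt = g.Yt.copy()
    return clone


@dataclass
class PowerCurve:
    term: str
    grid: np.ndarray
    n_iter: int
    alpha: float
    seed: int
    power: np.ndarray                    # rejection proportion per grid point
    median_sig_eta: np.ndarray           # median eta2p among significant iters
    n_failed: np.ndarray                 # refits excluded per grid point
    pvalues: list = field(repr=False, default_factory=list)
    etas: list = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {"term": self.term, "grid": self.grid.tolist(),
                "n_iter": self.n_iter, "alpha": self.alpha, "seed": self.seed,
                "power": self.power.tolist(),
                "median_sig_eta": self.median_sig_eta.tolist(),
                "n_failed": self.n_failed.tolist(),
                "pvalues": [list(map(float, p)) for p in self.pvalues],
                "etas": [list(map(float, e)) for e in self.etas]}


def power_curve(fit: FitResult, term: str, grid, n_iter: int = 200,
                alpha: float = 0.05, seed: int = 0,
                method: str = "REML") -> PowerCurve:
    """Simulate -> refit -> test cycles across an effect-size grid.

    Refit failures are excluded with a logged count; a grid point where all
    refits fail raises.  Refits warm-start at the reference fit's covariance
    parameters (the generating values), a single start.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("effect grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("effect grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    sim_bundle = _clone_bundle(fit.bundle)
    power = np.empty(len(grid))
    med_eta = np.full(len(grid), np.nan)
    failed = np.zeros(len(grid), dtype=int)
    all_p, all_eta = [], []
    for gi, coef in enumerate(grid):
        pvals, etas = [], []
        for _ in range(n_iter):
            y = simulate_response(fit, term, coef, rng=rng)
            sim_bundle.set_y(y)
            try:
                f = fit_model(fit.spec, None, method=method,
                              start_theta=fit.theta, bundle=sim_bundle)
            except Exception:
                failed[gi] += 1
                continue
            if not f.converged:
                failed[gi] += 1
                continue
            w = type3_wald(f, term)
            pvals.append(w.p)
            etas.append(w.eta_sq_p)
        if not pvals:
            raise RuntimeError(f"all refits failed at grid point {coef}")
        pvals = np.array(pvals)
        etas = np.array(etas)
        power[gi] = float(np.mean(pvals < alpha))
        sig = etas[pvals < alpha]
        if sig.size:
            med_eta[gi] = float(np.median(sig))
        all_p.append(pvals)
        all_eta.append(etas)
    return PowerCurve(term, grid, n_iter, alpha, seed, power, med_eta,
                      failed, all_p, all_eta)


@dataclass
class MdesResult:
    term: str
    coefficient: float                   # coefficient at target power
    mdes_eta_sq_p: float
    power_target: float
    interpolation: dict

    def to_dict(self) -> dict:
        return {"term": self.term, "coefficient": self.coefficient,
                "mdes_eta_sq_p": self.mdes_eta_sq_p,
                "power_target": self.power_target,
                "interpolation": self.interpolation}


def mdes(curve: PowerCurve, target: float = 0.80) -> MdesResult:
    """Minimum detectable effect size at the target power.

    If a grid point sits exactly at the target, its median significant
    eta2p is returned without interpolation; otherwise the coefficient and
    the median-significant-eta2p series are both linearly interpolated
    between the first pair of grid points bracketing the target.
    """
    pw = curve.power
    exact = np.flatnonzero(np.isclose(pw, target))
    if exact.size:
        i = int(exact[0])
        return MdesResult(curve.term, float(curve.grid[i]),
                          float(curve.median_sig_eta[i]), target,
                          {"kind": "exact_grid_point", "index": i})
    bracket = None
    for i in range(len(pw) - 1):
        lo, hi = sorted((pw[i], pw[i + 1]))
        if lo < target < hi:
            bracket = i
            break
    if bracket is None:
        raise ValueError(
            f"power curve does not bracket target {target}; extend the grid "
            f"(observed powers {pw.tolist()})")
    i = bracket
    w = (target - pw[i]) / (pw[i + 1] - pw[i])
    coef = float(curve.grid[i] + w * (curve.grid[i + 1] - curve.grid[i]))
    e0, e1 = curve.median_sig_eta[i], curve.median_sig_eta[i + 1]
    if np.isnan(e0):
        eta = float(e1)
    elif np.isnan(e1):
        eta = float(e0)
    else:
        eta = float(e0 + w * (e1 - e0))
    return MdesResult(curve.term, coef, eta, target,
                      {"kind": "linear", "bracket": [int(i), int(i + 1)],
                       "weight": float(w),
                       "bracket_power": [float(pw[i]), float(pw[i + 1])],
                       "bracket_eta": [float(e0), float(e1)]})


def type_m_flag(observed: WaldTest, mdes_result: MdesResult,
                alpha: float = 0.05) -> dict:
    """Flag a significant result whose observed eta2p falls below its MDES.

    Such effects are detectable only when overestimated, so their printed
    magnitude is likely biased upward (Type M error).
    """
    if observed.term != mdes_result.term:
        raise ValueError("observed test and MDES refer to different terms")
    significant = observed.p < alpha
    if observed.eta_sq_p == 0 and significant:
        raise ValueError("inconsistent inputs: significant test with zero "
                         "effect size")
    ratio = (np.inf if observed.eta_sq_p == 0
             else mdes_result.mdes_eta_sq_p / observed.eta_sq_p)
    return {"term": observed.term, "ratio": float(ratio),
            "flagged": bool(significant and ratio > 1.0),
            "observed_eta_sq_p": observed.eta_sq_p,
            "mdes_eta_sq_p": mdes_result.mdes_eta_sq_p,
            "significant": bool(significant)}


def default_grid(fit: FitResult, term: str, n_points: int = 12,
                 span_mult: float = 3.0) -> np.ndarray:
    """Default effect grid: 0 to span_mult x the observed coefficient
    magnitude (or 4 SE when the observed coefficient is negligible)."""
    cols = fit.bundle.term_cols[term]
    mag = float(np.linalg.norm(fit.beta[cols]))
    se = float(np.sqrt(np.mean(np.diag(fit.cov_beta)[cols])))
    upper = max(span_mult * mag, 4.0 * se)
    return np.linspace(0.0, upper, n_points)
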