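"""Synthetic cohorts from the two-level random-slope model.

Generates long-format score tables with the study layout (31 classes: 23 of
size 8 and 8 of size 16, balanced sexes, three domains per child) from

    y = X beta + Z b_class + Z b_student + eps,

with ``b_class ~ N(0, Sigma_class)`` and ``b_student ~ N(0, Sigma_student)``
(3x3 covariances over intercept, aiming-catching offset, balance offset, with
manual dexterity as the random-effect reference level) and iid residual noise
``eps ~ N(0, sigma^2)``.  The realized random-effect draws are returned as a
truth record so downstream estimators can be checked against them.

Default parameters reproduce the study-scale variance decomposition: with
residual SD sigma = 0.95 contributing 7.8% of total variance, total variance
is T = sigma^2 / 0.078 ~= 11.57, class-level shares (8.9, 7.9, 6.3)% and
student-level shares (25.4, 21.2, 22.4)%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .scores import DOMAINS

SEX_CYCLE = ("boy", "girl")

# random-effect design row per domain: (intercept, AC indicator, Bal indicator)
Z_DOMAIN = np.array([[1.0, 0.0, 0.0],   # manual_dexterity (reference)
                     [1.0, 1.0, 0.0],   # aiming_catching
                     [1.0, 0.0, 1.0]])  # balance


def _cov_from(sds, corr):
    sds = np.asarray(sds, dtype=float)
    return np.asarray(corr, dtype=float) * np.outer(sds, sds)


@dataclass
class CohortParams:
    """Generating truth for a synthetic cohort.

    ``beta`` holds the fixed effects in score units: grand intercept, domain
    offsets (sum to zero), the boy-vs-mean sex offset, domain x sex offsets
    (applied with sign +1 for boys, -1 for girls; sum to zero over domains),
    and the within-/between-class age slopes (score points per year).
    """
    n_classes_small: int = 23
    class_size_small: int = 8
    n_classes_large: int = 8
    class_size_large: int = 16
    n_schools: int = 14
    intercept: float = 9.8
    domain_offsets: dict = field(default_factory=lambda: {
        "manual_dexterity": -2.2, "aiming_catching": 0.8, "balance": 1.4})
    sex_offset: float = 0.05
    domain_sex_offsets: dict = field(default_factory=lambda: {
        "manual_dexterity": -0.25, "aiming_catching": 0.45, "balance": -0.2})
    beta_age_within: float = -0.495
    beta_age_between: float = 0.132
    sigma_class: np.ndarray = None
    sigma_student: np.ndarray = None
    sigma_resid: float = 0.95
    age_between_sd: float = 1.71
    age_within_sd: float = 0.5
    age_center: float = 9.0
    round_scores: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma_class", "sigma_student"):
            m = getattr(self, name)
            m = np.asarray(m, dtype=float)
            if m.shape != (3, 3) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric 3x3 matrix")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
            setattr(self, name, m)
        if self.sigma_resid < 0 or self.age_between_sd < 0 or self.age_within_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_classes_small + self.n_classes_large < 1:
            raise ValueError("need at least one class")

    @property
    def total_variance(self) -> float:
        """Sum of the six random-effect variances and the residual variance."""
        return float(np.trace(self.sigma_class) + np.trace(self.sigma_student)
                     + self.sigma_resid ** 2)

    @property
    def variance_shares(self) -> dict:
        """Generating shares of total variance, keyed like VarianceDecomposition."""
        t = self.total_variance
        dc = np.diag(self.sigma_class)
        ds = np.diag(self.sigma_student)
        return {
            "class_intercept": dc[0] / t, "class_ac_slope": dc[1] / t,
            "class_bal_slope": dc[2] / t,
            "student_intercept": ds[0] / t, "student_ac_slope": ds[1] / t,
            "student_bal_slope": ds[2] / t,
            "residual": self.sigma_resid ** 2 / t,
        }

    def mean_score(self, domain: str, sex: str, age_within: float,
                   age_between: float) -> float:
        """Fixed-effect prediction for one observation."""
        s = 1.0 if sex == "boy" else -1.0
        return (self.intercept + self.domain_offsets[domain]
                + s * self.sex_offset + s * self.domain_sex_offsets[domain]
                + self.beta_age_within * age_within
                + self.beta_age_between * (age_between - self.age_center))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sigma_class"] = np.asarray(self.sigma_class).tolist()
        d["sigma_student"] = np.asarray(self.sigma_student).tolist()
        return d


def default_params(seed: int = 0) -> CohortParams:
    """Study-scale defaults.

    Variance magnitudes are derived from the printed decomposition: residual
    share 7.8% with sigma = 0.95 gives total T = 0.95**2/0.078; level-wise
    variances are T times the printed shares.  Class-level correlations
    (intercept-AC 0.49, intercept-Bal 0.35, AC-Bal -0.26) and the student
    AC-Bal correlation (-0.58) are as reported; unreported student
    intercept-slope correlations default to 0.
    """
    sigma = 0.95
    total = sigma ** 2 / 0.078
    class_sds = np.sqrt(total * np.array([0.089, 0.079, 0.063]))
    student_sds = np.sqrt(total * np.array([0.254, 0.212, 0.224]))
    class_corr = np.array([[1.0, 0.49, 0.35],
                           [0.49, 1.0, -0.26],
                           [0.35, -0.26, 1.0]])
    student_corr = np.array([[1.0, 0.0, 0.0],
                             [0.0, 1.0, -0.58],
                             [0.0, -0.58, 1.0]])
    p = CohortParams(
        sigma_class=_cov_from(class_sds, class_corr),
        sigma_student=_cov_from(student_sds, student_corr),
        sigma_resid=sigma,
        seed=seed,
    )
    p.validate()
    return p


def _truncnorm(rng, loc, scale, low, high, size):
    if scale == 0:
        return np.full(size, loc)
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                               random_state=rng)


def generate_cohort(params: CohortParams,
                    seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort; returns (score table, truth record).

    The table has the columns ``read_scores`` expects plus the decomposed
    ages and a ``percentile`` column from the normal approximation.  The
    truth record holds the realized class- and student-level random-effect
    draws (DataFrames keyed by id) and the generating parameters.

    Sexes alternate within class (balanced to within one child); class mean
    ages are drawn around ``age_center`` with SD ``age_between_sd`` and child
    ages around the class mean with SD ``age_within_sd``, truncated to the
    eligible 6-12-year range.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    sizes = ([params.class_size_small] * params.n_classes_small
             + [params.class_size_large] * params.n_classes_large)
    n_classes = len(sizes)
    class_ids = [f"c{idx + 1:02d}" for idx in range(n_classes)]
    school_of = {cid: f"s{(idx % max(params.n_schools, 1)) + 1:02d}"
                 for idx, cid in enumerate(class_ids)}

    b_class = rng.multivariate_normal(np.zeros(3), params.sigma_class,
                                      size=n_classes, method="eigh")
    class_mean_age = _truncnorm(rng, params.age_center, params.age_between_sd,
                                6.5, 11.5, n_classes)

    n_students = int(np.sum(sizes))
    child_ids = np.array([f"ch{i + 1:04d}" for i in range(n_students)])
    class_of_child = np.repeat(np.arange(n_classes), sizes)
    sex_of_child = np.concatenate(
        [np.array(SEX_CYCLE * ((m + 1) // 2))[:m] for m in sizes])
    ages = np.concatenate(
        [np.round(_truncnorm(rng, class_mean_age[k], params.age_within_sd,
                             6.0, 12.0, m), 3) for k, m in enumerate(sizes)])
    b_students = rng.multivariate_normal(np.zeros(3), params.sigma_student,
                                         size=n_students, method="eigh")
    mean_age = np.array([ages[class_of_child == k].mean()
                         for k in range(n_classes)])

    # expand to one row per child x domain (canonical domain order)
    rep = np.repeat(np.arange(n_students), 3)
    dom_idx = np.tile(np.arange(3), n_students)
    dom_off = np.array([params.domain_offsets[d] for d in DOMAINS])
    dsx_off = np.array([params.domain_sex_offsets[d] for d in DOMAINS])
    sex_sign = np.where(sex_of_child == "boy", 1.0, -1.0)
    age_within = ages - mean_age[class_of_child]
    mu = (params.intercept + dom_off[dom_idx]
          + sex_sign[rep] * (params.sex_offset + dsx_off[dom_idx])
          + params.beta_age_within * age_within[rep]
          + params.beta_age_between * (mean_age[class_of_child][rep]
                                       - params.age_center))
    Zrows = Z_DOMAIN[dom_idx]
    y = (mu
         + np.einsum("ni,ni->n", Zrows, b_class[class_of_child][rep])
         + np.einsum("ni,ni->n", Zrows, b_students[rep])
         + rng.normal(0.0, params.sigma_resid, 3 * n_students))
    if params.round_scores:
        y = np.round(y)

    cls_arr = np.array(class_ids)[class_of_child]
    table = pd.DataFrame({
        "child_id": child_ids[rep],
        "class_id": cls_arr[rep],
        "school_id": np.array([school_of[c] for c in cls_arr])[rep],
        "sex": sex_of_child[rep],
        "age_years": ages[rep],
        "domain": np.array(DOMAINS)[dom_idx],
        "standard_score": y,
    })
    from .scores import ensure_percentile, decompose_age, validate_scores
    table = decompose_age(ensure_percentile(validate_scores(table)))

    truth = {
        "params": params,
        "class_effects": pd.DataFrame({
            "class_id": class_ids,
            "b_intercept": b_class[:, 0], "b_ac": b_class[:, 1],
            "b_bal": b_class[:, 2],
            "mean_age": class_mean_age,
        }),
        "student_effects": pd.DataFrame({
            "child_id": child_ids,
            "class_id": cls_arr,
            "b_intercept": b_students[:, 0], "b_ac": b_students[:, 1],
            "b_bal": b_students[:, 2],
        }),
    }
    return table, truth
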