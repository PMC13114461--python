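"""Engine correctness: design construction, likelihood, fitting, LRT, IC."""

import copy

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import motorprof as mp
from motorprof.lmm import (DesignError, _Group, build_design, loglik,
                           pack_chol, unpack_chol)
from _oracle import oracle_loglik
from conftest import small_params, true_theta


# ---------------------------------------------------------------------------
# design construction

def test_final_model_has_eight_fixed_columns(study_cohort):
    table, _ = study_cohort
    b = build_design(mp.final_model_spec(), table)
    assert b.X.shape == (936, 8)
    assert b.labels == [
        "intercept", "domain[manual_dexterity]", "domain[aiming_catching]",
        "sex[boy]", "domain[manual_dexterity]:sex[boy]",
        "domain[aiming_catching]:sex[boy]", "age_within", "age_between"]


def test_sum_coded_columns_sum_to_zero_on_balanced_table(study_cohort):
    table, _ = study_cohort
    b = build_design(mp.final_model_spec(), table)
    for term in ("domain",):
        for c in b.term_cols[term]:
            assert abs(b.X[:, c].sum()) < 1e-9


def test_rank_deficient_design_names_aliased_columns(study_cohort):
    table, _ = study_cohort
    # age_c is an exact linear combination of age_within + age_between
    spec = mp.ModelSpec(("intercept", "age_c", "age_within", "age_between"))
    with pytest.raises(DesignError, match="aliased"):
        build_design(spec, table)


def test_interaction_requires_margins():
    with pytest.raises(DesignError, match="margin"):
        mp.ModelSpec(("intercept", "domain:sex"))


# ---------------------------------------------------------------------------
# Log-Cholesky parametrization

@given(st.lists(st.floats(-2, 2), min_size=6, max_size=6))
@settings(deadline=None, max_examples=50)
def test_log_cholesky_round_trip(theta6):
    theta6 = np.array(theta6)
    L = unpack_chol(theta6)
    cov = L @ L.T
    assert np.min(np.linalg.eigvalsh(cov)) >= -1e-12
    np.testing.assert_allclose(pack_chol(cov), theta6, atol=1e-8)


# ---------------------------------------------------------------------------
# likelihood

def _random_small_bundle(rng, class_re, school_re):
    p = small_params(seed=int(rng.integers(1e6)),
                     n_classes=int(rng.integers(2, 5)),
                     class_size=int(rng.integers(2, 5)))
    p.n_schools = 2
    table, _ = mp.generate_cohort(p, seed=int(rng.integers(1e6)))
    spec = mp.ModelSpec(("intercept", "domain", "sex", "domain:sex",
                         "age_within", "age_between"),
                        class_re=class_re, school_re=school_re)
    return build_design(spec, table)


def test_loglik_matches_dense_oracle_on_random_instances():
    """Engine likelihood vs brute-force dense MVN assembly: >= 100 random
    small instances across all random-structure variants, |diff| < 1e-8."""
    rng = np.random.default_rng(2024)
    checked = 0
    for class_re in ("none", "intercept", "full"):
        for school_re in (False, True):
            for _ in range(3):
                b = _random_small_bundle(rng, class_re, school_re)
                for _ in range(3):
                    theta = rng.normal(0.0, 0.8, b.spec.n_theta)
                    for method in ("ML", "REML"):
                        a = loglik(theta, b, method)
                        o = oracle_loglik(b, theta, method)
                        assert abs(a - o) < 1e-8
                        checked += 1
    assert checked >= 100


def test_loglik_reduces_to_iid_normal_when_variances_zero(tiny_cohort):
    table, _ = tiny_cohort
    spec = mp.final_model_spec()
    b = build_design(spec, table)
    theta = np.full(12, -15.0)          # log-scale diagonals -> Lambda ~ 0
    theta[[1, 3, 4, 7, 9, 10]] = 0.0    # off-diagonals exactly 0
    n = b.n_obs
    beta, *_ = np.linalg.lstsq(b.X, b.y, rcond=None)
    rss = np.sum((b.y - b.X @ beta) ** 2)
    expected = -0.5 * n * (np.log(2 * np.pi) + 1 + np.log(rss / n))
    assert loglik(theta, b, "ML") == pytest.approx(expected, abs=1e-6)


def test_reml_invariant_to_design_reparametrization(tiny_cohort):
    table, _ = tiny_cohort
    b = build_design(mp.final_model_spec(), table)
    rng = np.random.default_rng(1)
    theta = rng.normal(0, 0.5, 12)
    T = rng.normal(0, 1, (b.p, b.p)) + 2 * np.eye(b.p)
    b2 = copy.copy(b)
    b2.X = b.X @ T
    b2.groups = {}
    for k, g in b.groups.items():
        d = g.Yt.shape[0]
        Xs = g.Xflat.reshape(d, g.k, b.p) @ T
        b2.groups[k] = _Group(g.pattern, g.k, g.Yt, Xs.reshape(d, -1), g.slices)
    b2.logdet_xtx = float(np.linalg.slogdet(b2.X.T @ b2.X)[1])
    assert loglik(theta, b, "REML") == pytest.approx(
        loglik(theta, b2, "REML"), abs=1e-8)


# ---------------------------------------------------------------------------
# fitting

def test_degenerate_recovery_zero_variances():
    """Data with no random effects: class covariance vanishes, beta matches
    OLS, and the per-student marginal covariance is diagonal at sigma^2.
    (The split between Sigma_student and sigma^2 is checked through the
    identified marginal, not componentwise: with one observation per domain
    the two trade off exactly along a flat likelihood ridge.)"""
    from motorprof.cohort import Z_DOMAIN

    p = small_params(seed=2, n_classes=12, class_size=10)
    p.sigma_class = np.zeros((3, 3))
    p.sigma_student = np.zeros((3, 3))
    p.sigma_resid = 0.3
    table, _ = mp.generate_cohort(p, seed=2)
    f = mp.fit(mp.final_model_spec(), table, method="REML", seed=0)
    assert np.all(np.diag(f.sigma_class) < 0.02)
    S_marg = Z_DOMAIN @ f.sigma_student @ Z_DOMAIN.T \
        + f.sigma_resid ** 2 * np.eye(3)
    np.testing.assert_allclose(S_marg, 0.3 ** 2 * np.eye(3), atol=0.03)
    b = f.bundle
    beta_ols, *_ = np.linalg.lstsq(b.X, b.y, rcond=None)
    np.testing.assert_allclose(f.beta, beta_ols, atol=0.02)


def test_fit_recovers_generating_parameters(study_cohort):
    """Single-cohort sanity: estimates land near the generating values
    (identified quantities only; full bias assessed in the acceptance suite)."""
    table, truth = study_cohort
    params = truth["params"]
    f = mp.fit(mp.final_model_spec(), table, method="REML", seed=0)
    assert f.converged
    est = dict(zip(f.labels, f.beta))
    assert est["age_between"] == pytest.approx(params.beta_age_between, abs=0.25)
    assert est["intercept"] == pytest.approx(params.intercept, abs=0.8)
    # class-level covariance is identified: entries within sampling error
    np.testing.assert_allclose(f.sigma_class, params.sigma_class, atol=0.9)


def test_warm_start_matches_default_start(study_cohort, study_fit):
    table, truth = study_cohort
    warm = mp.fit(mp.final_model_spec(), table, method="REML",
                  start_theta=true_theta(truth["params"]))
    assert warm.loglik == pytest.approx(study_fit.loglik, abs=1e-4)
    np.testing.assert_allclose(warm.beta, study_fit.beta, atol=1e-5)


def test_ml_loglik_monotone_under_nesting(tiny_cohort):
    table, _ = tiny_cohort
    lls = []
    for fixed in (("intercept",),
                  ("intercept", "domain"),
                  ("intercept", "domain", "sex"),
                  ("intercept", "domain", "sex", "domain:sex")):
        f = mp.fit(mp.ModelSpec(fixed, class_re="intercept"), table,
                   method="ML", seed=0)
        lls.append(f.loglik)
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_statsmodels_cross_check_student_level_model():
    """Independent cross-check of the student-level-only model against
    statsmodels MixedLM: fixed effects and the per-student marginal
    covariance must agree (the split between Sigma_student and sigma^2 is
    not separately identified with one observation per domain)."""
    import statsmodels.formula.api as smf
    from motorprof.cohort import Z_DOMAIN

    p = small_params(seed=5, n_classes=6, class_size=8)
    table, _ = mp.generate_cohort(p, seed=5)
    f = mp.fit(mp.ModelSpec(("intercept", "domain", "sex"), class_re="none"),
               table, method="REML", seed=0)

    df = f.bundle.df.copy()
    df["ac"] = (df["domain"] == "aiming_catching").astype(float)
    df["bal"] = (df["domain"] == "balance").astype(float)
    code = {"manual_dexterity": (1.0, 0.0), "aiming_catching": (0.0, 1.0),
            "balance": (-1.0, -1.0)}
    df["d1"] = [code[d][0] for d in df["domain"]]
    df["d2"] = [code[d][1] for d in df["domain"]]
    df["sx"] = [1.0 if s == "boy" else -1.0 for s in df["sex"]]
    m = smf.mixedlm("standard_score ~ d1 + d2 + sx", df,
                    groups=df["child_id"], re_formula="~ac+bal").fit(reml=True)
    np.testing.assert_allclose(f.beta, m.fe_params.to_numpy(), atol=1e-3)
    S_ours = Z_DOMAIN @ f.sigma_student @ Z_DOMAIN.T \
        + f.sigma_resid ** 2 * np.eye(3)
    S_sm = Z_DOMAIN @ m.cov_re.to_numpy() @ Z_DOMAIN.T + m.scale * np.eye(3)
    np.testing.assert_allclose(S_ours, S_sm, atol=0.02)


# ---------------------------------------------------------------------------
# LRT and information criteria

def test_lrt_identical_fits_gives_zero(medium_fit):
    stat, df, p = mp.lrt(medium_fit, medium_fit)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert df == 0 and p == 1.0


def test_lrt_rejects_method_mismatch(tiny_cohort):
    table, _ = tiny_cohort
    f_ml = mp.fit(mp.ModelSpec(("intercept",), class_re="intercept"),
                  table, method="ML", seed=0)
    f_reml = mp.fit(mp.ModelSpec(("intercept", "sex"), class_re="intercept"),
                    table, method="REML", seed=0)
    with pytest.raises(ValueError):
        mp.lrt(f_ml, f_reml)


def test_reml_lrt_rejects_different_fixed_designs(tiny_cohort):
    table, _ = tiny_cohort
    f1 = mp.fit(mp.ModelSpec(("intercept",), class_re="intercept"),
                table, method="REML", seed=0)
    f2 = mp.fit(mp.ModelSpec(("intercept", "sex"), class_re="intercept"),
                table, method="REML", seed=0)
    with pytest.raises(ValueError, match="not comparable"):
        mp.lrt(f1, f2)


def test_information_criteria_formulas():
    aic, bic = mp.information_criteria(-1000.0, 10, 500)
    assert aic == pytest.approx(2020.0)
    assert bic == pytest.approx(2000.0 + 10 * np.log(500))


def test_parameter_counts_match_model_structure(tiny_cohort):
    table, _ = tiny_cohort
    chain = ("intercept", "domain", "sex", "domain:sex", "age_c")
    # 7 fixed + student 6 + sigma = 14; +1 class intercept = 15; class full = 20
    for class_re, expected in (("none", 14), ("intercept", 15), ("full", 20)):
        f = mp.fit(mp.ModelSpec(chain, class_re=class_re), table,
                   method="ML", seed=0)
        assert f.n_params == expected
    f = mp.fit(mp.final_model_spec(), table, method="ML", seed=0)
    assert f.n_params == 21
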