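"""Type III tests, effect sizes, contrasts, R2, decomposition, EB, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import motorprof as mp
from motorprof.inference import (ContrastResult, cell_contrast,
                                 contrast_correlation, conditional_residuals,
                                 domain_pairwise, sex_within_domain)
from conftest import small_params


# ---------------------------------------------------------------------------
# containment df

def test_containment_df_reproduces_study_layout_triples(study_fit):
    f = study_fit
    args = (f.spec, f.n_obs, f.n_students, f.n_classes)
    assert mp.containment_df(*args, term="domain") == 620
    assert mp.containment_df(*args, term="domain:sex") == 620
    assert mp.containment_df(*args, term="sex") == 279
    assert mp.containment_df(*args, term="age_within") == 279
    assert mp.containment_df(*args, term="age_between") == 29


def test_containment_df_unknown_term_errors(study_fit):
    f = study_fit
    with pytest.raises(ValueError):
        mp.containment_df(f.spec, f.n_obs, f.n_students, f.n_classes,
                          term="age_c")


# ---------------------------------------------------------------------------
# effect-size transformations (exact closed forms)

@pytest.mark.parametrize("F, d1, d2, expected", [
    (48.77, 2, 620, 0.14),
    (9.47, 2, 620, 0.03),
    (0.0, 2, 620, 0.0),
])
def test_partial_eta_sq_values(F, d1, d2, expected):
    value, lo, hi = mp.partial_eta_sq(F, d1, d2)
    assert value == pytest.approx(expected, abs=0.005)
    assert 0.0 <= lo <= value <= hi <= 1.0


def test_partial_eta_sq_ci_brackets_noncentral_f():
    # the 95% CI for a clearly nonzero F excludes 0 and covers the estimate
    value, lo, hi = mp.partial_eta_sq(48.77, 2, 620)
    assert lo > 0.05 and hi < 0.25


@pytest.mark.parametrize("t, df, expected", [
    (3.15, 279, 0.38), (-0.72, 279, -0.09), (0.0, 100, 0.0),
])
def test_cohens_d_from_t(t, df, expected):
    assert mp.cohens_d_from_t(t, df) == pytest.approx(expected, abs=0.005)


# ---------------------------------------------------------------------------
# Type III Wald

def test_wald_zero_coefficients_give_zero_F(study_fit):
    import copy
    f = copy.copy(study_fit)
    f.beta = study_fit.beta.copy()
    f.beta[f.bundle.term_cols["sex"]] = 0.0
    w = mp.type3_wald(f, "sex")
    assert w.F == 0.0 and w.p == 1.0 and w.eta_sq_p == 0.0


def test_wald_matches_squared_t_for_single_df_term(study_fit):
    w = mp.type3_wald(study_fit, "age_within")
    i = study_fit.labels.index("age_within")
    t = study_fit.beta[i] / np.sqrt(study_fit.cov_beta[i, i])
    assert w.F == pytest.approx(t ** 2, rel=1e-10)
    assert w.df_num == 1 and w.df_den == 279


# ---------------------------------------------------------------------------
# marginal means and contrasts

def test_emmeans_equal_grand_mean_without_effects():
    p = small_params(seed=4, n_classes=8, class_size=8)
    p.domain_offsets = {k: 0.0 for k in p.domain_offsets}
    p.sex_offset = 0.0
    p.domain_sex_offsets = {k: 0.0 for k in p.domain_sex_offsets}
    p.sigma_class = np.zeros((3, 3))
    p.sigma_student = np.zeros((3, 3))
    p.sigma_resid = 0.01
    table, _ = mp.generate_cohort(p, seed=4)
    f = mp.fit(mp.final_model_spec(), table, method="REML", seed=0)
    emm = mp.emmeans(f, by=("domain",))
    # all cell EMMs coincide with the observed grand mean (the model centers
    # covariates at their sample means, so that is the reference point)
    grand = table["standard_score"].mean()
    np.testing.assert_allclose(emm["estimate"], grand, atol=0.02)
    assert emm["estimate"].max() - emm["estimate"].min() < 0.02


def test_emm_difference_equals_contrast_estimate(medium_fit):
    emm = mp.emmeans(medium_fit, by=("domain",)).set_index("domain")
    c = cell_contrast(medium_fit, {"domain": "balance"},
                      {"domain": "manual_dexterity"})
    diff = emm.loc["balance", "estimate"] - emm.loc["manual_dexterity",
                                                    "estimate"]
    assert c.estimate == pytest.approx(diff, rel=1e-10)


def test_contrast_df_tracks_innermost_level(medium_fit):
    dom = cell_contrast(medium_fit, {"domain": "balance"},
                        {"domain": "aiming_catching"})
    sex = cell_contrast(medium_fit, {"domain": "balance", "sex": "boy"},
                        {"domain": "balance", "sex": "girl"})
    args = (medium_fit.spec, medium_fit.n_obs, medium_fit.n_students,
            medium_fit.n_classes)
    assert dom.df == mp.containment_df(*args, term="domain")
    assert sex.df == mp.containment_df(*args, term="sex")


def test_single_contrast_adjustment_is_identity(medium_fit):
    c = domain_pairwise(medium_fit)[:1]
    out = mp.adjust_contrasts(c, np.eye(1), seed=0)
    assert out[0].p_adj == out[0].p_raw


def test_maxt_adjustment_bounded_by_bonferroni_and_monotone(medium_fit):
    contrasts = domain_pairwise(medium_fit) + sex_within_domain(medium_fit)
    corr = contrast_correlation(medium_fit, contrasts)
    adj = mp.adjust_contrasts([ContrastResult(**{k: getattr(c, k) for k in
                               ("label", "estimate", "se", "t", "df",
                                "p_raw", "d")}, row=c.row)
                               for c in contrasts], corr, seed=1)
    k = len(adj)
    for c in adj:
        assert c.p_adj >= c.p_raw - 1e-12
        assert c.p_adj <= min(1.0, k * c.p_raw) + 0.01  # max-t <= Bonferroni
    # seed stability
    adj2 = mp.adjust_contrasts([ContrastResult(**{k2: getattr(c, k2) for k2 in
                                ("label", "estimate", "se", "t", "df",
                                 "p_raw", "d")}, row=c.row)
                                for c in contrasts], corr, seed=1)
    assert [c.p_adj for c in adj] == [c.p_adj for c in adj2]


def test_familywise_error_of_maxt_under_global_null():
    """FWER oracle: independent z-like contrasts under the global null;
    the max-t adjustment keeps FWER near alpha."""
    rng = np.random.default_rng(8)
    k, reps, df = 4, 2000, 400
    corr = np.eye(k)
    fwer = 0
    from scipy import stats as ss
    for _ in range(reps):
        t = rng.standard_t(df, k)
        contrasts = [ContrastResult(str(i), 0.0, 1.0, t[i], df,
                                    2 * float(ss.t.sf(abs(t[i]), df)), 0.0)
                     for i in range(k)]
        mp.adjust_contrasts(contrasts, corr, n_draws=4000, seed=0)
        fwer += any(c.p_adj < 0.05 for c in contrasts)
    assert fwer / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------------------------
# R2 and pseudo-R2

def test_r2_conditional_equals_marginal_without_random_variance(study_fit):
    import copy
    f = copy.copy(study_fit)
    f.sigma_class = np.zeros((3, 3))
    f.sigma_student = np.zeros((3, 3))
    r2m, r2c = mp.r2_nakagawa(f)
    assert r2c == pytest.approx(r2m, rel=1e-12)


def test_r2_marginal_ordering_on_study_cohort(study_fit):
    r2m, r2c = mp.r2_nakagawa(study_fit)
    assert 0 < r2m < r2c < 1


@pytest.mark.parametrize("lrt_stat, n, expected", [
    (63.37, 936, 0.0655), (0.0, 936, 0.0),
])
def test_pseudo_r2_cox_snell_form(lrt_stat, n, expected):
    out = mp.pseudo_r2_from_lrt(lrt_stat, n)
    assert out["cox_snell"] == pytest.approx(expected, abs=5e-4)


def test_pseudo_r2_monotone_in_lrt():
    vals = [mp.pseudo_r2_from_lrt(s, 936)["cox_snell"]
            for s in (0.0, 10.0, 30.0, 63.37, 120.0)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_pseudo_r2_rejects_negative_improvement():
    with pytest.raises(ValueError):
        mp.pseudo_r2(-100.0, -90.0, 936)


# ---------------------------------------------------------------------------
# variance decomposition

def test_shares_sum_to_one_and_vpc_in_range(study_fit):
    vd = mp.variance_decomposition(study_fit)
    assert sum(vd.shares.values()) == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= vd.vpc_grand_mean <= 1.0
    assert np.allclose(np.diag(vd.corr_class), 1.0)


def test_decomposition_invariant_to_response_rescaling(study_cohort):
    """Rescaling the response leaves the VPC unchanged and scales the
    identified covariance functionals by the square of the factor.

    The check runs on the identified quantities (VPC, class covariance, the
    per-student marginal, beta): the finer student/residual split sits on an
    exactly flat likelihood ridge, so its numerical resolution point is not
    stable under monotone transformations of the data.
    """
    from motorprof.cohort import Z_DOMAIN

    table, _ = study_cohort
    scaled = table.copy()
    scaled["standard_score"] = 2.0 * scaled["standard_score"]
    f1 = mp.fit(mp.final_model_spec(), table, method="REML", seed=0)
    f2 = mp.fit(mp.final_model_spec(), scaled, method="REML", seed=0)
    v1 = mp.variance_decomposition(f1)
    v2 = mp.variance_decomposition(f2)
    assert v1.vpc_grand_mean == pytest.approx(v2.vpc_grand_mean, abs=1e-3)
    np.testing.assert_allclose(4.0 * f1.sigma_class, f2.sigma_class,
                               atol=1e-2)
    marg1 = Z_DOMAIN @ f1.sigma_student @ Z_DOMAIN.T \
        + f1.sigma_resid ** 2 * np.eye(3)
    marg2 = Z_DOMAIN @ f2.sigma_student @ Z_DOMAIN.T \
        + f2.sigma_resid ** 2 * np.eye(3)
    np.testing.assert_allclose(4.0 * marg1, marg2, atol=1e-2)
    np.testing.assert_allclose(2.0 * f1.beta, f2.beta, atol=1e-4)


# ---------------------------------------------------------------------------
# empirical Bayes

def test_blups_vanish_when_class_variance_zero(study_fit):
    import copy
    f = copy.copy(study_fit)
    f.sigma_class = np.zeros((3, 3))
    eb = mp.eb_estimates(f)
    assert np.allclose(eb["intercept_blup"], 0.0)
    assert not eb["intercept_significant"].any()


def test_blups_shrink_toward_zero_vs_unshrunken_class_estimates():
    """In an intercept-only random-class model the BLUP never exceeds (in
    magnitude) the unshrunken GLS estimate of the class deviation, i.e. the
    class mean residual weighted by the within-class covariance."""
    from motorprof.cohort import Z_DOMAIN

    p = small_params(seed=6, n_classes=8, class_size=6)
    table, _ = mp.generate_cohort(p, seed=6)
    f = mp.fit(mp.ModelSpec(("intercept", "domain"), class_re="intercept"),
               table, method="REML", seed=0)
    eb = mp.eb_estimates(f).set_index("class_id")
    resid = f.bundle.y - f.bundle.X @ f.beta
    S_stu = Z_DOMAIN @ f.sigma_student @ Z_DOMAIN.T
    df = f.bundle.df
    for cid, grp in df.groupby("class_id"):
        idx = grp.index.to_numpy()
        m = len(idx) // 3
        V0 = np.kron(np.eye(m), S_stu) + f.sigma_resid ** 2 * np.eye(3 * m)
        ones = np.ones(3 * m)
        w = np.linalg.solve(V0, ones)
        raw_gls = float(w @ resid[idx]) / float(w @ ones)
        blup = eb.loc[cid, "intercept_blup"]
        assert abs(blup) <= abs(raw_gls) + 1e-9
        assert blup * raw_gls >= 0  # shrinkage preserves sign


def test_eb_prediction_intervals_match_posterior_sd(study_fit):
    eb = mp.eb_estimates(study_fit)
    np.testing.assert_allclose(
        eb["intercept_pi_high"] - eb["intercept_blup"],
        1.96 * eb["intercept_post_sd"], rtol=1e-9)
    # caterpillar order
    assert eb["intercept_blup"].is_monotonic_increasing


# ---------------------------------------------------------------------------
# diagnostics

def test_gvif_is_one_for_orthogonal_design(study_fit):
    d = mp.diagnostics(study_fit)
    # balanced sum-coded factors and centered covariates: near-orthogonal
    for term, g in d["gvif"].items():
        assert g["gvif"] == pytest.approx(1.0, abs=0.2)
        assert g["gvif_scaled"] >= 1.0 - 1e-9
    assert 0.0 <= d["breusch_pagan_p"] <= 1.0


def test_breusch_pagan_calibrated_on_model_generated_cohorts():
    """Homoscedasticity diagnostic calibration: data generated from the
    model (whose conditional errors are homoscedastic) rejects at the
    nominal rate, within the binomial band at 150 simulated cohorts."""
    from motorprof.inference import diagnostics
    from conftest import true_theta

    params = mp.default_params(seed=0)
    spec = mp.final_model_spec()
    theta0 = true_theta(params)
    n_sim = 150
    rej = 0
    for i in range(n_sim):
        table, _ = mp.generate_cohort(params, seed=300_000 + i)
        f = mp.fit(spec, table, method="REML", start_theta=theta0)
        rej += diagnostics(f)["breusch_pagan_p"] < 0.05
    band = 2.5 * np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rej / n_sim - 0.05) <= band, rej / n_sim


def test_conditional_residuals_are_studentized(study_fit):
    e = conditional_residuals(study_fit)
    # unit-scale after studentizing under the fitted model
    assert np.std(e) == pytest.approx(1.0, abs=0.15)
    by_domain = pd.Series(e).groupby(
        study_fit.bundle.df["domain"].to_numpy()).std()
    assert (abs(by_domain - 1.0) < 0.25).all()
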