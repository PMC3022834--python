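import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd4slope import (
    GeneratorConfig,
    build_endpoints,
    eligible_patients,
    fit_random_intercept,
    fit_terms,
    forward_select,
    model_rows,
    pair_concurrent,
    report_table,
    univariate_scan,
)
from cd4slope.endpoints import add_t_days
from cd4slope.mixedlm import SingularDesignError
from cd4slope.model import ALL_TERMS

from conftest import simulate_mixed
from oracles import grid_fit


@pytest.fixture(scope="module")
def small_endpoints(small_cohort):
    pairs = add_t_days(pair_concurrent(small_cohort.labs), small_cohort)
    elig = eligible_patients(small_cohort, pairs)
    return model_rows(build_endpoints(small_cohort, pairs, restrict=elig))


# ----------------------------------------------------------------- basic fits
def test_boundary_case_matches_pooled_ols():
    """With no between-patient variance in truth, the profiled fit lands on
    the lambda=0 boundary and reproduces pooled OLS."""
    rng = np.random.default_rng(5)  # seed chosen so the ML boundary binds
    y, X, groups = simulate_mixed(rng, n_groups=30, group_size=3, sigma_b=0.0)
    fit = fit_random_intercept(y, X, groups, criterion="REML")
    if fit.sigma_b2 == 0.0:
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-8)
    # regardless of boundary, the estimate must agree with the brute-force grid
    beta_grid, *_ = grid_fit(y, X, groups, reml=True)
    assert np.allclose(fit.beta, beta_grid, atol=1e-6)


def test_exact_linear_response_flags_degeneracy():
    X = np.column_stack([np.ones(12), np.tile(np.arange(4.0), 3)])
    y = X @ np.array([2.0, -3.0])
    groups = np.repeat([0, 1, 2], 4)
    fit = fit_random_intercept(y, X, groups)
    assert np.allclose(fit.beta, [2.0, -3.0], atol=1e-8)
    assert "residual_degenerate" in fit.flags


def test_simulated_fit_matches_dense_grid_oracle():
    rng = np.random.default_rng(42)
    y, X, groups = simulate_mixed(rng, n_groups=50, group_size=4,
                                  beta=(10.0, -40.0), sigma_b=15.0, sigma_e=60.0)
    fit = fit_random_intercept(y, X, groups, criterion="REML")
    beta_grid, lam_grid, sigma2_grid, _ = grid_fit(y, X, groups, reml=True)
    assert np.allclose(fit.beta, beta_grid, atol=1e-6)
    assert fit.sigma_e2 == pytest.approx(sigma2_grid, rel=1e-4)
    assert fit.beta[1] == pytest.approx(-40.0, abs=3 * fit.se[1])


def test_ml_criterion_matches_grid_oracle():
    rng = np.random.default_rng(7)
    y, X, groups = simulate_mixed(rng, n_groups=40, group_size=3)
    fit = fit_random_intercept(y, X, groups, criterion="ML")
    beta_grid, *_ = grid_fit(y, X, groups, reml=False)
    assert np.allclose(fit.beta, beta_grid, atol=1e-6)


def test_reml_matches_statsmodels_mixedlm():
    statsmodels = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    y, X, groups = simulate_mixed(rng, n_groups=60, group_size=5,
                                  sigma_b=20.0, sigma_e=50.0)
    ours = fit_random_intercept(y, X, groups, criterion="REML")
    sm_fit = statsmodels.MixedLM(y, X, groups=groups).fit(reml=True)
    assert np.allclose(ours.beta, sm_fit.fe_params, atol=1e-4)
    assert ours.sigma_b2 == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]),
                                          rel=1e-3, abs=1e-3)
    assert ours.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)
    # statsmodels derives fixed-effect SEs from the joint information matrix,
    # not the plug-in GLS covariance at the REML optimum; ~1% agreement
    assert np.allclose(ours.se, np.asarray(sm_fit.bse_fe), rtol=0.02)


def test_row_permutation_leaves_estimates_unchanged():
    rng = np.random.default_rng(3)
    y, X, groups = simulate_mixed(rng)
    fit = fit_random_intercept(y, X, groups)
    perm = rng.permutation(len(y))
    fit_p = fit_random_intercept(y[perm], X[perm], np.asarray(groups)[perm])
    assert np.allclose(fit.beta, fit_p.beta, atol=1e-6)
    assert fit.sigma_b2 == pytest.approx(fit_p.sigma_b2, rel=1e-4, abs=1e-6)


def test_singular_design_names_collinear_column():
    X = pd.DataFrame({"const": 1.0, "a": np.arange(10.0), "twice_a": 2 * np.arange(10.0)})
    with pytest.raises(SingularDesignError, match="collinear") as exc:
        fit_random_intercept(np.arange(10.0), X, np.repeat([0, 1], 5))
    assert set(exc.value.columns) & {"a", "twice_a"}


def test_singleton_groups_flagged_and_fit_as_ols():
    rng = np.random.default_rng(9)
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    y = X @ np.array([1.0, 2.0]) + rng.normal(size=20)
    fit = fit_random_intercept(y, X, np.arange(20))
    assert "sigma_b_unidentifiable" in fit.flags
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.beta, ols, atol=1e-10)


def test_needs_more_observations_than_terms():
    with pytest.raises(ValueError, match="n_obs"):
        fit_random_intercept(np.ones(2), np.ones((2, 2)), [0, 1])


# --------------------------------------------------------------------- property
@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000),
       n_groups=st.integers(min_value=3, max_value=20),
       group_size=st.integers(min_value=1, max_value=6),
       sigma_b=st.floats(min_value=0.0, max_value=40.0))
def test_profile_fit_equals_grid_oracle_on_random_instances(
        seed, n_groups, group_size, sigma_b):
    rng = np.random.default_rng(seed)
    y, X, groups = simulate_mixed(rng, n_groups=n_groups, group_size=group_size,
                                  sigma_b=sigma_b, sigma_e=30.0)
    if len(y) <= X.shape[1]:
        return
    fit = fit_random_intercept(y, X, groups)
    beta_grid, *_ = grid_fit(y, X, groups, reml=True)
    assert np.allclose(fit.beta, beta_grid, atol=1e-6)


def test_reml_and_ml_agree_at_scale(small_endpoints):
    reml = fit_terms(small_endpoints, ["vl", "period"], criterion="REML")
    ml = fit_terms(small_endpoints, ["vl", "period"], criterion="ML")
    assert np.allclose(reml.beta, ml.beta, rtol=0.05)


# ----------------------------------------------------------- scan & selection
def test_univariate_scan_returns_one_fit_per_block(small_endpoints):
    fits = univariate_scan(small_endpoints)
    assert set(fits) == set(ALL_TERMS)
    vl = fits["vl"]
    assert set(vl.names) == {"const", "log10_vl"}
    stage = fits["stage"]
    assert set(stage.names) == {"const", "stage_tb", "stage_nontb"}


def test_scan_skips_constant_covariate_and_continues(small_endpoints):
    broken = small_endpoints.copy()
    broken["hepatitis"] = 0  # constant -> collinear with intercept
    fits = univariate_scan(broken)
    assert "hepatitis" not in fits
    assert "vl" in fits


def test_scan_rejects_empty_table():
    with pytest.raises(ValueError, match="empty"):
        univariate_scan(pd.DataFrame())


def test_single_strong_candidate_is_retained(small_endpoints):
    final, trace = forward_select(small_endpoints, candidates=["vl"])
    assert trace.final_terms == ["vl"]
    assert trace.steps[0][1] == "vl"
    assert trace.steps[0][2] < 0.05


def test_selection_entry_respects_alpha(small_endpoints):
    final, trace = forward_select(small_endpoints, alpha=0.20)
    assert all(p <= 0.20 for _, _, p in trace.steps)
    assert set(trace.dropped_p) == set(ALL_TERMS) - set(trace.final_terms)


def test_pure_noise_candidate_retained_at_about_alpha_rate():
    """A covariate unrelated to the response should enter a forward step at
    roughly the entry level alpha."""
    rng = np.random.default_rng(21)
    retained = 0
    reps = 120
    for _ in range(reps):
        y, X, groups = simulate_mixed(rng, n_groups=30, group_size=3,
                                      beta=(5.0, 0.0), sigma_b=5.0, sigma_e=30.0)
        fit = fit_random_intercept(y, X, groups)
        retained += fit.wald_p[1] <= 0.20
    # binomial(120, 0.2): middle 99.9% well inside (0.09, 0.33)
    assert 0.09 <= retained / reps <= 0.33


# ------------------------------------------------------------------ reporting
def test_report_renders_published_constant_row():
    from cd4slope import published_coefficients

    table = report_table({}, published_coefficients())
    assert "205.5" in table and "(174.4, 236.6)" in table
    assert "per log10 copies/mL higher" in table


def test_report_with_no_fits_is_header_only():
    table = report_table({}, None)
    assert "Covariate" in table
    assert "205.5" not in table


def test_report_emits_degeneracy_footnote():
    X = np.column_stack([np.ones(12), np.tile(np.arange(4.0), 3)])
    y = X @ np.array([2.0, -3.0])
    fit = fit_random_intercept(y, X, np.repeat([0, 1, 2], 4), names=["const", "cd4_per100"])
    table = report_table({}, fit)
    assert "residual_degenerate" in table
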