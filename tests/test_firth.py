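"""Penalized likelihood, the modified-score solver, profile intervals and
likelihood-ratio tests, checked against closed forms and brute-force
oracles."""


import numpy as np
import pytest
from scipy import optimize, stats

from albistat.firth import (
    FirthOptions,
    SingularInformationError,
    fit_firth,
    fit_group_model,
    penalized_lrt_pvalue,
    penalized_loglik,
    profile_ci,
)

# score-only convergence: the log-likelihood-change criterion saturates at
# machine precision before the score reaches 1e-12
TIGHT = FirthOptions(tol_score=1e-12, tol_loglik=0.0, max_iter=200)

TWO_BY_TWO_X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
TWO_BY_TWO_Y = np.array([1.0, 0.0, 1.0, 0.0])


def _naive_penalized_loglik(beta, X, y, w=None):
    """Independent evaluation: plain sums and a determinant call."""
    w = np.ones(len(y)) if w is None else w
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p)))
    info = X.T @ np.diag(w * p * (1 - p)) @ X
    return ll + 0.5 * np.log(np.linalg.det(info))


def test_penalized_loglik_hand_value():
    # intercept-only, n=2, y=(0,1), beta=0: 2 ln(1/2) + 0.5 ln(2 * 1/4)
    X = np.ones((2, 1))
    y = np.array([0.0, 1.0])
    assert penalized_loglik(np.zeros(1), X, y) == pytest.approx(
        2 * np.log(0.5) + 0.5 * np.log(0.5), abs=1e-10)


def test_penalized_loglik_matches_naive_determinant_oracle(rng):
    for _ in range(20):
        X = np.column_stack([np.ones(5), rng.normal(size=(5, 2))])
        y = rng.integers(0, 2, size=5).astype(float)
        beta = rng.normal(scale=0.8, size=3)
        assert penalized_loglik(beta, X, y) == pytest.approx(
            _naive_penalized_loglik(beta, X, y), abs=1e-10)


def test_penalty_diverges_to_minus_infinity():
    X = np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2.0]])
    y = np.array([0, 0, 1, 1, 0, 1.0])
    vals = [penalized_loglik(np.array([0.0, b]), X, y) for b in (0, 5, 15, 30)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_singular_information_names_offending_columns():
    X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
    y = np.array([0, 1, 0, 1, 0, 1.0])
    with pytest.raises(SingularInformationError, match="x[12]"):
        penalized_loglik(np.zeros(3), X, y)


def test_intercept_only_closed_form_all_k_n_up_to_50():
    # Jeffreys-penalized intercept model: pi_hat = (k + 1/2) / (n + 1)
    for n in range(1, 51):
        X = np.ones((n, 1))
        for k in range(n + 1):
            y = np.zeros(n)
            y[:k] = 1.0
            fit = fit_firth(X, y, options=TIGHT)
            expected = np.log((k + 0.5) / (n - k + 0.5))
            assert fit.beta[0] == pytest.approx(expected, abs=1e-8), (n, k)


def test_intercept_closed_form_verified_by_grid_maximization():
    # one-dimensional grid maximization confirms the closed form itself
    X = np.ones((10, 1))
    y = np.array([1.0] * 3 + [0.0] * 7)
    grid = np.linspace(-3, 2, 20001)
    vals = [penalized_loglik(np.array([b]), X, y) for b in grid]
    assert grid[int(np.argmax(vals))] == pytest.approx(np.log(3.5 / 7.5), abs=1e-3)
    assert fit_firth(X, y, options=TIGHT).beta[0] == pytest.approx(
        np.log(3.5 / 7.5), abs=1e-10)


def _haldane_log_or(a, b, c, d):
    return np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))


def _fit_2x2(a, b, c, d):
    w = np.array([a, b, c, d], dtype=float)
    return fit_firth(TWO_BY_TWO_X, TWO_BY_TWO_Y, weights=w, options=TIGHT)


def test_saturated_2x2_equals_haldane_exhaustive_and_sampled(rng):
    # exhaustive over tables with total size <= 30 (non-empty rows)
    for n1 in range(1, 30):
        for n2 in range(1, 31 - n1):
            for a in range(n1 + 1):
                for c in range(n2 + 1):
                    fit = _fit_2x2(a, n1 - a, c, n2 - c)
                    assert abs(fit.beta[1] - _haldane_log_or(a, n1 - a, c, n2 - c)) \
                        < 1e-8, (a, n1 - a, c, n2 - c)
    # seeded sample of larger tables with each row margin up to 30
    for _ in range(200):
        n1, n2 = rng.integers(1, 31, size=2)
        a, c = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
        fit = _fit_2x2(a, n1 - a, c, n2 - c)
        assert abs(fit.beta[1] - _haldane_log_or(a, n1 - a, c, n2 - c)) < 1e-8


def test_zero_cell_2x2_example_stays_finite():
    # exposed 0/10 cases vs unexposed 10/100
    fit = _fit_2x2(0, 10, 10, 90)
    assert fit.beta[1] == pytest.approx(np.log(0.5 * 90.5 / (10.5 * 10.5)),
                                        abs=1e-8)
    # 2-D grid maximization of l* agrees with the Haldane identity
    w = np.array([0.0, 10, 10, 90])
    b1 = np.linspace(-2, 0.5, 301)
    b0 = np.linspace(-4, 0, 301)
    vals = np.array([[penalized_loglik(np.array([i0, i1]), TWO_BY_TWO_X,
                                       TWO_BY_TWO_Y, weights=w)
                      for i1 in b1] for i0 in b0])
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    assert b1[j] == pytest.approx(fit.beta[1], abs=0.01)


def test_symmetric_2x2_slope_zero():
    fit = _fit_2x2(5, 5, 5, 5)
    assert abs(fit.beta[1]) < 1e-12


def test_estimates_finite_under_complete_separation():
    X = np.column_stack([np.ones(8), [0, 0, 0, 0, 1, 1, 1, 1.0]])
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1.0])
    fit = fit_firth(X, y)
    assert fit.converged and np.all(np.isfinite(fit.beta))
    # quasi-complete separation
    y2 = np.array([0, 0, 0, 1, 1, 1, 1, 1.0])
    fit2 = fit_firth(X, y2)
    assert np.all(np.isfinite(fit2.beta))


def test_solver_never_decreases_penalized_loglik(rng):
    for _ in range(10):
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.integers(0, 2, size=30).astype(float)
        fit = fit_firth(X, y)
        # started from 0 with improving steps only
        assert fit.loglik_pen >= penalized_loglik(np.zeros(3), X, y) - 1e-12


# ------------------------------------------------------------- profile CIs

@pytest.fixture(scope="module")
def random_design():
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(40), rng.normal(size=40),
                         rng.binomial(1, 0.4, 40)])
    eta = 0.4 * X[:, 1] - 0.6 * X[:, 2]
    y = (rng.random(40) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def test_profile_ci_contains_estimate_and_satisfies_drop_equation(random_design):
    X, y = random_design
    fit = fit_firth(X, y, options=TIGHT)
    target_drop = 0.5 * stats.chi2.ppf(0.95, 1)
    for j in range(3):
        lo, hi, flag = profile_ci(X, y, fit, j, options=TIGHT)
        assert flag == "" and lo < fit.beta[j] < hi
        for b in (lo, hi):
            prof = fit_firth(X, y, fixed={j: b}, beta0=fit.beta,
                             options=TIGHT).loglik_pen
            assert abs((fit.loglik_pen - prof) - target_drop) < 1e-6


def test_profile_ci_matches_grid_scan_oracle(random_design):
    X, y = random_design
    fit = fit_firth(X, y, options=TIGHT)
    j = 1
    lo, hi, _ = profile_ci(X, y, fit, j, options=TIGHT)
    # independent oracle: grid over beta_j with a Nelder-Mead profile
    # maximization of the raw penalized likelihood at each point
    grid = np.linspace(fit.beta[j] - 3, fit.beta[j] + 3, 241)

    def prof(b):
        res = optimize.minimize(
            lambda th: -penalized_loglik(np.insert(th, j, b), X, y),
            np.delete(fit.beta, j), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 4000})
        return -res.fun

    target = fit.loglik_pen - 0.5 * stats.chi2.ppf(0.95, 1)
    vals = np.array([prof(b) for b in grid])
    inside = grid[vals >= target]
    step = grid[1] - grid[0]
    assert inside.min() == pytest.approx(lo, abs=step)
    assert inside.max() == pytest.approx(hi, abs=step)
    # refine the grid oracle by bisecting its own profile to 1e-4
    for endpoint, lo_b in ((lo, inside.min() - step), (hi, inside.max())):
        root = optimize.brentq(lambda b: prof(b) - target,
                               lo_b - 1e-9, lo_b + step + 1e-9, xtol=1e-7)
        assert root == pytest.approx(endpoint, abs=1e-4)


def test_symmetric_profile_interval_for_balanced_2x2():
    w = np.array([5.0, 5, 5, 5])
    fit = fit_firth(TWO_BY_TWO_X, TWO_BY_TWO_Y, weights=w, options=TIGHT)
    lo, hi, _ = profile_ci(TWO_BY_TWO_X, TWO_BY_TWO_Y, fit, 1, weights=w,
                           options=TIGHT)
    assert lo == pytest.approx(-hi, abs=1e-6)


def test_profile_ci_finite_under_complete_separation():
    # the penalty bends the profile down on both sides, so even a fully
    # separated table yields a closed interval containing the estimate
    X = np.column_stack([np.ones(4), [0.0, 0, 1, 1]])
    y = np.array([0.0, 0, 1, 1])
    w = np.array([20.0, 20, 20, 20])
    fit = fit_firth(X, y, weights=w, options=TIGHT)
    lo, hi, flag = profile_ci(X, y, fit, 1, weights=w, options=TIGHT)
    assert flag == "" and np.isfinite(lo) and np.isfinite(hi)
    assert lo < fit.beta[1] < hi


# ---------------------------------------------------------------- LRT tests

def test_lrt_zero_statistic_when_estimate_is_zero():
    w = np.array([5.0, 5, 5, 5])
    fit = fit_firth(TWO_BY_TWO_X, TWO_BY_TWO_Y, weights=w, options=TIGHT)
    p, stat, conv = penalized_lrt_pvalue(TWO_BY_TWO_X, TWO_BY_TWO_Y, fit, 1,
                                         weights=w, options=TIGHT)
    assert conv and stat == pytest.approx(0.0, abs=1e-10) and p == pytest.approx(1.0)


def test_lrt_pvalues_in_unit_interval(rng):
    for _ in range(10):
        X = np.column_stack([np.ones(25), rng.normal(size=25)])
        y = rng.integers(0, 2, size=25).astype(float)
        fit = fit_firth(X, y)
        p, stat, _ = penalized_lrt_pvalue(X, y, fit, 1)
        assert 0.0 <= p <= 1.0 and stat >= 0.0


def test_lrt_matches_independent_restricted_maximization():
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(30), rng.normal(size=30),
                         rng.binomial(1, 0.5, 30)])
    y = (rng.random(30) < 0.4).astype(float)
    fit = fit_firth(X, y, options=TIGHT)
    p, stat, _ = penalized_lrt_pvalue(X, y, fit, 1, options=TIGHT)
    res = optimize.minimize(
        lambda th: -penalized_loglik(np.insert(th, 1, 0.0), X, y),
        np.delete(fit.beta, 1), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 8000})
    stat_oracle = 2 * (fit.loglik_pen - (-res.fun))
    assert stat == pytest.approx(stat_oracle, abs=1e-6)


# ----------------------------------------------------------- group model

def test_group_a_reference_reports_or_exactly_one(default_cohort):
    kept = default_cohort["kept"]
    table, _ = fit_group_model(kept[kept["group"] != "unassigned"],
                               ci=False, pvalues=False)
    row = table[table["group"] == "A"].iloc[0]
    assert row["OR"] == 1.0 and np.isnan(row["p"])


def test_null_disease_model_estimates_near_zero():
    from albistat.cohort import assign_groups_frame, filter_frame
    from albistat.simulate import DiseaseModelConfig, simulate_cohort

    cfg = DiseaseModelConfig(
        seed=11, group_log_or={g: 0.0 for g in "BCDEF"},
        modifier_log_or=0.0, n_cases=400, n_controls=19600,
        population_size=60000)
    cohort = simulate_cohort(cfg)
    kept, _ = filter_frame(assign_groups_frame(cohort.frame))
    table, fit = fit_group_model(kept[kept["group"] != "unassigned"],
                                 ci=False, pvalues=False)
    for g in "BCDE":  # F may be empty at this scale
        sub = table[table["group"] == g]
        if len(sub) == 0:
            continue
        j = fit.names.index(f"group_{g}")
        assert abs(np.log(sub["OR"].iloc[0])) < 3 * fit.se_wald[j]


def test_dual_heterozygote_effect_exceeds_single_het_groups():
    from albistat.cohort import assign_groups_frame, filter_frame
    from albistat.simulate import DiseaseModelConfig, simulate_cohort

    cfg = DiseaseModelConfig(seed=5, n_cases=400, n_controls=20000,
                             population_size=120000)
    cohort = simulate_cohort(cfg)
    kept, _ = filter_frame(assign_groups_frame(cohort.frame))
    table, _ = fit_group_model(kept[kept["group"] != "unassigned"],
                               ci=False, pvalues=False)
    ors = table.set_index("group")["OR"]
    assert ors["D"] > ors["B"] and ors["D"] > ors["C"]


def test_empty_group_level_dropped_with_warning(default_cohort):
    kept = default_cohort["kept"]
    sub = kept[kept["group"].isin(["A", "B", "D"])]
    with pytest.warns(RuntimeWarning, match="group level"):
        table, _ = fit_group_model(sub, ci=False, pvalues=False)
    assert set(table["group"]) == {"A", "B", "D"}
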