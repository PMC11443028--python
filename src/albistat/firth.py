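"""Firth bias-reduced logistic regression.

Implements the penalized-likelihood machinery used throughout the
case-control analysis: the Jeffreys-penalized binomial log-likelihood
``l*(beta) = l(beta) + 0.5 * log det I(beta)`` with
``I(beta) = X' diag(w * pi * (1 - pi)) X``, a modified-score Newton
solver with step-halving, profile penalized-likelihood confidence
intervals, and penalized likelihood-ratio p-values.

The penalty keeps estimates finite under complete and quasi-complete
separation, which matters here because the dual-heterozygote genotype
group is rare and the case/control split is extremely imbalanced.

Rows may carry frequency weights, so a 2x2 table can be fitted as four
weighted rows; in that saturated case the Firth estimate coincides with
the Haldane-corrected (add 1/2 to each cell) log odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "FirthOptions",
    "FirthFit",
    "SingularInformationError",
    "penalized_loglik",
    "fit_firth",
    "profile_ci",
    "penalized_lrt_pvalue",
    "fit_group_model",
    "GROUP_ORDER",
]

GROUP_ORDER = ["A", "B", "C", "D", "E", "F"]


class SingularInformationError(np.linalg.LinAlgError):
    """Raised when the Fisher information matrix is not positive definite."""


@dataclass
class FirthOptions:
    """Solver and interval settings.

    max_iter: Newton iteration cap.
    max_step_halvings: halvings allowed before accepting a non-improving step.
    tol_score: convergence threshold on max |modified score|.
    tol_loglik: convergence threshold on the penalized log-likelihood change.
    ci_level: two-sided coverage for profile intervals.
    """

    max_iter: int = 50
    max_step_halvings: int = 10
    tol_score: float = 1e-6
    tol_loglik: float = 1e-9
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if min(self.max_iter, self.max_step_halvings) <= 0:
            raise ValueError("iteration limits must be positive")
        if self.tol_score <= 0 or self.tol_loglik < 0 or not 0 < self.ci_level < 1:
            # tol_loglik = 0 disables the likelihood-change criterion
            raise ValueError("tolerances must be positive and ci_level in (0,1)")


@dataclass
class FirthFit:
    """A fitted penalized logistic model (log-odds scale)."""

    beta: np.ndarray
    se_wald: np.ndarray
    loglik_pen: float
    converged: bool
    n_iter: int
    names: list[str] = field(default_factory=list)
    ci_profile: np.ndarray | None = None   # (p, 2) lo/hi, NaN where not computed
    p_lrt: np.ndarray | None = None
    ci_flags: list[str] | None = None      # per-coefficient "" / "open_lo" / "open_hi"


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _chol_info(X: np.ndarray, wvar: np.ndarray, names: list[str] | None):
    """Cholesky factor of X' diag(wvar) X; informative error when singular."""
    info = (X * wvar[:, None]).T @ X
    try:
        L = np.linalg.cholesky(info)
    except np.linalg.LinAlgError:
        cols = _offending_columns(X, names)
        raise SingularInformationError(
            f"information matrix is singular; offending columns: {cols}"
        ) from None
    return info, L


def _offending_columns(X: np.ndarray, names: list[str] | None) -> list[str]:
    # name columns past the numerical rank of X as the aliased set
    r = np.linalg.matrix_rank(X)
    labels = names if names else [f"x{j}" for j in range(X.shape[1])]
    if r >= X.shape[1]:
        return list(labels)
    _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
    return [labels[j] for j in sorted(piv[r:])]


def penalized_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
) -> float:
    """Penalized binomial log-likelihood l(beta) + 0.5 log det I(beta)."""
    beta = np.asarray(beta, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    eta = X @ beta
    # log(1 + e^eta) computed stably
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    p = _sigmoid(eta)
    _, L = _chol_info(X, w * p * (1.0 - p), names)
    return ll + float(np.sum(np.log(np.diag(L))))


def _state(beta, X, y, w, names):
    """Evaluate (loglik*, modified score, information) at beta."""
    eta = X @ beta
    p = _sigmoid(eta)
    wvar = w * p * (1.0 - p)
    info, L = _chol_info(X, wvar, names)
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    llpen = ll + float(np.sum(np.log(np.diag(L))))
    # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2, as wvar_i * x_i' I^-1 x_i
    h = wvar * np.einsum("ij,ji->i", X, np.linalg.solve(info, X.T))
    score = X.T @ (w * (y - p) + h * (0.5 - p))
    return llpen, score, info


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    options: FirthOptions | None = None,
    names: list[str] | None = None,
    fixed: dict[int, float] | None = None,
    beta0: np.ndarray | None = None,
) -> FirthFit:
    """Maximize the penalized log-likelihood by modified-score Newton steps.

    ``fixed`` maps coefficient indices to values held constant (used for
    profile likelihood and restricted LRT fits); the remaining coordinates
    are optimized. Accepted steps never decrease l*; a step is halved up to
    ``max_step_halvings`` times before being taken as-is.
    """
    opts = options or FirthOptions()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    fixed = fixed or {}
    free = np.array([j for j in range(p) if j not in fixed], dtype=int)

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    for j, v in fixed.items():
        beta[j] = v

    llpen, score, info = _state(beta, X, y, w, names)
    n_iter = 0
    converged = False
    stagnant = 0
    for n_iter in range(1, opts.max_iter + 1):
        if free.size == 0:
            converged = True
            break
        g = score[free]
        H = info[np.ix_(free, free)]
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            cols = _offending_columns(X[:, free], [str(j) for j in free])
            raise SingularInformationError(
                f"information matrix is singular; offending columns: {cols}"
            ) from None
        # the Newton direction ascends l* (information is pd), so halving far
        # enough always yields an improving, evaluable step; non-evaluable
        # trials (overflow into a singular information matrix) don't count
        # against the halving budget
        halvings = overflows = 0
        new_ll = -np.inf
        # machine-precision slack: near the optimum l* is flat to rounding,
        # and demanding strict improvement would stall the score criterion
        accept_floor = llpen - 1e-12 * (1.0 + abs(llpen))
        while True:
            new_beta = beta.copy()
            new_beta[free] += step
            try:
                new_ll, new_score, new_info = _state(new_beta, X, y, w, names)
            except SingularInformationError:
                new_ll = -np.inf
                overflows += 1
            if np.isfinite(new_ll) and new_ll >= accept_floor:
                break
            if halvings >= opts.max_step_halvings + 40 or overflows > 60:
                break
            step *= 0.5
            halvings += 1
        if not np.isfinite(new_ll) or new_ll < accept_floor:
            warnings.warn("Firth step-halving stalled; stopping at the last "
                          "accepted point", RuntimeWarning)
            break
        delta = new_ll - llpen
        beta, llpen, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(score[free])) < opts.tol_score or (
                opts.tol_loglik > 0 and abs(delta) < opts.tol_loglik):
            converged = True
            break
        # creep detection: l* barely moves while the score stays large;
        # hand over to the quasi-Newton/root polish below
        stagnant = stagnant + 1 if abs(delta) < 1e-10 * (1 + abs(llpen)) else 0
        if stagnant >= 3:
            break
    if not converged and free.size:
        # the expected information is a poor Hessian of l* on very small
        # designs (the penalty's curvature is comparable to I there) and
        # the main loop can creep; polish locally, cheapest stage first
        def score_free(bf: np.ndarray) -> np.ndarray | None:
            full = beta.copy()
            full[free] = bf
            try:
                return _state(full, X, y, w, names)[1][free]
            except SingularInformationError:
                return None

        def fd_newton(bf0: np.ndarray, g0: np.ndarray):
            # Newton on U*(beta) = 0 with a finite-difference Jacobian of
            # the exact gradient; quadratic close to the optimum
            bf, g = bf0.copy(), g0.copy()
            for _ in range(30):
                if np.max(np.abs(g)) < opts.tol_score:
                    break
                eps = 1e-6 * (1.0 + np.abs(bf))
                J = np.empty((free.size, free.size))
                ok = True
                for r in range(free.size):
                    up, dn = bf.copy(), bf.copy()
                    up[r] += eps[r]
                    dn[r] -= eps[r]
                    gu, gd = score_free(up), score_free(dn)
                    if gu is None or gd is None:
                        ok = False
                        break
                    J[:, r] = (gu - gd) / (2 * eps[r])
                if not ok:
                    break
                try:
                    delta_b = np.linalg.solve(J, -g)
                except np.linalg.LinAlgError:
                    break
                improved = False
                for _ in range(20):
                    g_new = score_free(bf + delta_b)
                    if g_new is not None and \
                            np.max(np.abs(g_new)) < np.max(np.abs(g)):
                        bf, g, improved = bf + delta_b, g_new, True
                        break
                    delta_b *= 0.5
                if not improved:
                    break
            return bf, g

        def adopt(bf: np.ndarray) -> None:
            nonlocal beta, llpen, score, info, converged
            cand = beta.copy()
            cand[free] = bf
            try:
                cll, cscore, cinfo = _state(cand, X, y, w, names)
            except SingularInformationError:
                return
            if np.max(np.abs(cscore[free])) < np.max(np.abs(score[free])):
                beta, llpen, score, info = cand, cll, cscore, cinfo
            converged = bool(np.max(np.abs(score[free])) < opts.tol_score)

        bf, _ = fd_newton(beta[free], score[free])
        adopt(bf)
        if not converged:
            # fall back to quasi-Newton ascent of l* with the exact
            # gradient, then re-polish
            def neg(bf: np.ndarray):
                full = beta.copy()
                full[free] = bf
                try:
                    ll, sc, _ = _state(full, X, y, w, names)
                except SingularInformationError:
                    return np.inf, np.zeros(free.size)
                return -ll, -sc[free]

            res = optimize.minimize(neg, beta[free], jac=True, method="BFGS",
                                    options={"gtol": opts.tol_score,
                                             "maxiter": 500})
            adopt(np.asarray(res.x))
            if not converged:
                bf, _ = fd_newton(beta[free], score[free])
                adopt(bf)
    if not converged:
        warnings.warn(
            f"Firth solver did not converge in {opts.max_iter} iterations "
            f"(max |score| = {np.max(np.abs(score[free])):.3g})"
            if free.size else "Firth solver did not converge",
            RuntimeWarning,
        )
    cov = linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return FirthFit(
        beta=beta,
        se_wald=se,
        loglik_pen=llpen,
        converged=converged,
        n_iter=n_iter,
        names=list(names) if names else [f"x{j}" for j in range(p)],
    )


def _profile_value(X, y, w, opts, names, j, value, start) -> float:
    """Max of l* over the other coefficients with coefficient j pinned."""
    fit = fit_firth(
        X, y, weights=w, options=opts, names=names, fixed={j: value}, beta0=start
    )
    return fit.loglik_pen


def profile_ci(
    X: np.ndarray,
    y: np.ndarray,
    fit: FirthFit,
    j: int,
    level: float | None = None,
    weights: np.ndarray | None = None,
    options: FirthOptions | None = None,
) -> tuple[float, float, str]:
    """Profile penalized-likelihood interval for coefficient ``j``.

    The endpoints solve ``2 (l*(beta_hat) - l*_profile(b)) = chi2_1(level)``
    by root bracketing from the estimate outwards (Wald-scaled steps) and
    Brent refinement. A root that cannot be bracketed within +/-20 on the
    log-odds scale yields an open bound (+/-inf) with a flag.

    Returns (lo, hi, flag) where flag is "", "open_lo", "open_hi" or both.
    """
    opts = options or FirthOptions()
    level = opts.ci_level if level is None else level
    w = None if weights is None else np.asarray(weights, dtype=float)
    target = fit.loglik_pen - 0.5 * stats.chi2.ppf(level, 1)
    bhat = fit.beta[j]
    step0 = max(fit.se_wald[j], 1e-2)

    def drop(b: float, start: np.ndarray) -> float:
        return _profile_value(X, y, w, opts, fit.names, j, b, start) - target

    flags = []
    bounds = []
    for sign in (-1.0, 1.0):
        lo_b, f_lo = bhat, fit.loglik_pen - target  # > 0 at the MLE
        start = fit.beta.copy()
        found = None
        stepsz = step0
        b = bhat
        while abs(b - bhat) < 20.0 + step0:
            b = b + sign * stepsz
            f = drop(b, start)
            if f < 0.0:
                found = (b, lo_b) if sign < 0 else (lo_b, b)
                break
            lo_b, f_lo = b, f
            stepsz *= 1.6
        if found is None:
            flags.append("open_lo" if sign < 0 else "open_hi")
            bounds.append(-np.inf if sign < 0 else np.inf)
            continue
        a, c = found
        root = optimize.brentq(
            lambda b: drop(b, fit.beta.copy()), a, c, xtol=1e-9, rtol=1e-12
        )
        bounds.append(root)
    return bounds[0], bounds[1], ",".join(flags)


def penalized_lrt_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    fit: FirthFit,
    j: int,
    weights: np.ndarray | None = None,
    options: FirthOptions | None = None,
) -> tuple[float, float, bool]:
    """Penalized likelihood-ratio test of ``beta_j = 0``.

    Returns (p, statistic, restricted_converged). The restricted maximum
    pins coefficient j at zero and re-maximizes l* over the rest with the
    same solver.
    """
    opts = options or FirthOptions()
    w = None if weights is None else np.asarray(weights, dtype=float)
    start = fit.beta.copy()
    start[j] = 0.0
    rfit = fit_firth(
        X, y, weights=w, options=opts, names=fit.names, fixed={j: 0.0}, beta0=start
    )
    stat = max(0.0, 2.0 * (fit.loglik_pen - rfit.loglik_pen))
    return float(stats.chi2.sf(stat, 1)), stat, rfit.converged


def build_group_design(
    table,
    group_col: str = "group",
    sex_col: str = "sex",
    modifier_col: str = "modifier_count",
    include_covariates: bool = True,
):
    """Treatment-coded design matrix: intercept, group B..F indicators
    (A = reference), sex (male = 1) and modifier-allele count.

    Empty group levels are dropped with a warning. Returns
    (X, names, levels) where ``levels`` are the group levels represented
    by an indicator column.
    """
    import pandas as pd  # local import keeps module load light

    groups = pd.Categorical(table[group_col], categories=GROUP_ORDER)
    if groups.isna().any():
        bad = sorted(set(table[group_col]) - set(GROUP_ORDER))
        raise ValueError(f"unknown genotype groups: {bad}")
    present = [g for g in GROUP_ORDER if (groups == g).any()]
    levels = [g for g in present if g != "A"]
    for g in GROUP_ORDER[1:]:
        if g not in present:
            warnings.warn(f"group level {g} is empty and was dropped", RuntimeWarning)
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for g in levels:
        cols.append((groups == g).astype(float))
        names.append(f"group_{g}")
    if include_covariates:
        sex = table[sex_col]
        if sex.dtype.kind in "if":
            cols.append(np.asarray(sex, dtype=float))
        else:
            cols.append((sex == "male").to_numpy(dtype=float))
        names.append("sex_male")
        cols.append(np.asarray(table[modifier_col], dtype=float))
        names.append("modifier_count")
    X = np.column_stack(cols)
    return X, names, levels


def fit_group_model(
    table,
    options: FirthOptions | None = None,
    include_covariates: bool = True,
    ci: bool = True,
    pvalues: bool = True,
):
    """Fit the genotype-group Firth model and tabulate per-group results.

    ``table`` is a DataFrame with columns ``label`` ("case"/"control"),
    ``group`` (A-F), ``sex`` ("male"/"female") and ``modifier_count``.
    Group A is the reference: its odds ratio is fixed at 1 by construction
    and reported without interval or p-value. Estimates are exponentiated
    to the odds-ratio scale.
    """
    import pandas as pd

    opts = options or FirthOptions()
    y = (table["label"] == "case").to_numpy(dtype=float)
    if y.min() == y.max():
        warnings.warn("response is constant; estimates are penalty-driven", RuntimeWarning)
    X, names, levels = build_group_design(table, include_covariates=include_covariates)
    fit = fit_firth(X, y, options=opts, names=names)

    rows = []
    ngrp = table.groupby("group", observed=True)["label"]
    counts = {
        g: (int((sub == "case").sum()), int((sub == "control").sum()))
        for g, sub in ngrp
    }
    rows.append({
        "group": "A", "n_cases": counts.get("A", (0, 0))[0],
        "n_controls": counts.get("A", (0, 0))[1],
        "OR": 1.0, "CI_lo": np.nan, "CI_hi": np.nan, "p": np.nan,
        "converged": fit.converged,
    })
    ci_arr = np.full((X.shape[1], 2), np.nan)
    p_arr = np.full(X.shape[1], np.nan)
    flags = [""] * X.shape[1]
    for g in levels:
        jidx = names.index(f"group_{g}")
        lo = hi = np.nan
        if ci:
            lo, hi, flag = profile_ci(X, y, fit, jidx, options=opts)
            ci_arr[jidx] = (lo, hi)
            flags[jidx] = flag
        pval = np.nan
        if pvalues:
            pval, _, _ = penalized_lrt_pvalue(X, y, fit, jidx, options=opts)
            p_arr[jidx] = pval
        ncase, nctrl = counts.get(g, (0, 0))
        rows.append({
            "group": g, "n_cases": ncase, "n_controls": nctrl,
            "OR": float(np.exp(fit.beta[jidx])),
            "CI_lo": float(np.exp(lo)), "CI_hi": float(np.exp(hi)),
            "p": pval, "converged": fit.converged,
        })
    fit.ci_profile = ci_arr
    fit.p_lrt = p_arr
    fit.ci_flags = flags
    return pd.DataFrame(rows), fit
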