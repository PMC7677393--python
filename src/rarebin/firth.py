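"""Firth-penalized logistic regression for sparse carrier tables.

Maximizes the Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 * log det I(beta),

with I the Fisher information, by damped Newton iteration on Firth's
modified score. The penalty keeps the carrier log-odds finite under
complete or quasi-separation (zero cells), which is the regime of
ultra-rare case-only variants. Confidence intervals invert the penalized
likelihood-ratio statistic at the chi-square(1) 0.95 quantile (profile
intervals; Wald intervals are meaningless under separation). Reported
upper bounds may be truncated to a conventional cap (999 on the
odds-ratio scale) with a flag.

For a saturated 2x2 table the penalized estimate has a closed form: the
Haldane-corrected cross-product ratio
(a + 1/2)(d + 1/2) / ((b + 1/2)(c + 1/2)), which `firth_2x2` uses as a
fast path; its profile CI inverts the corrected-count binomial
likelihood, which equals the penalized likelihood up to an additive
constant.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2

from rarebin.containers import ContingencyTable2x2, FirthFit

_CHI2_95_HALF = float(chi2.ppf(0.95, 1)) / 2.0  # 1.9207...


def _check_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first offending column for the error message
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValueError(f"design matrix is rank deficient at column {j - 1}")
    return


def _penalized_parts(X, k, n, beta):
    eta = X @ beta
    p = expit(eta)
    w = n * p * (1.0 - p)
    XtWX = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return p, w, XtWX, -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.sum(
            np.where(k > 0, k * np.log(p), 0.0)
            + np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
        )
    return p, w, XtWX, ll + 0.5 * logdet


def _modified_score(X, k, n, p, w, XtWX):
    A_inv = np.linalg.inv(XtWX)
    h = w * np.einsum("ij,jk,ik->i", X, A_inv, X)
    return X.T @ (k - n * p + h * (0.5 - p))


def _newton(
    X: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    beta0: Optional[np.ndarray] = None,
    free: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> Tuple[np.ndarray, float, np.ndarray, int, bool]:
    """Damped Newton ascent of the penalized log-likelihood.

    ``free`` masks the coefficients being updated (profile fits fix the
    rest). Returns (beta, loglik, information, iterations, converged).
    """
    m = X.shape[1]
    if beta0 is None:
        beta = np.zeros(m)
        # start the intercept at the smoothed marginal logit
        ktot, ntot = k.sum(), n.sum()
        beta[0] = np.log((ktot + 0.5) / (ntot - ktot + 0.5))
    else:
        beta = beta0.astype(float).copy()
    if free is None:
        free = np.ones(m, dtype=bool)
    p, w, XtWX, ll = _penalized_parts(X, k, n, beta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        U = _modified_score(X, k, n, p, w, XtWX)[free]
        if np.max(np.abs(U)) < tol:
            converged = True
            break
        A = XtWX[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(A, U)
        except np.linalg.LinAlgError:
            break
        # trust-region style cap on the step length
        norm = np.max(np.abs(delta))
        if norm < 1e-9:  # remaining movement below any reported precision
            converged = True
            break
        if norm > 5.0:
            delta *= 5.0 / norm
        step = 1.0
        improved = False
        for _ in range(25):
            trial = beta.copy()
            trial[free] += step * delta
            p2, w2, XtWX2, ll2 = _penalized_parts(X, k, n, trial)
            if ll2 > ll:
                beta, p, w, XtWX, ll = trial, p2, w2, XtWX2, ll2
                improved = True
                break
            step *= 0.5
        if not improved:
            # ascent stalled at the numerical noise floor of the objective;
            # accept if the outstanding Newton step is already negligible
            converged = norm < 1e-7
            break
    if not converged:
        # XtWX is only an approximation to the penalized Hessian; on nearly
        # degenerate tables the damped Newton ascent can stall short of the
        # score tolerance. Polish with quasi-Newton on the exact gradient.
        from scipy.optimize import minimize

        def neg(bfree):
            full = beta.copy()
            full[free] = bfree
            _, _, _, llv = _penalized_parts(X, k, n, full)
            return -llv

        def grad(bfree):
            full = beta.copy()
            full[free] = bfree
            pp, ww, AA, _ = _penalized_parts(X, k, n, full)
            return -_modified_score(X, k, n, pp, ww, AA)[free]

        res = minimize(neg, beta[free], jac=grad, method="BFGS",
                       options={"gtol": tol, "maxiter": 200})
        if -res.fun >= ll:
            beta = beta.copy()
            beta[free] = res.x
            p, w, XtWX, ll = _penalized_parts(X, k, n, beta)
            converged = bool(np.max(np.abs(
                _modified_score(X, k, n, p, w, XtWX)[free])) < 10 * tol)
    return beta, ll, XtWX, it, converged


def _profile_value(X, k, n, j, bj, beta_init):
    free = np.ones(X.shape[1], dtype=bool)
    free[j] = False
    start = beta_init.copy()
    start[j] = bj
    _, ll, _, _, _ = _newton(X, k, n, beta0=start, free=free)
    return ll


def _profile_bound(X, k, n, j, beta_hat, ll_max, se, upper: bool) -> float:
    """Root of the penalized LR statistic on one side of the estimate."""
    target = ll_max - _CHI2_95_HALF
    direction = 1.0 if upper else -1.0
    step = max(se, 0.5) if np.isfinite(se) else 1.0
    x0 = beta_hat[j]
    f0 = 0.0  # ll_max - target > 0 at the estimate
    for _ in range(200):
        x1 = x0 + direction * step
        f1 = _profile_value(X, k, n, j, x1, beta_hat) - target
        if f1 < 0:
            lo, hi = (x0, x1) if upper else (x1, x0)
            return float(
                brentq(
                    lambda b: _profile_value(X, k, n, j, b, beta_hat) - target,
                    lo,
                    hi,
                    xtol=1e-6,
                )
            )
        x0, f0 = x1, f1
        step *= 1.6
    return direction * np.inf  # likelihood never dropped: unbounded side


def firth_fit(
    X: np.ndarray,
    y: np.ndarray,
    coef: int = 1,
    trials: Optional[np.ndarray] = None,
    ci: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FirthFit:
    """Fit a Firth-penalized logistic model; report coefficient ``coef``.

    ``X`` must contain an intercept column; rows may be grouped binomial
    observations when ``trials`` is given (then ``y`` holds success
    counts). The returned odds ratio and profile CI are for ``X[:, coef]``
    (the carrier indicator in the standard design).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = np.ones(X.shape[0]) if trials is None else np.asarray(trials, dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("successes must lie in [0, trials]")
    _check_rank(X)
    beta, ll, XtWX, it, converged = _newton(X, y, n, tol=tol, max_iter=max_iter)
    try:
        se = float(np.sqrt(np.linalg.inv(XtWX)[coef, coef]))
    except np.linalg.LinAlgError:
        se = np.inf
    b = float(beta[coef])
    if ci and converged:
        lo = _profile_bound(X, y, n, coef, beta, ll, se, upper=False)
        hi = _profile_bound(X, y, n, coef, beta, ll, se, upper=True)
    else:
        lo, hi = -np.inf, np.inf
    return FirthFit(
        beta=b,
        se=se,
        or_=float(np.exp(b)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        ci_capped=False,
        converged=converged,
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Fast saturated 2x2 path


def _ll_2x2(a5, c5, b5, d5, beta0, beta1):
    """Haldane-corrected-count log-likelihood (= penalized ll + const)."""
    p1 = expit(beta0 + beta1)
    p0 = expit(beta0)
    return (
        a5 * np.log(p1)
        + c5 * np.log1p(-p1)
        + b5 * np.log(p0)
        + d5 * np.log1p(-p0)
    )


def _profile_2x2(a5, c5, b5, d5, beta1):
    """Maximize the corrected-count likelihood over the intercept."""
    beta0 = float(np.log(b5 / d5))  # start at the non-carrier fit
    for _ in range(60):
        p1 = expit(beta0 + beta1)
        p0 = expit(beta0)
        g = a5 - (a5 + c5) * p1 + b5 - (b5 + d5) * p0
        H = (a5 + c5) * p1 * (1 - p1) + (b5 + d5) * p0 * (1 - p0)
        step = g / H
        beta0 += np.clip(step, -4.0, 4.0)
        if abs(g) < 1e-12:
            break
    return _ll_2x2(a5, c5, b5, d5, beta0, beta1)


def firth_2x2(
    table: ContingencyTable2x2, ci: bool = True, cap: Optional[float] = 999.0
) -> FirthFit:
    """Firth fit of the carrier odds ratio from a 2x2 table (fast path).

    The point estimate is the Haldane-corrected cross-product ratio, which
    is exactly the penalized-likelihood maximizer for the saturated 2x2
    design; the profile CI inverts the corrected-count likelihood ratio.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("empty case or control margin")
    a5, b5, c5, d5 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    beta = float(np.log(a5 * d5 / (b5 * c5)))
    # observed information at the fit, using the true group sizes
    n1, n0 = a + c, b + d
    p1, p0 = a5 / (n1 + 1.0), b5 / (n0 + 1.0)
    w1, w0 = n1 * p1 * (1 - p1), n0 * p0 * (1 - p0)
    se = float(np.sqrt(1.0 / w1 + 1.0 / w0)) if w1 > 0 and w0 > 0 else np.inf
    lo, hi = -np.inf, np.inf
    if ci:
        # ll at the joint maximizer: p1 = a5/(a5+c5), p0 = b5/(b5+d5)
        ll_max = (
            a5 * np.log(a5 / (a5 + c5))
            + c5 * np.log(c5 / (a5 + c5))
            + b5 * np.log(b5 / (b5 + d5))
            + d5 * np.log(d5 / (b5 + d5))
        )
        target = ll_max - _CHI2_95_HALF

        def f(b1):
            return _profile_2x2(a5, c5, b5, d5, b1) - target

        sstep = min(se, 4.0) if np.isfinite(se) else 1.0
        for bound_upper in (False, True):
            direction = 1.0 if bound_upper else -1.0
            x0, step = beta, sstep
            found = None
            for _ in range(200):
                x1 = x0 + direction * step
                if f(x1) < 0:
                    lo_b, hi_b = (x0, x1) if bound_upper else (x1, x0)
                    found = float(brentq(f, lo_b, hi_b, xtol=1e-8))
                    break
                x0 = x1
                step *= 1.6
            if bound_upper:
                hi = found if found is not None else np.inf
            else:
                lo = found if found is not None else -np.inf
    fit = FirthFit(
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        ci_capped=False,
        converged=True,
        iterations=0,
    )
    return cap_ci(fit, cap) if cap is not None else fit


def firth_from_counts(
    a: int, b: int, c: int, d: int, ci: bool = True, cap: Optional[float] = 999.0
) -> FirthFit:
    """Convenience wrapper over :func:`firth_2x2`."""
    return firth_2x2(ContingencyTable2x2(a, b, c, d), ci=ci, cap=cap)


def cap_ci(fit: FirthFit, cap: float = 999.0) -> FirthFit:
    """Truncate an unbounded or oversized upper CI to the reporting cap."""
    if fit.ci_high > cap or not np.isfinite(fit.ci_high):
        return FirthFit(
            beta=fit.beta,
            se=fit.se,
            or_=fit.or_,
            ci_low=fit.ci_low,
            ci_high=float(cap),
            ci_capped=True,
            converged=fit.converged,
            iterations=fit.iterations,
        )
    return fit


def design_from_table(table: ContingencyTable2x2):
    """Grouped binomial design equivalent to a 2x2 carrier table:
    rows (carrier, non-carrier) with case counts as successes."""
    X = np.array([[1.0, 1.0], [1.0, 0.0]])
    successes = np.array([table.a, table.b], dtype=float)
    trials = np.array([table.a + table.c, table.b + table.d], dtype=float)
    return X, successes, trials
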