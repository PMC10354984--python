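"""Reusable statistical engine.

Ordinary and empirical-Bayes moderated linear-model inference, the
Benjamini-Hochberg step-up FDR adjustment, and Fisher's method for
combining independent p-values.  Pure library: no file I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "ModerationResult",
    "fit_linear_model",
    "fit_linear_models",
    "moderate_variances",
    "moderated_t_test",
    "bh_adjust",
    "fisher_combine",
    "trigamma_inverse",
]


@dataclass
class ModelFit:
    """Least-squares fit of a single response on a fixed design.

    Attributes
    ----------
    coefficients : (p,) array
        Least-squares coefficient estimates.
    stdev_unscaled : (p,) array
        Design-dependent scale of each coefficient, i.e. the square root
        of the diagonal of ``(X'X)^-1``; the standard error of
        coefficient ``j`` is ``stdev_unscaled[j] * sqrt(s2)``.
    residual_variance : float
        Unbiased residual variance ``s2`` with ``residual_df`` degrees
        of freedom.
    residual_df : int
        ``n - rank(design)``.
    n : int
        Number of observations.
    column_names : list of str
        Names of the design columns, if provided.
    """

    coefficients: np.ndarray
    stdev_unscaled: np.ndarray
    residual_variance: float
    residual_df: int
    n: int
    column_names: list = field(default_factory=list)


@dataclass
class ModerationResult:
    """Empirical-Bayes variance-moderation hyperparameters and posteriors.

    ``posterior_variances[g] = (d0*s0^2 + df[g]*s2[g]) / (d0 + df[g])``;
    ``prior_df`` may be ``inf`` (complete pooling to ``prior_variance``).
    """

    prior_df: float
    prior_variance: float
    posterior_variances: np.ndarray
    total_df: np.ndarray
    no_shrinkage_fallback: bool = False


class RankDeficientDesignError(np.linalg.LinAlgError):
    """Raised when a design matrix is not of full column rank."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


def _check_rank(X: np.ndarray, column_names=None):
    """Return rank; raise RankDeficientDesignError naming offending columns."""
    n, p = X.shape
    # pivoted QR: columns pivoted past the numerical rank are the culprits
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d[0] * max(n, p) * np.finfo(float).eps if d.size and d[0] > 0 else 0.0
    rank = int(np.sum(d > tol))
    if rank < p:
        bad = piv[rank:]
        if column_names is not None:
            bad = [column_names[j] for j in bad]
        raise RankDeficientDesignError(bad)
    return rank


def fit_linear_model(response, design, column_names=None) -> ModelFit:
    """Ordinary least squares of one response vector on a design matrix.

    Parameters
    ----------
    response : (n,) array-like
    design : (n, p) array-like
        Must be of full column rank with ``n > p``.

    Raises
    ------
    RankDeficientDesignError
        If the design is rank deficient.
    ValueError
        If ``n <= rank`` (no residual degrees of freedom).
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"response length {y.shape[0]} != design rows {n}")
    rank = _check_rank(X, column_names)
    if n <= rank:
        raise ValueError(f"need n > rank(design); got n={n}, rank={rank}")
    coef, s2, su, df = _ols_core(y[:, None], X)
    return ModelFit(
        coefficients=coef[:, 0],
        stdev_unscaled=su,
        residual_variance=float(s2[0]),
        residual_df=df,
        n=n,
        column_names=list(column_names) if column_names is not None else [],
    )


def fit_linear_models(responses, design, column_names=None):
    """Vectorised OLS of many responses sharing one design.

    Parameters
    ----------
    responses : (n, m) array
        One column per response (e.g. per probe).
    design : (n, p) array

    Returns
    -------
    coefficients : (p, m) array
    stdev_unscaled : (p,) array
    residual_variance : (m,) array
    residual_df : int
    """
    Y = np.asarray(responses, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"responses rows {Y.shape[0]} != design rows {n}")
    rank = _check_rank(X, column_names)
    if n <= rank:
        raise ValueError(f"need n > rank(design); got n={n}, rank={rank}")
    coef, s2, su, df = _ols_core(Y, X)
    return coef, su, s2, df


def _ols_core(Y, X):
    """QR-based OLS shared by the single- and multi-response entry points."""
    n, p = X.shape
    q, r = np.linalg.qr(X)
    coef = linalg.solve_triangular(r, q.T @ Y)
    resid = Y - X @ coef
    df = n - p
    s2 = np.einsum("ij,ij->j", resid, resid) / df
    rinv = linalg.solve_triangular(r, np.eye(p))
    su = np.sqrt(np.sum(rinv * rinv, axis=1))
    return coef, s2, su, df


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ``trigamma(x) = y`` for ``x > 0`` by Newton iteration.

    Monotone decreasing target, so the iteration is globally convergent
    from the asymptotic starting value.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def moderate_variances(s2, df) -> ModerationResult:
    """Estimate variance-moderation hyperparameters by method of moments.

    Models the per-probe sample variances as scaled inverse-chi-square
    draws around a prior variance ``s0^2`` with prior degrees of freedom
    ``d0``, estimated from the moments of the log sample variances
    (closed-form trigamma inversion).  ``d0 = inf`` is returned when the
    observed log-variance dispersion is at or below its sampling
    expectation (posteriors collapse onto ``s0^2``).

    Parameters
    ----------
    s2 : (m,) array of sample variances (>= 0)
    df : scalar or (m,) array of residual degrees of freedom (>= 1)
    """
    s2 = np.asarray(s2, dtype=float)
    df_arr = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    if np.any(df_arr < 1):
        raise ValueError("degrees of freedom must be >= 1")

    ok = s2 > 0
    if ok.sum() < 2:
        warnings.warn(
            "fewer than 2 positive finite variances; falling back to no shrinkage",
            RuntimeWarning,
        )
        return ModerationResult(
            prior_df=0.0,
            prior_variance=float(np.median(s2)) if s2.size else np.nan,
            posterior_variances=s2.copy(),
            total_df=df_arr.copy(),
            no_shrinkage_fallback=True,
        )

    z = np.log(s2[ok])
    d = df_arr[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(special.polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(e_mean)

    post = _posterior_variances(s2, df_arr, d0, s0_2)
    return ModerationResult(
        prior_df=float(d0),
        prior_variance=float(s0_2),
        posterior_variances=post,
        total_df=df_arr + d0,
    )


def _posterior_variances(s2, df, d0, s0_2):
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_2)
    if d0 == 0:
        return np.asarray(s2, dtype=float).copy()
    return (d0 * s0_2 + df * s2) / (d0 + df)


def moderated_t_test(fit: ModelFit, moderation: ModerationResult, coef_index: int,
                     which: int = 0):
    """Moderated t-statistic, two-sided p and 95% CI for one coefficient.

    ``which`` selects the probe's posterior variance / total df inside
    ``moderation`` when the moderation was computed across many fits.

    Returns
    -------
    (t, p, (ci_low, ci_high))
    """
    if coef_index < 0 or coef_index >= len(fit.coefficients):
        raise IndexError(f"coef_index {coef_index} out of range")
    post = np.atleast_1d(moderation.posterior_variances)[which]
    tdf = np.atleast_1d(moderation.total_df)[which]
    beta = fit.coefficients[coef_index]
    su = fit.stdev_unscaled[coef_index]
    if post <= 0:
        warnings.warn("zero posterior variance; p set to 0", RuntimeWarning)
        return (np.inf if beta > 0 else (-np.inf if beta < 0 else 0.0)), 0.0, (beta, beta)
    se = su * np.sqrt(post)
    t = beta / se
    p = 2.0 * sps.t.sf(abs(t), tdf)
    q = sps.t.ppf(0.975, tdf)
    return float(t), float(p), (float(beta - q * se), float(beta + q * se))


def moderated_t_tests(coefs, stdev_unscaled, moderation: ModerationResult):
    """Vectorised moderated t over many probes sharing one design column.

    Parameters
    ----------
    coefs : (m,) coefficient estimates (one per probe)
    stdev_unscaled : scalar or (m,) unscaled coefficient sd

    Returns
    -------
    t, p, ci_low, ci_high : (m,) arrays
    """
    coefs = np.asarray(coefs, dtype=float)
    su = np.broadcast_to(np.asarray(stdev_unscaled, dtype=float), coefs.shape)
    post = np.asarray(moderation.posterior_variances, dtype=float)
    tdf = np.asarray(moderation.total_df, dtype=float)
    se = su * np.sqrt(post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coefs / se, np.where(coefs == 0, 0.0, np.inf * np.sign(coefs)))
    p = 2.0 * sps.t.sf(np.abs(t), tdf)
    q = sps.t.ppf(0.975, tdf)
    return t, p, coefs - q * se, coefs + q * se


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; output is monotone non-decreasing in the
    input p-values and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_combine(p):
    """Combine independent p-values with Fisher's method.

    ``X2 = -2 * sum(log(p_i))`` referred to chi-square with ``2k``
    degrees of freedom; returns the upper-tail probability.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 passed to fisher_combine; combined p is 0",
                      RuntimeWarning)
        return 0.0
    x2 = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x2, 2 * p.size))
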