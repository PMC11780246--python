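"""Time-invariant logistic exposure-response model and slope inference.

The model is  logit P(responder_i) = beta0 + beta * X_i  with X_i an
exposure metric (CavTE or Cav,ss), fitted by Newton's method on the exact
log-likelihood.  Slope inference is the two-sided Wald test beta/SE against
the standard normal; a likelihood-ratio p-value against the intercept-only
model is reported alongside.  Exposure enters untransformed — the slope
p-value is invariant to rescaling of X, so no centering is applied to the
reported coefficients (the optimiser standardises internally for
conditioning and maps the estimates back exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm
from statsmodels.stats.proportion import proportion_confint

from .metrics import ERDataset

__all__ = [
    "FitResult",
    "DegenerateDataError",
    "fit_logistic",
    "fit_logistic_xy",
    "wald_p",
    "quartile_summary",
]

_MAX_ITER = 100
_LL_RTOL = 1e-10
# |standardised coefficient| beyond which estimates are considered divergent
# (perfect or quasi-perfect separation along x)
_SEPARATION_BOUND = 1e3


class DegenerateDataError(ValueError):
    """Outcome has a single class or exposure is constant: the slope is
    unidentifiable (distinct from separation, where both classes exist but
    x splits them perfectly)."""


@dataclass(frozen=True)
class FitResult:
    """Logistic-fit estimates and slope inference for one ER dataset."""

    beta0: float
    beta: float
    se_beta0: float
    se_beta: float
    z: float
    p_slope: float
    p_slope_lr: float
    loglik: float
    n: int
    n_event: int
    n_censored: int
    n_iter: int
    converged: bool
    separation_detected: bool


def wald_p(beta: float, se: float) -> float:
    """Two-sided Wald p-value, 2*Phi(-|beta/se|)."""
    if se <= 0:
        raise ValueError("standard error must be strictly positive")
    return float(2.0 * norm.sf(abs(beta / se)))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: log(expit) via logaddexp
    return float(-np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)))


def fit_logistic_xy(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Fit logit P(y=1) = beta0 + beta*x by Newton-Raphson.

    Convergence: relative log-likelihood change below 1e-10 within 100
    iterations, with step halving on any likelihood decrease.  Separation
    is flagged when a standardised coefficient exceeds 1e3 while the
    likelihood is still improving, or when the fitted probabilities
    perfectly predict the outcome; the (divergent) estimates are returned
    with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    n_event = int(y.sum())
    if n_event == 0 or n_event == n:
        raise DegenerateDataError("outcome has a single class")
    sx = float(x.std())
    if sx == 0:
        raise DegenerateDataError("exposure is constant")
    mx = float(x.mean())
    xs = (x - mx) / sx
    X = np.column_stack([np.ones(n), xs])

    ybar = n_event / n
    theta = np.array([np.log(ybar / (1 - ybar)), 0.0])
    ll = _loglik(X @ theta, y)
    converged = False
    separation = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ theta
        p = expit(eta)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step halving keeps the likelihood non-decreasing
        alpha = 1.0
        for _ in range(30):
            cand = theta + alpha * step
            ll_new = _loglik(X @ cand, y)
            if ll_new >= ll - 1e-14:
                break
            alpha /= 2.0
        theta = theta + alpha * step
        if np.max(np.abs(theta)) > _SEPARATION_BOUND:
            separation = True
            break
        if abs(ll_new - ll) <= _LL_RTOL * (abs(ll) + 1e-300):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    eta = X @ theta
    p = expit(eta)
    # perfect prediction: the likelihood has no interior maximum
    if np.all(np.abs(y - p) < 1e-4):
        separation = True
        converged = False
    w = p * (1 - p)
    hess = X.T @ (X * w[:, None])
    cov_std = np.linalg.pinv(hess)
    # exact back-transform to the raw-x parameterisation
    A = np.array([[1.0, -mx / sx], [0.0, 1.0 / sx]])
    beta_raw = A @ theta
    cov = A @ cov_std @ A.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    ll = _loglik(eta, y)
    zval = beta_raw[1] / se[1] if se[1] > 0 else np.nan
    p_wald = wald_p(beta_raw[1], se[1]) if se[1] > 0 else np.nan
    ll0 = n_event * np.log(ybar) + (n - n_event) * np.log(1 - ybar)
    p_lr = float(chi2.sf(max(2.0 * (ll - ll0), 0.0), df=1))
    return FitResult(
        beta0=float(beta_raw[0]),
        beta=float(beta_raw[1]),
        se_beta0=float(se[0]),
        se_beta=float(se[1]),
        z=float(zval),
        p_slope=float(p_wald),
        p_slope_lr=p_lr,
        loglik=ll,
        n=n,
        n_event=n_event,
        n_censored=n - n_event,
        n_iter=it,
        converged=converged and not separation,
        separation_detected=separation,
    )


def fit_logistic(dataset: ERDataset) -> FitResult:
    """Fit the logistic ER model to one dataset (exposure vs responder)."""
    return fit_logistic_xy(dataset.exposure, dataset.responder)


def quartile_summary(dataset: ERDataset, alpha: float = 0.05) -> pd.DataFrame:
    """Event proportion by exposure quartile with Wilson confidence limits.

    Bins are formed from the type-7 (linear-interpolation) quartiles of the
    exposure distribution; subjects with exposure exactly at a cut point go
    to the lower bin.  Returns one row per quartile with columns
    ``quartile, lo, hi, median_exposure, n, n_event, prop, ci_lo, ci_hi``;
    ``lo``/``hi`` are the observed exposure range within the bin.
    """
    x = dataset.exposure
    y = dataset.responder
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 subjects for quartile bins")
    cuts = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 / linear
    bins = np.digitize(x, cuts, right=True)
    rows = []
    for q in range(4):
        mask = bins == q
        nq = int(mask.sum())
        eq = int(y[mask].sum())
        if nq:
            lo, hi = float(x[mask].min()), float(x[mask].max())
            med = float(np.median(x[mask]))
            prop = eq / nq
            ci_lo, ci_hi = proportion_confint(eq, nq, alpha=alpha, method="wilson")
        else:
            lo = hi = med = prop = ci_lo = ci_hi = np.nan
        rows.append(
            {
                "quartile": q + 1,
                "lo": lo,
                "hi": hi,
                "median_exposure": med,
                "n": nq,
                "n_event": eq,
                "prop": prop,
                "ci_lo": float(ci_lo) if nq else np.nan,
                "ci_hi": float(ci_hi) if nq else np.nan,
            }
        )
    return pd.DataFrame(rows)
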