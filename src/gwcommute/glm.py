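"""Global Poisson regression and shared likelihood statistics.

Weekly active-commuting hours are rounded to the nearest half hour and
modelled, as counts of half-hour units, with a log-linear Poisson model fit
by iteratively reweighted least squares (IRLS). This module also provides the
fit statistics shared with the geographically weighted model: deviance,
AICc on the deviance scale (D + 2k), Nagelkerke's pseudo-R² and Wald
odds-ratio summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats

__all__ = [
    "GlmFit",
    "discretize_outcome",
    "fit_poisson_glm",
    "poisson_deviance",
    "poisson_loglik",
    "deviance_stats",
    "wald_summary",
]


def discretize_outcome(hours) -> np.ndarray:
    """Convert weekly hours to integer counts of half-hour units.

    Hours are rounded to the nearest 0.5 h (ties rounded half away from
    zero), then expressed as the number of half-hour units, which makes the
    zero-heavy outcome suitable for Poisson regression.

    >>> discretize_outcome([0.0, 2.34, 0.25])
    array([0, 5, 1])
    """
    h = np.asarray(hours, float)
    if np.any(~np.isfinite(h)):
        raise ValueError("hours must be finite")
    if np.any(h < 0):
        raise ValueError("hours must be non-negative")
    # half-away-from-zero on non-negative input: floor(2h + 0.5)
    return np.floor(2.0 * h + 0.5).astype(int)


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    yf = np.asarray(y, float)
    if not np.allclose(yf, np.round(yf)):
        raise ValueError("counts must be integral")
    return yf


def _check_rank(X: np.ndarray, labels) -> None:
    """Raise naming (near-)collinear columns if X is rank deficient."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p; got n={n}, p={p}")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = piv[diag <= tol] if diag.max() > 0 else piv
    if len(bad):
        names = [labels[j] if labels is not None else str(j) for j in np.sort(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {names}")


def poisson_loglik(y, mu, prior_weights=None) -> float:
    """Full Poisson log-likelihood, including the log y! term."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    w = np.ones_like(y) if prior_weights is None else np.asarray(prior_weights, float)
    return float(np.sum(w * (y * np.log(mu) - mu - special.gammaln(y + 1.0))))


def poisson_deviance(y, mu, prior_weights=None) -> float:
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    w = np.ones_like(y) if prior_weights is None else np.asarray(prior_weights, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(w * (ylogy - (y - mu))))


@dataclass
class GlmFit:
    """Result of a (weighted) Poisson IRLS fit with log link."""

    coefficients: np.ndarray
    covariance: np.ndarray
    fitted: np.ndarray           # fitted means λ_i
    deviance: float
    null_deviance: float
    loglik: float
    null_loglik: float
    n: int
    p: int
    labels: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.labels, map(float, self.coefficients))),
            "se": dict(zip(self.labels, map(float, self.se))),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "loglik": self.loglik,
            "n": self.n,
            "p": self.p,
            "converged": self.converged,
        }


def _irls(y, X, prior_weights, offset, tol=1e-8, max_iter=100, start=None):
    """Core IRLS loop for log-link Poisson. Returns (beta, mu, n_iter)."""
    n, p = X.shape
    w = prior_weights
    if start is None:
        # standard mean-initialised working response
        mu = np.maximum(y + 0.5, 0.01)
        eta = np.log(mu) - offset
        z = eta + (y - mu) / mu
        W = w * mu
        beta = linalg.lstsq(X * np.sqrt(W)[:, None], z * np.sqrt(W))[0]
    else:
        beta = np.array(start, float)
    dev_prev = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta + offset
        if np.any(eta > 700):
            raise FloatingPointError("linear predictor overflow in IRLS")
        mu = np.exp(eta)
        dev = poisson_deviance(y, mu, w)
        if abs(dev_prev - dev) <= tol * (abs(dev) + 0.1):
            return beta, mu, it
        dev_prev = dev
        W = w * mu
        z = (eta - offset) + (y - mu) / mu
        WX = X * W[:, None]
        beta = linalg.solve(X.T @ WX, WX.T @ z, assume_a="pos")
    raise RuntimeError(
        f"IRLS did not converge in {max_iter} iterations (last deviance {dev_prev:.6g})"
    )


def fit_poisson_glm(y, X, prior_weights=None, offset=None, labels=None,
                    tol=1e-8, max_iter=100) -> GlmFit:
    """Fit a log-link Poisson regression by IRLS.

    Parameters
    ----------
    y : array of non-negative integer counts.
    X : (n, p) design matrix (include the intercept column explicitly, or use
        a DataFrame whose columns name the terms).
    prior_weights : optional non-negative case weights.
    offset : optional linear-predictor offset.

    The covariance returned is the inverse Fisher information at the optimum.
    """
    if isinstance(X, pd.DataFrame):
        labels = list(X.columns) if labels is None else labels
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    y = _validate_counts(y)
    n, p = X.shape
    if labels is None:
        labels = [f"x{j}" for j in range(p)]
    w = np.ones(n) if prior_weights is None else np.asarray(prior_weights, float)
    if np.any(w < 0):
        raise ValueError("prior weights must be non-negative")
    if np.sum(w > 0) < p:
        raise ValueError("need at least p observations with positive weight")
    off = np.zeros(n) if offset is None else np.asarray(offset, float)
    _check_rank(X[w > 0] * np.sqrt(w[w > 0])[:, None], labels)

    beta, mu, it = _irls(y, X, w, off, tol=tol, max_iter=max_iter)
    W = w * mu
    info = X.T @ (X * W[:, None])
    cov = linalg.inv(info)
    dev = poisson_deviance(y, mu, w)
    ll = poisson_loglik(y, mu, w)

    # intercept-only (null) fit on the same data/weights/offset
    mu0 = np.full(n, np.sum(w * y) / np.sum(w * np.exp(off))) * np.exp(off)
    dev0 = poisson_deviance(y, mu0, w)
    ll0 = poisson_loglik(y, mu0, w)

    return GlmFit(beta, cov, mu, dev, dev0, ll, ll0, n, p,
                  labels=labels, n_iter=it, converged=True)


def deviance_stats(fit: GlmFit = None, k: float = None, *, deviance: float = None,
                   null_deviance: float = None, n: int = None,
                   loglik: float = None, null_loglik: float = None,
                   small_sample_correction: bool = False) -> dict:
    """Deviance-based fit statistics.

    AICc is reported on the deviance scale, ``D + 2k``, with ``k`` the
    (possibly real-valued) effective number of parameters; this is the form
    used to compare the global and geographically weighted fits. An optional
    small-sample correction term ``2k(k+1)/(n-k-1)`` can be switched on.

    Nagelkerke's pseudo-R² uses full log-likelihoods (including the log y!
    term in both numerator and denominator consistently).
    """
    if fit is not None:
        deviance = fit.deviance if deviance is None else deviance
        null_deviance = fit.null_deviance if null_deviance is None else null_deviance
        n = fit.n if n is None else n
        loglik = fit.loglik if loglik is None else loglik
        null_loglik = fit.null_loglik if null_loglik is None else null_loglik
        if k is None:
            k = fit.p
    if deviance is None or k is None:
        raise ValueError("need at least a deviance and an effective parameter count")
    out = {"deviance": float(deviance), "k": float(k)}
    aicc = deviance + 2.0 * k
    if small_sample_correction:
        if n is None or n - k - 1 <= 0:
            raise ValueError("small-sample correction needs n > k + 1")
        aicc += 2.0 * k * (k + 1.0) / (n - k - 1.0)
    out["aicc"] = float(aicc)
    if null_deviance is not None:
        out["deviance_explained"] = (
            0.0 if null_deviance == 0 else float(1.0 - deviance / null_deviance)
        )
    if loglik is not None and null_loglik is not None and n is not None:
        num = 1.0 - np.exp((2.0 / n) * (null_loglik - loglik))
        den = 1.0 - np.exp((2.0 / n) * null_loglik)
        out["nagelkerke_r2"] = float(num / den) if den != 0 else 0.0
    return out


def wald_summary(fit: GlmFit, alpha: float = 0.05) -> pd.DataFrame:
    """Per-coefficient Wald summary: log-odds, OR, CI and two-sided p.

    ORs are ``exp(coefficient)``; confidence limits exponentiate the Wald
    interval on the log scale. Entries with non-finite standard errors are
    flagged unstable.
    """
    se = fit.se
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    beta = fit.coefficients
    with np.errstate(invalid="ignore"):
        tval = beta / se
        p = 2.0 * stats.norm.sf(np.abs(tval))
    unstable = ~np.isfinite(se)
    return pd.DataFrame(
        {
            "log_odds": beta,
            "OR": np.exp(beta),
            "CI_low": np.exp(beta - z * se),
            "CI_high": np.exp(beta + z * se),
            "p": p,
            "unstable": unstable,
        },
        index=fit.labels,
    )
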