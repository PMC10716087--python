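"""Fast profiled-likelihood linear mixed model with a single random intercept.

Used for the per-bin screening fits inside the cross-validated window
search, where hundreds of models are fit per dataset.  The model is

    y_ij = b0 + b1 * x_ij + u_i + e_ij,   u_i ~ N(0, s_b^2), e_ij ~ N(0, s^2)

Profiling: for a fixed variance ratio lam = s_b^2 / s^2 the GLS estimates
and the residual variance have closed forms computable from per-group
sufficient statistics, so the likelihood is maximized by a 1-D search over
log(lam).  Estimates agree with a full ML mixed-model fit; standard errors
use the GLS information with a small-sample residual-df correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RiLmeFit", "fit_random_intercept_lme"]


@dataclass(frozen=True)
class RiLmeFit:
    b: float
    se: float
    t: float
    lam: float
    sigma2: float
    loglik: float


def _gls_pieces(lam, n_i, s1x, s1y, sxx, sxy, syy):
    c = lam / (1.0 + lam * n_i)
    a11 = np.sum(n_i - c * n_i * n_i)
    a12 = np.sum(s1x - c * n_i * s1x)
    a22 = np.sum(sxx - c * s1x * s1x)
    b1 = np.sum(s1y - c * n_i * s1y)
    b2 = np.sum(sxy - c * s1x * s1y)
    yvy = np.sum(syy - c * s1y * s1y)
    det = a11 * a22 - a12 * a12
    beta0 = (a22 * b1 - a12 * b2) / det
    beta1 = (a11 * b2 - a12 * b1) / det
    rss = yvy - (beta0 * b1 + beta1 * b2)
    return beta0, beta1, rss, a11, a12, a22, det


def fit_random_intercept_lme(y: np.ndarray, x: np.ndarray,
                             groups: np.ndarray) -> RiLmeFit:
    """ML fit of the random-intercept model; returns slope, SE and t.

    ``groups`` are integer codes 0..G-1.  The slope must have within-group
    variance (an entirely between-group regressor is not identified here).
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    groups = np.asarray(groups)
    n = y.size
    g = int(groups.max()) + 1
    n_i = np.bincount(groups, minlength=g).astype(np.float64)
    s1x = np.bincount(groups, weights=x, minlength=g)
    s1y = np.bincount(groups, weights=y, minlength=g)
    sxx = np.bincount(groups, weights=x * x, minlength=g)
    sxy = np.bincount(groups, weights=x * y, minlength=g)
    syy = np.bincount(groups, weights=y * y, minlength=g)

    def nll(log_lam):
        lam = np.exp(log_lam)
        _, _, rss, *_ = _gls_pieces(lam, n_i, s1x, s1y, sxx, sxy, syy)
        if rss <= 0:
            return np.inf
        return 0.5 * (n * np.log(rss / n) + np.sum(np.log1p(lam * n_i)))

    opt = minimize_scalar(nll, bounds=(-12.0, 8.0), method="bounded",
                          options={"xatol": 1e-6})
    lam = float(np.exp(opt.x))
    b0, b1, rss, a11, a12, a22, det = _gls_pieces(lam, n_i, s1x, s1y, sxx, sxy, syy)
    sigma2 = rss / max(n - 2, 1)
    var_b1 = sigma2 * a11 / det
    se = float(np.sqrt(var_b1)) if var_b1 > 0 else np.nan
    t = float(b1 / se) if se and np.isfinite(se) and se > 0 else np.nan
    return RiLmeFit(b=float(b1), se=se, t=t, lam=lam,
                    sigma2=float(sigma2), loglik=float(-opt.fun))
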