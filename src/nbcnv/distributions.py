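"""Noise models for binned read counts: NB2, Poisson, Gaussian.

The negative binomial is parameterized by its mean mu and over-dispersion
alpha (NB2): variance = mu + mu**2/alpha, pmf

    P(y) = Gamma(y + a) / (y! Gamma(a)) * (mu/(mu+a))**y * (a/(mu+a))**a ,

which converges to Poisson(mu) as alpha -> infinity.  Whole-genome
amplification makes single-cell read counts strongly over-dispersed, which
is why the NB2 likelihood (with alpha estimated once on a copy-neutral
track) is the fidelity term of the caller.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

from .core import NBParams, ValidationError

_ALPHA_BRACKET = (1e-3, 1e6)


def nb_logpmf(y, mean: float, dispersion: float):
    """Log pmf of NB2(mean, dispersion) at integer counts ``y``.

    Computed via log-gamma (scipy's nbinom with size = dispersion and
    success probability dispersion / (mean + dispersion)).
    """
    if not mean > 0:
        raise ValidationError("mean must be positive")
    if not dispersion > 0:
        raise ValidationError("dispersion must be positive")
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValidationError("counts must be nonnegative")
    p = dispersion / (mean + dispersion)
    out = stats.nbinom.logpmf(y, dispersion, p)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def _nb_profile_score(alpha: float, y: np.ndarray, m: float) -> float:
    # derivative of the profile log-likelihood in alpha with mu fixed at the
    # sample mean (the exact NB2 MLE for mu)
    n = y.size
    return float(
        np.sum(special.digamma(y + alpha)) - n * special.digamma(alpha)
        + n * np.log(alpha / (m + alpha))
    )


def _nb_profile_score_deriv(alpha: float, y: np.ndarray, m: float) -> float:
    n = y.size
    return float(
        np.sum(special.polygamma(1, y + alpha)) - n * special.polygamma(1, alpha)
        + n * (1.0 / alpha - 1.0 / (m + alpha))
    )


def fit_nb_mle(y) -> NBParams:
    """NB2 maximum likelihood fit to a count sample.

    The mean MLE is the sample mean.  The dispersion maximizes the profile
    log-likelihood, located by safeguarded Newton iteration on the digamma
    score from the moment-matched start alpha0 = m^2/(s^2 - m); if Newton
    leaves the bracket [1e-3, 1e6] a bisection (brentq) fallback is used.

    Raises
    ------
    ValidationError
        If the sample is under-dispersed (variance <= mean), for which the
        NB2 dispersion MLE does not exist; a Poisson model is then advised.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 30:
        raise ValidationError("need at least 30 observations to fit dispersion")
    if np.any(y < 0):
        raise ValidationError("counts must be nonnegative")
    m = float(y.mean())
    s2 = float(y.var(ddof=1))
    if not m > 0:
        raise ValidationError("all-zero sample; cannot fit NB")
    if s2 <= m:
        raise ValidationError(
            f"sample is not over-dispersed (variance {s2:.4g} <= mean {m:.4g}); "
            "use a Poisson model instead"
        )
    lo, hi = _ALPHA_BRACKET
    alpha = float(np.clip(m * m / (s2 - m), lo, hi))
    ok = False
    for _ in range(100):
        f = _nb_profile_score(alpha, y, m)
        fp = _nb_profile_score_deriv(alpha, y, m)
        if fp == 0:
            break
        step = f / fp
        new = alpha - step
        if not (lo <= new <= hi) or not np.isfinite(new):
            break
        if abs(new - alpha) / alpha < 1e-8:
            alpha = new
            ok = True
            break
        alpha = new
    if not ok:
        # log-scale bisection fallback; the score is decreasing in alpha
        f_lo = _nb_profile_score(lo, y, m)
        f_hi = _nb_profile_score(hi, y, m)
        if f_lo * f_hi > 0:
            alpha = lo if abs(f_lo) < abs(f_hi) else hi
        else:
            alpha = brentq(
                lambda la: _nb_profile_score(np.exp(la), y, m),
                np.log(lo), np.log(hi), xtol=1e-12,
            )
            alpha = float(np.exp(alpha))
    ll = float(np.sum(nb_logpmf(np.round(y).astype(np.int64), m, alpha))) \
        if np.allclose(y, np.round(y)) else float("nan")
    return NBParams(mean=m, dispersion=float(alpha), loglik=ll)


def fit_poisson_mle(y) -> float:
    """Poisson MLE: the sample mean (warns on an all-zero sample)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("empty sample")
    m = float(y.mean())
    if m == 0:
        warnings.warn("all-zero sample: Poisson mean estimated as 0")
    return m


def fit_gaussian_mle(y) -> tuple[float, float]:
    """Gaussian MLE: sample mean and the 1/n standard deviation."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("empty sample")
    return float(y.mean()), float(y.std(ddof=0))
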