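"""Shifted-gamma response likelihood.

With shape alpha_m = exp(log_alpha_m) and additive-scale mean mu, the response
is modelled as  y + c ~ Gamma(alpha, alpha / (mu + c)),  so E[y] = mu while the
effects stay additive.  The shift c > max plausible |concentration| keeps the
support positive; alpha controls the coefficient of variation 1/sqrt(alpha).
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["gamma_shifted_logpdf", "log_likelihood",
           "dlogpdf_dmu", "dlogpdf_dlogalpha"]


def gamma_shifted_logpdf(y, mu, log_alpha, shift_c):
    """Elementwise log density of the shifted gamma (broadcasting)."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    a = np.exp(np.asarray(log_alpha, float))
    ys = y + shift_c
    ms = mu + shift_c
    return (a * (np.log(a) - np.log(ms)) - gammaln(a)
            + (a - 1.0) * np.log(ys) - a * ys / ms)


def log_likelihood(y, mu, log_alpha, shift_c, mask=None):
    """Sum of shifted-gamma log densities over observed responses.

    ``y``/``mu`` are length-M vectors (or arrays with trailing response axis);
    missing responses (mask False) contribute zero.
    """
    y = np.atleast_1d(np.asarray(y, float))
    mu = np.atleast_1d(np.asarray(mu, float))
    la = np.broadcast_to(np.atleast_1d(np.asarray(log_alpha, float)), y.shape)
    if mask is None:
        mask = np.ones(y.shape, bool)
    mask = np.broadcast_to(np.asarray(mask, bool), y.shape)
    ms = mu + shift_c
    bad = mask & (ms <= 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValueError(
            f"mu + shift_c = {ms[tuple(idx)]:.4g} <= 0 for response index "
            f"{int(idx[-1])}; shift_c={shift_c} is too small")
    ys = y + shift_c
    if np.any(mask & (ys <= 0)):
        raise ValueError("y + shift_c must be positive for observed responses")
    out = np.where(mask, gamma_shifted_logpdf(np.where(mask, y, 1.0),
                                              np.where(mask, mu, 1.0),
                                              la, shift_c), 0.0)
    return float(out.sum())


def dlogpdf_dmu(y, mu, alpha, shift_c):
    """d log f / d mu of the shifted gamma (alpha on natural scale)."""
    ys = y + shift_c
    ms = mu + shift_c
    return alpha * (ys - ms) / (ms * ms)


def dlogpdf_dlogalpha(y, mu, alpha, shift_c):
    """d log f / d log(alpha)."""
    ys = y + shift_c
    ms = mu + shift_c
    return alpha * (np.log(alpha) - np.log(ms) + 1.0 - digamma(alpha)
                    + np.log(ys) - ys / ms)
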