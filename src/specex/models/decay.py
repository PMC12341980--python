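"""Exponential decay A(t) = A0 exp(-k t) with a lognormal decay rate.

The simplest fixture: a closed-form solution whose pushforward PDF under the
lognormal rate distribution is also available in closed form, so surrogate
and Monte-Carlo output distributions can be compared against exact answers.
"""

from __future__ import annotations

import numpy as np

from ..transforms import ParameterSpec

__all__ = ["decay_model", "decay_pdf_analytic", "DECAY_SPEC"]

#: fixture distribution of the decay rate (arithmetic mean / sd)
DECAY_SPEC = ParameterSpec.lognormal("k", mu=0.5, sigma=0.2)


def decay_model(A0: float, k: float, t):
    """Concentration trajectory A(t) = A0 exp(-k t)."""
    if A0 <= 0:
        raise ValueError("A0 must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = A0 * np.exp(-k * t)
    return out if out.ndim else float(out)


def decay_pdf_analytic(t: float, spec: ParameterSpec, a_grid, A0: float = 1.0):
    """Exact PDF of A(t) by change of variables from the rate distribution.

    For t > 0, a = A0 exp(-k t) is monotone in k, so
    P_A(a) = P_k(k(a)) * |dk/da| with k(a) = -ln(a / A0) / t and
    |dk/da| = 1 / (a t).
    """
    if t <= 0:
        raise ValueError("the output distribution is degenerate at t = 0")
    a = np.asarray(a_grid, dtype=float)
    out = np.zeros_like(a)
    # mass above A0 would require a negative rate, impossible for lognormal k
    ok = a > 0
    k = np.where(ok, -np.log(np.where(ok, a, 1.0) / A0) / t, 0.0)
    pk = _lognormal_pdf(k, spec)
    out[ok] = pk[ok] / (a[ok] * t)
    return out


def _lognormal_pdf(k, spec: ParameterSpec):
    """PDF of the mean/sd-parameterised lognormal at k (0 for k <= 0)."""
    if spec.family != "lognormal":
        raise ValueError("spec must be lognormal")
    mu = spec.params["mu"]
    alpha = spec.alpha
    k = np.asarray(k, dtype=float)
    out = np.zeros_like(k)
    pos = k > 0
    # k = mu exp(alpha theta - alpha^2/2)  =>  log k ~ N(log mu - alpha^2/2, alpha)
    loc = np.log(mu) - 0.5 * alpha**2
    kp = k[pos]
    out[pos] = np.exp(-0.5 * ((np.log(kp) - loc) / alpha) ** 2) / (
        kp * alpha * np.sqrt(2 * np.pi))
    return out
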