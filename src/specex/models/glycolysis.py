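"""Glycolytic oscillator: a two-species negative-feedback model.

    dx/dt = -x + alpha * y + x^2 y
    dy/dt = beta - alpha * y - x^2 y

x and y are the ADP and F6P concentrations.  Depending on (alpha, beta) the
system settles on a stable fixed point or a stable limit cycle, so the
response surface contains a Hopf bifurcation.  Fixture uncertainty:
alpha ~ U(0.1, 0.5) (Legendre basis), beta ~ Lognormal(0.3, 0.1) (Hermite
basis), making this the mixed-basis example.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

from ..transforms import ParameterSpec

__all__ = ["glycolysis_model", "glycolysis_fixed_point", "GLYCOLYSIS_SPECS"]

GLYCOLYSIS_SPECS = [
    ParameterSpec.uniform("alpha", 0.1, 0.5),
    ParameterSpec.lognormal("beta", mu=0.3, sigma=0.1),
]


def glycolysis_fixed_point(alpha: float, beta: float):
    """The unique fixed point (x*, y*) = (beta, beta / (alpha + beta^2))."""
    return beta, beta / (alpha + beta**2)


def _rhs(s, t, alpha, beta):
    x, y = s
    flux = alpha * y + x * x * y
    return (-x + flux, beta - flux)


def glycolysis_model(alpha: float, beta: float, t_grid=None,
                     x0=(1.0, 1.0), rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Trajectories (x, y); shape (2, len(t_grid))."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if t_grid is None:
        t_grid = np.linspace(0.0, 20.0, 201)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = odeint(_rhs, list(x0), t_grid, args=(alpha, beta), rtol=rtol, atol=atol)
    if not np.all(np.isfinite(sol)):
        raise FloatingPointError("glycolysis integration produced non-finite values")
    return sol.T
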