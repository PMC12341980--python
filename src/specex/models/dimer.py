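"""Dimerisation network: two monomers reversibly binding into a dimer.

    dx1/dt = k1 - k2 x1 x2 + k3 x3 - k5 x1
    dx2/dt = k4 - k2 x1 x2 + k3 x3 - k5 x2
    dx3/dt = k2 x1 x2 - k3 x3 - k5 x3

Monomers x1, x2 are produced at k1, k4, bind at k2 into the dimer x3 which
unbinds at k3; everything is degraded at k5.  Fixture parameter uncertainty:
lognormal with mean 0.1, sd 0.1 for k1, k4, k5 and mean 0.4, sd 0.1 for
k2, k3.  Initial conditions are zero.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

from ..transforms import ParameterSpec

__all__ = ["dimer_model", "DIMER_SPECS"]

DIMER_SPECS = [
    ParameterSpec.lognormal("k1", mu=0.1, sigma=0.1),
    ParameterSpec.lognormal("k2", mu=0.4, sigma=0.1),
    ParameterSpec.lognormal("k3", mu=0.4, sigma=0.1),
    ParameterSpec.lognormal("k4", mu=0.1, sigma=0.1),
    ParameterSpec.lognormal("k5", mu=0.1, sigma=0.1),
]


def _rhs(x, t, k1, k2, k3, k4, k5):
    x1, x2, x3 = x
    bind = k2 * x1 * x2 - k3 * x3
    return (k1 - bind - k5 * x1,
            k4 - bind - k5 * x2,
            bind - k5 * x3)


def dimer_model(k, t_grid=None, rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Trajectories (x1, x2, x3) from zero initial conditions.

    ``k`` is the rate vector (k1..k5); returns an array of shape
    (3, len(t_grid)).  Uses lsoda, which switches automatically between
    stiff and non-stiff integration.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (5,) or np.any(k <= 0):
        raise ValueError("need five positive rates k1..k5")
    if t_grid is None:
        t_grid = np.linspace(0.0, 10.0, 21)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = odeint(_rhs, [0.0, 0.0, 0.0], t_grid, args=tuple(k),
                 rtol=rtol, atol=atol)
    if not np.all(np.isfinite(sol)):
        raise FloatingPointError("dimer integration produced non-finite values")
    return sol.T
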