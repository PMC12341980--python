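"""Schnakenberg reaction-diffusion system on a 1-D line of coupled cells.

    du/dt = L u + gamma * (alpha - u + u^2 v)
    dv/dt = d L v + gamma * (beta - u^2 v)

u is autocatalytically produced, consuming v; L is the discrete Laplacian on
a line of cells (zero-flux boundaries, unit spacing) and d the diffusion
ratio.  For parameter combinations inside the Turing space the homogeneous
steady state (u0, v0) = (alpha + beta, beta / (alpha + beta)^2) is stable
without diffusion but unstable against some spatial mode, and the system
relaxes to a periodic pattern.

Fixture: beta = 1, gamma = 5, d = 20 on 20 cells, with alpha the single
uncertain parameter, alpha ~ U(0.001, 0.45).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

from ..transforms import ParameterSpec

__all__ = ["schnakenberg_model", "turing_space_test", "laplacian_1d",
           "SCHNAKENBERG_SPEC", "SCHNAKENBERG_DEFAULTS"]

SCHNAKENBERG_SPEC = ParameterSpec.uniform("alpha", 0.001, 0.45)
SCHNAKENBERG_DEFAULTS = {"beta": 1.0, "gamma": 5.0, "d": 20.0, "n_cells": 20}


def laplacian_1d(n: int) -> np.ndarray:
    """Discrete Laplacian on a line of n cells with zero-flux boundaries."""
    L = np.diag(-2.0 * np.ones(n)) + np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
    L[0, 0] = L[-1, -1] = -1.0
    return L


def _reaction_jacobian(alpha: float, beta: float, gamma: float):
    u0 = alpha + beta
    v0 = beta / u0**2
    fu = gamma * (-1.0 + 2.0 * u0 * v0)
    fv = gamma * u0**2
    gu = -2.0 * gamma * u0 * v0
    gv = -gamma * u0**2
    return np.array([[fu, fv], [gu, gv]])


def turing_space_test(alpha: float, beta: float = 1.0, gamma: float = 5.0,
                      d: float = 20.0, n_cells: int = 20) -> bool:
    """Whether (alpha, beta, gamma, d) supports a Turing pattern on the grid.

    Checks the standard conditions: the homogeneous steady state is stable
    without diffusion, and at least one non-zero spatial mode of the discrete
    Laplacian is linearly unstable with diffusion (1, d).
    """
    J = _reaction_jacobian(alpha, beta, gamma)
    if np.trace(J) >= 0 or np.linalg.det(J) <= 0:
        return False
    ell = np.linalg.eigvalsh(laplacian_1d(n_cells))  # <= 0
    D = np.diag([1.0, d])
    for l in ell:
        if l > -1e-12:
            continue
        growth = np.linalg.eigvals(J + l * D)
        if np.max(growth.real) > 0:
            return True
    return False


def schnakenberg_model(alpha: float, beta: float = 1.0, gamma: float = 5.0,
                       d: float = 20.0, n_cells: int = 20, seed: int = 0,
                       steady_tol: float = 1e-6, t_window: float = 10.0,
                       t_max: float = 5000.0) -> np.ndarray:
    """Steady-state v profile (length n_cells).

    Starts from the homogeneous steady state with 1% seeded multiplicative
    noise and integrates until the relative state change over a window of
    ``t_window`` time units drops below ``steady_tol``.
    """
    if min(alpha, beta, gamma, d) <= 0:
        raise ValueError("all parameters must be > 0")
    L = laplacian_1d(n_cells)
    u0 = alpha + beta
    v0 = beta / u0**2
    rng = np.random.default_rng(seed)
    state = np.concatenate([np.full(n_cells, u0), np.full(n_cells, v0)])
    state *= 1.0 + 0.01 * rng.standard_normal(state.size)

    def rhs(s, t):
        u, v = s[:n_cells], s[n_cells:]
        uv2 = u * u * v
        du = L @ u + gamma * (alpha - u + uv2)
        dv = d * (L @ v) + gamma * (beta - uv2)
        return np.concatenate([du, dv])

    t = 0.0
    while t < t_max:
        sol = odeint(rhs, state, [0.0, t_window], rtol=1e-8, atol=1e-10)
        new = sol[-1]
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("integration produced non-finite values")
        scale = np.max(np.abs(new)) + 1e-12
        if np.max(np.abs(new - state)) / scale < steady_tol:
            return new[n_cells:]
        state = new
        t += t_window
    raise ArithmeticError(f"no steady state reached within t = {t_max}")
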