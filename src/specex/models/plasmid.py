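"""Plasmid transfection model with correlated bivariate-Poisson uptake.

Cells are transfected with two plasmids: pl1 carries the induction construct
(n copies per cell), pl2 the reporter construct (m copies).  Per plasmid
composition (n, m) the intracellular dynamics are

    dx_{n,m}/dt = n * alpha * I(t) - beta * x_{n,m}
    dy_{n,m}/dt = m * gamma * x_{n,m} / (1 + eta * x_{n,m}) - (mu + kappa) * y_{n,m}

with induction I(t) = 1 for t >= 0.  The population is tracked by the pool
tensor Q_{n,m} (number of cells with composition (n, m)), which grows
logistically while plasmids are diluted by division:

    dQ/dt = omega * (1 - |Q|_1 / Nmax) * (2 P Q P^T - Q),

where P[k_daughter, k_mother] is the binomial partition matrix (equal
division q = 0.5), so |Q|_1 itself follows logistic growth.  A secreted bulk
reporter S accumulates as dS/dt = v * kappa * sum Q y - delta * S.

Because y_{n,m} is linear in m, only the n-indexed profiles w_n(t) (the
y response per reporter plasmid) are integrated: y_{n,m}(t) = m * w_n(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import odeint

from ..correlated import BivariatePoissonDist

__all__ = ["PlasmidFixture", "plasmid_model", "PlasmidSolution",
           "partition_matrix", "y_steady_state", "readout_histogram"]


def partition_matrix(n_max: int, q: float = 0.5) -> np.ndarray:
    """P[k, n]: probability a daughter inherits k of the mother's n plasmids."""
    n = np.arange(n_max + 1)
    return stats.binom.pmf(n[:, None], n[None, :], q)


@dataclass(frozen=True)
class PlasmidFixture:
    """Rates and population settings; defaults follow the single-cell readout
    scenario (non-secreted reporter, kappa = 0)."""

    alpha: float = 2.0       # x production per pl1 plasmid [1/(V h)]
    beta: float = 2.0        # x degradation [1/h]
    gamma: float = 6.0       # y production per pl2 plasmid [1/h]
    eta: float = 0.5         # expression-capacity saturation [1/V]
    mu: float = 1.5          # y degradation [1/h]
    kappa: float = 0.0       # reporter secretion [1/h]; 3.0 for bulk readout
    delta: float = 0.01      # bulk reporter decay [1/h]
    v: float = 1e-8          # volume correction for the bulk
    omega: float = 0.034     # cell growth rate [1/h] (20 h doubling time)
    q: float = 0.5           # equal division
    N0: float = 1e5          # initial population size
    Nmax: float = 1e6        # carrying capacity
    g: float = 5.0           # histogram binning width


def y_steady_state(fix: PlasmidFixture, n, m):
    """y* = m gamma x* / ((1 + eta x*)(mu + kappa)) with x* = n alpha / beta."""
    n = np.asarray(n, dtype=float)
    m = np.asarray(m, dtype=float)
    xs = n * fix.alpha / fix.beta
    out = m * fix.gamma * xs / ((1.0 + fix.eta * xs) * (fix.mu + fix.kappa))
    return out if out.ndim else float(out)


def x_exact(fix: PlasmidFixture, n, t):
    """x_{n,.}(t) = (n alpha / beta)(1 - exp(-beta t)) from x(0) = 0, I = 1."""
    n = np.asarray(n, dtype=float)
    t = np.asarray(t, dtype=float)
    return np.multiply.outer(n * fix.alpha / fix.beta, 1.0 - np.exp(-fix.beta * t))


@dataclass
class PlasmidSolution:
    """Trajectories of the plasmid model on a time grid."""

    fixture: PlasmidFixture
    uptake: BivariatePoissonDist
    t: np.ndarray
    w: np.ndarray          # (n_max+1, T): y per reporter plasmid, by n
    Q: np.ndarray          # (T, n_max+1, n_max+1)
    S: np.ndarray          # (T,)

    @property
    def n_max(self) -> int:
        return self.w.shape[0] - 1

    def y(self, n: int, m: int) -> np.ndarray:
        """Trajectory y_{n,m}(t) = m * w_n(t)."""
        return m * self.w[n]

    def readout_histogram(self, t_index: int, g: float | None = None):
        """Binned single-cell reporter distribution P(z, t) at a grid time.

        z = g * floor(y_{n,m}(t) / g); returns (bin levels, probabilities).
        """
        g = self.fixture.g if g is None else g
        nm = np.arange(self.n_max + 1)
        y = nm[None, :] * self.w[:, t_index][:, None]   # y[n, m]
        z = g * np.floor(y / g)
        Q = self.Q[t_index]
        wgt = Q / Q.sum()
        levels = np.unique(z)
        probs = np.array([wgt[z == lv].sum() for lv in levels])
        return levels, probs


def plasmid_model(fix: PlasmidFixture, uptake: BivariatePoissonDist,
                  t_grid=None) -> PlasmidSolution:
    """Integrate per-pool reporter dynamics, the pool tensor Q, and bulk S.

    The initial population is distributed over compositions (n, m) according
    to the uptake PMF truncated at its n_max (tail mass < 1e-10).
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 50.0, 101)
    t_grid = np.asarray(t_grid, dtype=float)
    n_max = uptake.n_max
    nn = np.arange(n_max + 1)
    P = partition_matrix(n_max, fix.q)
    Q0 = fix.N0 * uptake.pmf_matrix(n_max)
    lost = 1.0 - Q0.sum() / fix.N0
    if lost > 1e-6:
        raise OverflowError(f"uptake truncation loses {lost:.2e} of the population")
    W = n_max + 1
    nQ = W * W

    def rhs(s, t):
        w = s[:W]
        Q = s[W:W + nQ].reshape(W, W)
        x = (nn * fix.alpha / fix.beta) * (1.0 - np.exp(-fix.beta * t))
        dw = fix.gamma * x / (1.0 + fix.eta * x) - (fix.mu + fix.kappa) * w
        norm = Q.sum()
        dQ = fix.omega * (1.0 - norm / fix.Nmax) * (2.0 * P @ Q @ P.T - Q)
        # y_{n,m} = m * w_n  =>  sum_nm Q_{nm} y_{nm} = sum_n (Q @ m)_n w_n
        y_tot = (Q @ nn) @ w
        dS = fix.v * fix.kappa * y_tot - fix.delta * s[-1]
        return np.concatenate([dw, dQ.ravel(), [dS]])

    s0 = np.concatenate([np.zeros(W), Q0.ravel(), [0.0]])
    sol = odeint(rhs, s0, t_grid, rtol=1e-8, atol=1e-8)
    if not np.all(np.isfinite(sol)):
        raise FloatingPointError("plasmid integration produced non-finite values")
    w = sol[:, :W].T
    Q = sol[:, W:W + nQ].reshape(len(t_grid), W, W)
    S = sol[:, -1]
    return PlasmidSolution(fixture=fix, uptake=uptake, t=t_grid, w=w, Q=Q, S=S)


def readout_histogram(solution: PlasmidSolution, t_index: int, g: float | None = None):
    return solution.readout_histogram(t_index, g)
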