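"""Trichome patterning on a hexagonal grid of leaf epidermis cells.

Substrate-depletion model for the three proteins TTG1 (T), GL3 (G) and their
activating complex AC (A), per cell j on a 20x20 hexagonal lattice:

    dT_j/dt = alpha - lam * T_j - T_j G_j + delta * (L T)_j
    dG_j/dt = beta * A_j^2 - G_j - T_j G_j
    dA_j/dt = T_j G_j - A_j

Only the substrate TTG1 diffuses (6-neighbour coupling L, periodic
boundaries).  Cells whose steady-state AC level exceeds half the grid
maximum are scored as trichomes; the model response is the trichome density
rho = |T| / N.  The density is only meaningful where a pattern forms, so the
gated response returns 0 whenever linear stability analysis says the
parameter set lies outside the Turing space.

Fixture: alpha (basal TTG1 production) uniform on [0.4, 0.9]; the remaining
non-dimensional parameters are fixed at documented defaults.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import odeint

from ..transforms import ParameterSpec

__all__ = ["trichome_model", "trichome_density", "trichome_turing_test",
           "trichome_steady_state", "hex_laplacian", "TRICHOME_SPEC",
           "TRICHOME_DEFAULTS"]

TRICHOME_SPEC = ParameterSpec.uniform("alpha", 0.4, 0.9)

#: fixed non-dimensional parameters (lam: TTG1 turnover, beta: AC->GL3
#: feedback strength, delta: TTG1 diffusion); chosen so that the Turing-space
#: boundary falls inside the fixture alpha range
TRICHOME_DEFAULTS = {"lam": 0.3, "beta": 6.0, "delta": 1.0, "n": 20}


def hex_laplacian(n: int) -> np.ndarray:
    """6-neighbour discrete Laplacian on an n x n periodic hexagonal lattice.

    Axial coordinates: cell (i, j) couples to (i+-1, j), (i, j+-1),
    (i+1, j-1), (i-1, j+1), all modulo n.  Rows sum to zero.
    """
    N = n * n
    L = np.zeros((N, N))
    idx = lambda i, j: (i % n) * n + (j % n)
    offsets = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
    for i in range(n):
        for j in range(n):
            a = idx(i, j)
            L[a, a] = -6.0
            for di, dj in offsets:
                L[a, idx(i + di, j + dj)] += 1.0
    return L


def trichome_steady_state(alpha: float, lam: float, beta: float):
    """Non-trivial homogeneous steady state (T*, G*, A*), or None.

    Solves lam*beta*T^2 + (1 - alpha*beta)*T + 1 = 0 and returns the
    smaller-T root (the branch that is stable without diffusion and
    destabilised by TTG1 transport), with G* = (1 + T*)/(beta T*^2) and
    A* = T* G*.
    """
    disc = (alpha * beta - 1.0) ** 2 - 4.0 * lam * beta
    if alpha * beta <= 1.0 or disc < 0:
        return None
    T = ((alpha * beta - 1.0) - np.sqrt(disc)) / (2.0 * lam * beta)
    G = (1.0 + T) / (beta * T**2)
    return T, G, T * G


def _jacobian(T, G, A, alpha, lam, beta, delta, ell):
    """Linearisation about the homogeneous state at Laplacian eigenvalue ell."""
    return np.array([
        [-lam - G + delta * ell, -T, 0.0],
        [-G, -1.0 - T, 2.0 * beta * A],
        [G, T, -1.0],
    ])


def trichome_turing_test(alpha: float, lam: float | None = None,
                         beta: float | None = None, delta: float | None = None,
                         n: int | None = None) -> bool:
    """Diffusion-driven instability test for the non-trivial steady state."""
    p = TRICHOME_DEFAULTS
    lam = p["lam"] if lam is None else lam
    beta = p["beta"] if beta is None else beta
    delta = p["delta"] if delta is None else delta
    n = p["n"] if n is None else n
    ss = trichome_steady_state(alpha, lam, beta)
    if ss is None:
        return False
    T, G, A = ss
    J0 = _jacobian(T, G, A, alpha, lam, beta, delta, 0.0)
    if np.max(np.linalg.eigvals(J0).real) >= 0:
        return False
    ell = np.unique(np.round(np.linalg.eigvalsh(hex_laplacian(n)), 10))
    for l in ell:
        if l > -1e-9:
            continue
        J = _jacobian(T, G, A, alpha, lam, beta, delta, l)
        if np.max(np.linalg.eigvals(J).real) > 0:
            return True
    return False


def trichome_model(alpha: float, lam: float | None = None,
                   beta: float | None = None, delta: float | None = None,
                   n: int | None = None, seed: int = 0,
                   steady_tol: float = 1e-6, t_window: float = 10.0,
                   t_max: float = 5000.0) -> np.ndarray:
    """Steady-state AC field (length n*n) from a 1% perturbed homogeneous start."""
    p = TRICHOME_DEFAULTS
    lam = p["lam"] if lam is None else lam
    beta = p["beta"] if beta is None else beta
    delta = p["delta"] if delta is None else delta
    n = p["n"] if n is None else n
    N = n * n
    L = hex_laplacian(n)
    ss = trichome_steady_state(alpha, lam, beta)
    if ss is None:
        # no non-trivial state: relax from the patternless branch
        ss = (alpha / lam, 1e-3, 1e-3)
    T0, G0, A0 = ss
    rng = np.random.default_rng(seed)
    state = np.concatenate([np.full(N, T0), np.full(N, G0), np.full(N, A0)])
    state *= 1.0 + 0.01 * rng.standard_normal(state.size)

    def rhs(s, t):
        T, G, A = s[:N], s[N:2 * N], s[2 * N:]
        TG = T * G
        return np.concatenate([
            alpha - lam * T - TG + delta * (L @ T),
            beta * A * A - G - TG,
            TG - A,
        ])

    t = 0.0
    while t < t_max:
        sol = odeint(rhs, state, [0.0, t_window], rtol=1e-6, atol=1e-9)
        new = sol[-1]
        if not np.all(np.isfinite(new)):
            raise FloatingPointError("integration produced non-finite values")
        scale = np.max(np.abs(new)) + 1e-12
        if np.max(np.abs(new - state)) / scale < steady_tol:
            return new[2 * N:]
        state = new
        t += t_window
    raise ArithmeticError(f"no steady state reached within t = {t_max}")


def trichome_density(ac_field: np.ndarray, uniform_cv: float = 1e-2) -> float:
    """Fraction of cells whose AC level exceeds half the field maximum.

    A quasi-uniform field (coefficient of variation below ``uniform_cv``)
    contains no differentiated cells and scores zero: without this guard a
    patternless epidermis would count every cell as a trichome, since all
    cells sit at the (shared) maximum.
    """
    ac = np.asarray(ac_field, dtype=float)
    if ac.max() <= 0 or ac.std() < uniform_cv * abs(ac.mean()):
        return 0.0
    thr = 0.5 * ac.max()
    return float(np.count_nonzero(ac > thr)) / ac.size
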