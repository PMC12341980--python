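"""Orthonormal basis families and the eigenvalue scheme for evaluation nodes.

The central object is the symmetric matrix

    B_{n,m} = ∫ phi_n(theta) * theta * phi_m(theta) * P(theta) dtheta,

the matrix of the multiplication-by-theta operator in a basis {phi_n}
orthonormal with respect to the parameter density P.  Its eigenvalues are the
model-evaluation nodes of the spectral scheme and the squared first components
of its (orthonormal) eigenvectors are the corresponding weights.  For the
classical polynomial families B is the Jacobi matrix of the three-term
recurrence, so the nodes/weights coincide with Gaussian quadrature
(Golub–Welsch); the same construction applies verbatim to non-polynomial
families such as Haar wavelets composed with the parameter CDF.

Supported families
------------------
legendre   orthonormal w.r.t. U(-1, 1)
hermite    probabilists' Hermite, orthonormal w.r.t. N(0, 1)
charlier   orthonormal w.r.t. Poisson(lam); requires hyperparameter ``lam``
haar       Haar wavelets composed with a reference CDF F; requires a frozen
           scipy distribution ``dist`` (its cdf/ppf define the composition)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np
from scipy import special, stats

__all__ = [
    "BasisFamily",
    "SpectralNodes",
    "eval_basis",
    "build_B_analytic",
    "build_B_numeric",
    "spectral_nodes",
    "haar_family",
]

_POLY_KINDS = ("legendre", "hermite", "charlier")

#: tail-mass cutoff for truncating discrete (Poisson) supports
_DISCRETE_TAIL = 1e-12


@dataclass(frozen=True)
class BasisFamily:
    """A family of N orthonormal basis functions (indices n = 0..N-1)."""

    kind: str
    order: int
    lam: Optional[float] = None        # charlier: mean of the Poisson weight
    dist: object = None                # haar: frozen scipy distribution (F)

    def __post_init__(self):
        if self.kind not in (*_POLY_KINDS, "haar"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        if self.kind == "charlier" and (self.lam is None or self.lam <= 0):
            raise ValueError("charlier requires lam > 0")
        if self.kind == "haar" and self.dist is None:
            raise ValueError("haar requires a reference distribution")

    @property
    def standard_dist(self):
        """Frozen scipy distribution of the weight measure."""
        if self.kind == "legendre":
            return stats.uniform(-1.0, 2.0)
        if self.kind == "hermite":
            return stats.norm()
        if self.kind == "charlier":
            return stats.poisson(self.lam)
        return self.dist

    @property
    def is_discrete(self) -> bool:
        return self.kind == "charlier"


def haar_family(level: int, dist) -> BasisFamily:
    """Haar basis through resolution level ``level``.

    Comprises the constant plus wavelets with scale j = 0..level, i.e.
    2**(level+1) functions in total (level 3 -> 16, level 6 -> 128).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    return BasisFamily("haar", 2 ** (level + 1), dist=dist)


# ---------------------------------------------------------------------------
# recurrence coefficients: theta*phi_n = b_n phi_{n+1} + a_n phi_n + b_{n-1} phi_{n-1}
# ---------------------------------------------------------------------------

def _recurrence(kind: str, N: int, lam: float | None = None):
    """Diagonal a_n and off-diagonal b_n (n = 0..N-1) of the Jacobi matrix."""
    n = np.arange(N, dtype=float)
    if kind == "legendre":
        a = np.zeros(N)
        b = (n + 1) / np.sqrt((2 * n + 1) * (2 * n + 3))
    elif kind == "hermite":
        a = np.zeros(N)
        b = np.sqrt(n + 1)
    elif kind == "charlier":
        # convention of the 2F0-normalized Charlier functions: negative
        # off-diagonal -sqrt((n+1) lam); diagonal n + lam
        a = n + lam
        b = -np.sqrt((n + 1) * lam)
    else:
        raise ValueError(f"no analytic recurrence for kind {kind!r}")
    return a, b[:-1]


# ---------------------------------------------------------------------------
# basis function evaluation
# ---------------------------------------------------------------------------

def _haar_split(n: int):
    """Decompose wavelet index n >= 1 into (scale j, shift k) with n = 2^j + k."""
    j = int(np.floor(np.log2(n)))
    return j, n - 2**j


def _mother_wavelet(y):
    y = np.asarray(y, dtype=float)
    return np.where((y >= 0) & (y < 0.5), 1.0, np.where((y >= 0.5) & (y < 1.0), -1.0, 0.0))


def eval_basis(family: BasisFamily, n: int, theta):
    """Value of the n-th orthonormal basis function at theta (vectorized).

    Polynomial families use the orthonormal three-term recurrence; the Haar
    family maps theta through the reference CDF and evaluates the dyadic
    wavelet ``2^(j/2) psi(2^j y - k)`` with n = 2^j + k (n = 0 is the
    constant function 1).
    """
    if not 0 <= n < family.order:
        raise IndexError(f"basis index {n} out of range [0, {family.order})")
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)

    if family.kind == "haar":
        lo, hi = family.standard_dist.support()
        if np.any(theta < lo) or np.any(theta > hi):
            raise ValueError("theta outside the support of the reference distribution")
        if n == 0:
            out = np.ones_like(theta)
        else:
            j, k = _haar_split(n)
            y = family.standard_dist.cdf(theta)
            out = 2.0 ** (j / 2.0) * _mother_wavelet(2.0**j * y - k)
    else:
        out = _eval_poly_table(family, theta)[:, n]
    return float(out[0]) if scalar else out


def _eval_poly_table(family: BasisFamily, theta: np.ndarray) -> np.ndarray:
    """All polynomial basis values; shape (len(theta), order)."""
    N = family.order
    a, b = _recurrence(family.kind, N, family.lam)
    out = np.empty((theta.size, N))
    out[:, 0] = 1.0
    if N > 1:
        out[:, 1] = (theta - a[0]) / b[0]
    for n in range(1, N - 1):
        out[:, n + 1] = ((theta - a[n]) * out[:, n] - b[n - 1] * out[:, n - 1]) / b[n]
    return out


def basis_matrix(family: BasisFamily, theta) -> np.ndarray:
    """Matrix of basis values phi_n(theta_i); shape (len(theta), order)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if family.kind == "haar":
        return np.column_stack([eval_basis(family, n, theta) for n in range(family.order)])
    return _eval_poly_table(family, theta)


# ---------------------------------------------------------------------------
# B matrix construction
# ---------------------------------------------------------------------------

def build_B_analytic(family: BasisFamily) -> np.ndarray:
    """Tridiagonal B from the orthonormal recurrence (polynomial families)."""
    if family.kind not in _POLY_KINDS:
        raise ValueError("analytic B is available for polynomial families only; "
                         "use build_B_numeric for the Haar basis")
    a, b = _recurrence(family.kind, family.order, family.lam)
    return np.diag(a) + np.diag(b, 1) + np.diag(b, -1)


def _discrete_support(dist, tail=_DISCRETE_TAIL):
    """0..n_max covering all but ``tail`` of the probability mass."""
    n_max = int(dist.ppf(1.0 - tail)) + 2
    while dist.sf(n_max) > tail:
        n_max += 1
    return np.arange(n_max + 1)


def build_B_numeric(family: BasisFamily, pdf=None, tol: float = 1e-8) -> np.ndarray:
    """B_{n,m} = ∫ phi_n(theta) theta phi_m(theta) P(theta) dtheta by quadrature.

    Continuous families are integrated on the CDF-mapped unit interval with a
    composite Gauss–Legendre rule; the order is doubled until every entry is
    stable to ``tol``.  Discrete families are summed over a truncated support
    (tail mass < 1e-12).  The result is symmetrized by averaging with its
    transpose.
    """
    dist = family.standard_dist
    N = family.order

    if family.is_discrete or (pdf is None and hasattr(dist, "pmf")):
        # extend the truncated support until the added terms are negligible
        # (the basis functions grow polynomially, so pmf tail mass alone is
        # not a sufficient criterion)
        n_hi = _discrete_support(dist)[-1]
        B = None
        for _ in range(12):
            theta = np.arange(n_hi + 1, dtype=float)
            w = dist.pmf(theta) if pdf is None else np.asarray(pdf(theta), dtype=float)
            Phi = basis_matrix(family, theta)
            B2 = Phi.T @ (Phi * (theta * w)[:, None])
            if B is not None and np.max(np.abs(B2 - B)) < 0.01 * tol:
                return 0.5 * (B2 + B2.T)
            B = B2
            n_hi *= 2
        raise ArithmeticError("discrete summation for B did not converge")

    # theta-space composite Gauss-Legendre; unbounded supports truncated where
    # the worst-case integrand pdf(theta) * |theta|^(2N+1) / (N-1)! is tiny
    # (the orthonormal basis values grow at most like theta^(N-1)/sqrt((N-1)!))
    lo, hi = dist.support()
    wf = dist.pdf if pdf is None else pdf

    def tail_negligible(t):
        return wf(t) * abs(t) ** (2 * N + 1) / special.gamma(N) < 1e-4 * tol

    if not np.isfinite(hi):
        hi = dist.ppf(1.0 - 1e-12)
        while not tail_negligible(hi):
            hi *= 1.25
    if not np.isfinite(lo):
        lo = dist.ppf(1e-12)
        while not tail_negligible(lo):
            lo *= 1.25
    if family.kind == "haar":
        # panel edges aligned with the dyadic breakpoints of the wavelets
        base_edges = dist.ppf(np.linspace(0.0, 1.0, max(N, 2) + 1))
        base_edges[0], base_edges[-1] = lo, hi
    else:
        base_edges = np.array([lo, hi])

    def entries(n_sub, order):
        x, wq = np.polynomial.legendre.leggauss(order)
        edges = np.concatenate([
            np.linspace(a, b, n_sub + 1)[:-1] for a, b in zip(base_edges[:-1], base_edges[1:])
        ] + [base_edges[-1:]])
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * np.diff(edges)
        theta = (mid[:, None] + half[:, None] * x[None, :]).ravel()
        wt = (half[:, None] * wq[None, :]).ravel()
        wt = wt * (dist.pdf(theta) if pdf is None else np.asarray(pdf(theta), dtype=float))
        Phi = basis_matrix(family, theta)
        B = Phi.T @ (Phi * (theta * wt)[:, None])
        return 0.5 * (B + B.T)

    n_sub = max(4, N)
    order = 32
    B = entries(n_sub, order)
    for _ in range(6):
        B2 = entries(2 * n_sub, order)
        delta = np.max(np.abs(B2 - B))
        if delta < tol:
            return B2
        n_sub *= 2
        B = B2
    raise ArithmeticError(
        f"quadrature for B did not converge to {tol:g}; "
        f"last change {delta:.3g} at {n_sub} subdivisions per panel")


# ---------------------------------------------------------------------------
# eigendecomposition -> nodes and weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralNodes:
    """Eigen-decomposition of B: evaluation nodes and weight vectors.

    ``eigenvalues[l]`` is the l-th model-evaluation node; column l of
    ``eigenvectors`` is the orthonormal eigenvector u^(l), sign-fixed so its
    first component is >= 0; ``first_components[l]**2`` is the quadrature
    weight attached to node l.
    """

    family: BasisFamily
    B: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def first_components(self) -> np.ndarray:
        return self.eigenvectors[0]

    @property
    def weights(self) -> np.ndarray:
        return self.first_components**2


def spectral_nodes(B: np.ndarray, family: BasisFamily) -> SpectralNodes:
    """Eigendecompose B into nodes (ascending) and sign-fixed eigenvectors."""
    B = np.asarray(B, dtype=float)
    if not np.allclose(B, B.T, rtol=0, atol=1e-12 * max(1.0, np.abs(B).max())):
        raise ValueError("B must be symmetric")
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    first = vecs[0].copy()
    degenerate = np.abs(first) < 1e-12
    if np.any(degenerate):
        warnings.warn(
            "eigenvector(s) with vanishing first component: the corresponding "
            "node(s) carry zero weight in the expansion", RuntimeWarning)
    sign = np.where(first < 0, -1.0, 1.0)
    vecs = vecs * sign[None, :]
    return SpectralNodes(family=family, B=B, eigenvalues=vals, eigenvectors=vecs)


def nodes_for(family: BasisFamily) -> SpectralNodes:
    """Convenience: build B (analytic where possible) and decompose it."""
    if family.kind in _POLY_KINDS:
        B = build_B_analytic(family)
    else:
        B = build_B_numeric(family)
    return spectral_nodes(B, family)
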