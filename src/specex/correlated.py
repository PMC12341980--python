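"""Spectral expansion with correlated parameters; bivariate Poisson uptake.

For two correlated counts (n, m) — e.g. the numbers of two plasmid types a
cell takes up — with joint PMF P(n, m) and Poisson(lam) marginals, the
expansion uses rescaled basis functions

    psi~_{l1,l2}(n, m) = sqrt(P(n) P(m) / P(n, m)) psi_l1(n) psi_l2(m),

where the psi_l are the eigen-combinations of the (Charlier) marginal basis.
The surrogate is

    Y_s(n, m) = sqrt(P(n) P(m) / P(n, m))
                * sum_{l1,l2} Y(lambda^(l1), lambda^(l2)) w_{l1,l2}
                  psi_l1(n) psi_l2(m),

with weight matrix w_{l1,l2} = E_joint[psi~_{l1,l2}], the joint-expectation
analogue of the independent-case product u1^(l1) u1^(l2).

The bivariate Poisson itself is evaluated through the trivariate-reduction
series

    P(n, m) = e^{-(2 lam - xi)} sum_{i=0}^{min(n,m)}
              (lam-xi)^{n-i} (lam-xi)^{m-i} xi^i / ((n-i)! (m-i)! i!),

i.e. n = n' + c, m = m'' + c with independent n' , m'' ~ Poisson(lam - xi)
and shared c ~ Poisson(xi); both marginals are Poisson(lam) and
corr(n, m) = xi / lam.  An equivalent Kummer-U closed form is provided as a
numerical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special, stats

from .basis import BasisFamily, basis_matrix, nodes_for

__all__ = ["BivariatePoissonDist", "bivariate_poisson_pmf", "correlated_weights",
           "fit_correlated", "CorrelatedSurrogate"]


@dataclass(frozen=True)
class BivariatePoissonDist:
    """Bivariate Poisson with common marginal mean lam and covariance xi."""

    lam: float
    xi: float
    tail: float = 1e-10

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 <= self.xi <= self.lam:
            raise ValueError("xi must lie in [0, lam]")

    @property
    def n_max(self) -> int:
        """Truncation point: smallest n with Poisson(lam) tail mass < tail."""
        dist = stats.poisson(self.lam)
        n = int(dist.ppf(1 - self.tail)) + 1
        while dist.sf(n) > self.tail:
            n += 1
        return n

    def pmf(self, n, m):
        return bivariate_poisson_pmf(self, n, m)

    def pmf_matrix(self, n_max: int | None = None) -> np.ndarray:
        """P(n, m) on the grid [0, n_max]^2."""
        n_max = self.n_max if n_max is None else n_max
        n = np.arange(n_max + 1)
        return bivariate_poisson_pmf(self, n[:, None], n[None, :])

    def marginal_pmf(self, n):
        return stats.poisson(self.lam).pmf(n)

    def correlation(self, n_max: int | None = None) -> float:
        """Pearson correlation of (n, m) computed from the truncated PMF."""
        P = self.pmf_matrix(n_max)
        n = np.arange(P.shape[0], dtype=float)
        pn, pm = P.sum(axis=1), P.sum(axis=0)
        En, Em = n @ pn, n @ pm
        vn = (n - En) ** 2 @ pn
        vm = (n - Em) ** 2 @ pm
        cov = (n[:, None] - En) * (n[None, :] - Em)
        return float(np.sum(cov * P) / np.sqrt(vn * vm))


def bivariate_poisson_pmf(d: BivariatePoissonDist, n, m):
    """Trivariate-reduction series PMF (vectorized over integer n, m)."""
    n = np.asarray(n, dtype=int)
    m = np.asarray(m, dtype=int)
    if np.any(n < 0) or np.any(m < 0):
        raise ValueError("counts must be non-negative")
    lam, xi = d.lam, d.xi
    if xi == 0:
        out = stats.poisson(lam).pmf(n) * stats.poisson(lam).pmf(m)
        return out if out.ndim else float(out)

    nb, mb = np.broadcast_arrays(n, m)
    out = np.zeros(nb.shape, dtype=float)
    log_rate = np.log(lam - xi) if lam > xi else -np.inf
    imax_all = int(np.max(np.minimum(nb, mb)))
    # accumulate the series in log space for stability
    for i in range(imax_all + 1):
        mask = (nb >= i) & (mb >= i)
        if not np.any(mask):
            continue
        with np.errstate(invalid="ignore"):
            logterm = ((nb - i) * log_rate + (mb - i) * log_rate + i * np.log(xi)
                       - special.gammaln(nb - i + 1.0) - special.gammaln(mb - i + 1.0)
                       - special.gammaln(i + 1.0))
        term = np.where(mask, np.exp(np.where(mask, logterm, -np.inf)), 0.0)
        out += term
    out *= np.exp(-(2.0 * lam - xi))
    return out if out.ndim else float(out)


def _kummer_u_terminating(n: int, b: float, x: float) -> float:
    """U(-n, b, x) for non-negative integer n via the terminating 2F0 series.

    U(a, b, x) = x^(-a) 2F0(a, a-b+1; ; -1/x); for a = -n the series has
    n+1 terms, valid for any sign of x.
    """
    a = -n
    total, term = 0.0, 1.0
    for i in range(n + 1):
        total += term
        term *= (a + i) * (a - b + 1 + i) / (i + 1.0) * (-1.0 / x)
    return x**n * total


def bivariate_poisson_pmf_kummer(d: BivariatePoissonDist, n: int, m: int) -> float:
    """Closed-form PMF via Kummer's confluent hypergeometric function U.

    Cross-check oracle only: the trivariate-reduction series resums to
    P(n,m) = e^{-(2 lam - xi)} (lam-xi)^(n+m) / (n! m!)
             * (-z)^n U(-n, 1 - n + m, -1/z),  z = xi / (lam-xi)^2, n <= m,
    using sum_i C(n,i) C(m,i) i! z^i = (-z)^n U(-n, 1-n+m, -1/z).
    """
    lam, xi = d.lam, d.xi
    if xi == 0:
        return float(stats.poisson(lam).pmf(n) * stats.poisson(lam).pmf(m))
    r = lam - xi
    nn, mm = (n, m) if n <= m else (m, n)
    z = xi / r**2
    s = (-z) ** nn * _kummer_u_terminating(nn, 1 - nn + mm, -1.0 / z)
    return float(np.exp(-(2 * lam - xi)) * r ** (nn + mm)
                 / (special.factorial(nn) * special.factorial(mm)) * s)


# ---------------------------------------------------------------------------
# correlated expansion
# ---------------------------------------------------------------------------

def _psi_matrix(family: BasisFamily, nodes, theta) -> np.ndarray:
    """psi_l(theta) = sum_n u_{n+1}^(l) phi_n(theta); shape (len(theta), N)."""
    Phi = basis_matrix(family, theta)
    return Phi @ nodes.eigenvectors


def correlated_weights(family1: BasisFamily, family2: BasisFamily,
                       joint_pmf: np.ndarray) -> np.ndarray:
    """Weight matrix w_{l1,l2} = E_joint[sqrt(P1 P2 / P12) psi_l1 psi_l2].

    ``joint_pmf`` is the truncated joint PMF on [0, n_max]^2.  Where the
    marginals are positive the joint must be as well; support points with
    zero joint mass but positive marginal product violate the method's
    assumption and raise.
    """
    P12 = np.asarray(joint_pmf, dtype=float)
    n = np.arange(P12.shape[0], dtype=float)
    m = np.arange(P12.shape[1], dtype=float)
    P1 = family1.standard_dist.pmf(n)
    P2 = family2.standard_dist.pmf(m)
    bad = (P12 <= 0) & ((P1[:, None] * P2[None, :]) > 1e-300)
    if np.any(bad):
        raise ValueError("joint PMF vanishes on a support point of the marginals")
    nodes1, nodes2 = nodes_for(family1), nodes_for(family2)
    Psi1 = _psi_matrix(family1, nodes1, n)   # (n, N1)
    Psi2 = _psi_matrix(family2, nodes2, m)   # (m, N2)
    W = np.sqrt(P1[:, None] * P2[None, :] * P12)
    return Psi1.T @ W @ Psi2


@dataclass
class CorrelatedSurrogate:
    """Expansion of a model of two correlated counts."""

    joint: BivariatePoissonDist
    family: BasisFamily
    nodes: object               # SpectralNodes of the shared Charlier basis
    responses: np.ndarray       # (N, N, *out)
    weights: np.ndarray         # (N, N)
    output_shape: tuple

    def evaluate(self, n: int, m: int):
        """Approximate Y(n, m) at an integer count pair."""
        fam = self.family
        nodes = self.nodes
        psi1 = _psi_matrix(fam, nodes, [float(n)])[0]
        psi2 = _psi_matrix(fam, nodes, [float(m)])[0]
        P1 = fam.standard_dist.pmf(n)
        P2 = fam.standard_dist.pmf(m)
        P12 = self.joint.pmf(n, m)
        pref = np.sqrt(P1 * P2 / P12)
        core = self.responses * self.weights.reshape(
            self.weights.shape + (1,) * len(self.output_shape))
        out = pref * np.einsum("i,j,ij...->...", psi1, psi2, core)
        return float(out) if not self.output_shape else out


def fit_correlated(model: Callable, joint: BivariatePoissonDist, N: int) -> CorrelatedSurrogate:
    """Fit the correlated expansion with N Charlier basis functions per margin.

    The model is evaluated at the N^2 pairs of (real-valued) Charlier
    eigen-nodes; no rounding to integers is applied.
    """
    fam = BasisFamily("charlier", N, lam=joint.lam)
    nodes = nodes_for(fam)
    lam_nodes = nodes.eigenvalues
    responses = None
    for i, a in enumerate(lam_nodes):
        for j, b in enumerate(lam_nodes):
            y = np.asarray(model(a, b), dtype=float)
            if responses is None:
                responses = np.empty((N, N) + y.shape)
            responses[i, j] = y
    P12 = joint.pmf_matrix()
    W = correlated_weights(fam, fam, P12)
    return CorrelatedSurrogate(joint=joint, family=fam, nodes=nodes,
                               responses=responses, weights=W,
                               output_shape=responses.shape[2:])
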