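"""Orthonormal bases, the multiplication matrix B, and its eigen-nodes."""

import numpy as np
import pytest
from scipy import stats

from specex.basis import (BasisFamily, basis_matrix, build_B_analytic,
                          build_B_numeric, eval_basis, haar_family,
                          nodes_for, spectral_nodes)

ALL_POLY = [
    BasisFamily("legendre", 8),
    BasisFamily("hermite", 8),
    BasisFamily("charlier", 8, lam=3.0),
]


def _quad_inner_products(family):
    """Gram matrix of the basis under its weight, by brute-force quadrature."""
    dist = family.standard_dist
    if family.is_discrete:
        n = np.arange(0, 200)
        Phi = basis_matrix(family, n.astype(float))
        return Phi.T @ (Phi * dist.pmf(n)[:, None])
    lo, hi = dist.support()
    lo = lo if np.isfinite(lo) else -14.0
    hi = hi if np.isfinite(hi) else 14.0
    x, w = np.polynomial.legendre.leggauss(60)
    edges = np.linspace(lo, hi, 65)
    mid, half = 0.5 * (edges[:-1] + edges[1:]), 0.5 * np.diff(edges)
    t = (mid[:, None] + half[:, None] * x).ravel()
    wt = (half[:, None] * w).ravel() * dist.pdf(t)
    Phi = basis_matrix(family, t)
    return Phi.T @ (Phi * wt[:, None])


@pytest.mark.parametrize("family", ALL_POLY, ids=lambda f: f.kind)
def test_polynomial_families_are_orthonormal(family):
    G = _quad_inner_products(family)
    assert np.abs(G - np.eye(family.order)).max() < 1e-8


def test_haar_family_is_orthonormal():
    fam = haar_family(2, stats.uniform(-1.0, 2.0))
    # piecewise-constant integrands: midpoint rule on fine dyadic cells is exact
    t = (np.arange(4096) + 0.5) / 4096 * 2.0 - 1.0
    Phi = basis_matrix(fam, t)
    G = Phi.T @ Phi / 4096
    assert np.abs(G - np.eye(fam.order)).max() < 1e-12


def test_constant_basis_function_is_one():
    for fam in ALL_POLY + [haar_family(1, stats.uniform(-1, 2))]:
        assert eval_basis(fam, 0, 0.7 if fam.kind != "charlier" else 2) == pytest.approx(1.0)


def test_hermite_degree_one_is_identity():
    # orthonormal probabilists' Hermite of degree 1 is theta itself
    fam = BasisFamily("hermite", 3)
    assert eval_basis(fam, 1, 2.0) == pytest.approx(2.0, abs=1e-14)


def test_haar_mother_wavelet_signs():
    fam = haar_family(1, stats.uniform(0.0, 1.0))  # F = identity on [0, 1]
    assert eval_basis(fam, 1, 0.25) == 1.0
    assert eval_basis(fam, 1, 0.75) == -1.0


def test_basis_index_out_of_range_raises():
    with pytest.raises(IndexError):
        eval_basis(BasisFamily("legendre", 3), 3, 0.0)


def test_haar_outside_support_raises():
    fam = haar_family(1, stats.uniform(0.0, 1.0))
    with pytest.raises(ValueError):
        eval_basis(fam, 1, 1.5)


@pytest.mark.parametrize("family,expected", [
    (BasisFamily("hermite", 2), [[0.0, 1.0], [1.0, 0.0]]),
    (BasisFamily("legendre", 2), [[0.0, 3**-0.5], [3**-0.5, 0.0]]),
    (BasisFamily("charlier", 2, lam=3.0), [[3.0, -np.sqrt(3)], [-np.sqrt(3), 4.0]]),
], ids=["hermite", "legendre", "charlier"])
def test_analytic_B_matches_closed_forms(family, expected):
    assert build_B_analytic(family) == pytest.approx(np.array(expected))


def test_analytic_B_rejects_haar():
    with pytest.raises(ValueError):
        build_B_analytic(haar_family(1, stats.uniform(-1, 2)))


@pytest.mark.parametrize("kind,lam", [("legendre", None), ("hermite", None),
                                      ("charlier", 3.0)])
@pytest.mark.parametrize("N", [2, 5, 10])
def test_numeric_B_matches_analytic(kind, lam, N):
    fam = BasisFamily(kind, N, lam=lam)
    assert np.abs(build_B_numeric(fam) - build_B_analytic(fam)).max() < 1e-8


def test_numeric_B_haar_level0_oracle():
    # F = CDF of U(-1,1): offdiag = int theta * W1(theta) * 0.5 dtheta = -1/2
    fam = haar_family(0, stats.uniform(-1.0, 2.0))
    B = build_B_numeric(fam)
    assert B == pytest.approx(np.array([[0.0, -0.5], [-0.5, 0.0]]), abs=1e-10)
    assert np.array_equal(B, B.T)


def test_spectral_nodes_two_point_hermite():
    nd = nodes_for(BasisFamily("hermite", 2))
    assert nd.eigenvalues == pytest.approx([-1.0, 1.0])
    assert nd.weights == pytest.approx([0.5, 0.5])


def test_spectral_nodes_three_point_legendre():
    nd = nodes_for(BasisFamily("legendre", 3))
    r = np.sqrt(3.0 / 5.0)
    assert nd.eigenvalues == pytest.approx([-r, 0.0, r])


@pytest.mark.parametrize("family", ALL_POLY + [haar_family(3, stats.uniform(-1, 2))],
                         ids=lambda f: f.kind)
def test_weights_sum_to_one_and_sign_convention(family):
    nd = nodes_for(family)
    assert nd.weights.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(nd.first_components >= -1e-15)
    # eigenvector columns orthonormal
    U = nd.eigenvectors
    assert np.abs(U.T @ U - np.eye(family.order)).max() < 1e-12


def test_spectral_nodes_requires_symmetry():
    with pytest.raises(ValueError):
        spectral_nodes(np.array([[0.0, 1.0], [0.0, 0.0]]), BasisFamily("hermite", 2))


@pytest.mark.parametrize("kind", ["legendre", "hermite"])
@pytest.mark.parametrize("N", list(range(2, 13)))
def test_eigenvalues_equal_classical_gauss_nodes(kind, N):
    """Independent oracle: numpy's Gauss rules (root finding on recurrences)."""
    nd = nodes_for(BasisFamily(kind, N))
    if kind == "legendre":
        x, w = np.polynomial.legendre.leggauss(N)
        w = w / 2.0  # U(-1,1) normalisation
    else:
        x, w = np.polynomial.hermite_e.hermegauss(N)
        w = w / np.sqrt(2.0 * np.pi)
    assert np.abs(np.sort(x) - nd.eigenvalues).max() < 1e-10
    assert np.abs(w[np.argsort(x)] - nd.weights).max() < 1e-10


@pytest.mark.parametrize("family", ALL_POLY, ids=lambda f: f.kind)
def test_induced_quadrature_exact_to_degree_2N_minus_1(family, rng):
    nd = nodes_for(family)
    N = family.order
    coeffs = rng.standard_normal(2 * N)  # random polynomial, degree 2N-1
    dist = family.standard_dist
    if family.is_discrete:
        n = np.arange(0, 400)
        exact = sum(c * np.sum(n.astype(float)**p * dist.pmf(n))
                    for p, c in enumerate(coeffs))
    else:
        moments = [dist.moment(p) for p in range(2 * N)]
        exact = sum(c * m for c, m in zip(coeffs, moments))
    quad = sum(c * np.sum(nd.eigenvalues**p * nd.weights) for p, c in enumerate(coeffs))
    assert quad == pytest.approx(exact, rel=1e-9, abs=1e-9)


def test_haar_counting_convention():
    assert haar_family(3, stats.uniform(-1, 2)).order == 16
    assert haar_family(6, stats.uniform(-1, 2)).order == 128
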