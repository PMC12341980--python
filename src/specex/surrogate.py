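"""Spectral-expansion surrogates: fit from node evaluations, evaluate, post-process.

A surrogate for a model Y(k_1, ..., k_M) with independent uncertain parameters
is the truncated tensor-product expansion

    Y_s(theta) = sum_{l1..lM} Y(lambda^(l1), ..., lambda^(lM))
                 * u1^(l1) ... u1^(lM) * psi_l1(theta_1) ... psi_lM(theta_M),

where per dimension the lambda^(l) are the eigenvalues of the basis matrix B
(the model-evaluation nodes), u^(l) its orthonormal eigenvectors, and
psi_l(theta) = sum_n u_{n+1}^(l) phi_n(theta).  Fitting therefore costs exactly
prod_j N_j model evaluations; everything else is precomputed linear algebra.

Equivalently the expansion has coefficients

    c_{n1..nM} = sum_{l1..lM} Y(...) * prod_j u1^(lj) u_{nj+1}^(lj),

which coincide with the Gaussian-quadrature projection coefficients for
polynomial bases.  Mean and variance follow directly from the coefficients,
as do Sobol sensitivity indices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .basis import BasisFamily, SpectralNodes, basis_matrix, nodes_for
from .transforms import ParameterSpec

__all__ = ["Surrogate", "fit", "evaluate", "moments", "sobol_first_order", "sobol_total_like"]


@dataclass(frozen=True)
class Dimension:
    spec: ParameterSpec
    family: BasisFamily
    nodes: SpectralNodes


@dataclass
class Surrogate:
    """Fitted spectral-expansion meta-model.

    ``responses`` holds the raw model outputs, shape ``(N_1, ..., N_M, *out)``;
    ``coefficients`` the expansion coefficients with the same shape, multi-index
    (n_1, ..., n_M) over basis-function degrees.
    """

    dims: list[Dimension]
    responses: np.ndarray
    coefficients: np.ndarray
    output_shape: tuple

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    @property
    def orders(self) -> tuple:
        return tuple(d.family.order for d in self.dims)

    def evaluate(self, theta):
        return evaluate(self, theta)

    def moments(self):
        return moments(self)

    def sobol_first_order(self, i: int) -> float:
        return sobol_first_order(self, i)

    def sobol_total_like(self, i: int) -> float:
        return sobol_total_like(self, i)


def _default_family(spec: ParameterSpec, N: int) -> BasisFamily:
    kind = spec.basis_kind
    if kind == "charlier":
        return BasisFamily("charlier", N, lam=spec.params["lam"])
    return BasisFamily(kind, N)


def _resolve_dims(specs, N, families=None) -> list[Dimension]:
    specs = list(specs)
    if N is None:
        if families is None or any(f is None for f in families):
            raise ValueError("N may only be omitted when every family is given")
        orders = [f.order for f in families]
    else:
        orders = [N] * len(specs) if np.isscalar(N) else list(N)
    if len(orders) != len(specs):
        raise ValueError("need one expansion order per parameter")
    dims = []
    for j, spec in enumerate(specs):
        fam = families[j] if families is not None and families[j] is not None \
            else _default_family(spec, orders[j])
        dims.append(Dimension(spec=spec, family=fam, nodes=nodes_for(fam)))
    return dims


def fit(model: Callable, specs: Sequence[ParameterSpec], N,
        families: Sequence[BasisFamily] | None = None) -> Surrogate:
    """Fit a surrogate by evaluating ``model`` once per node tuple.

    ``model`` receives *physical* parameter values (one positional vector) and
    may return a scalar or an array (time course, field, several species);
    vector outputs are expanded component-wise sharing the node set.  Node
    tuples are visited in row-major order over ascending eigenvalues.
    """
    dims = _resolve_dims(specs, N, families)
    orders = tuple(d.family.order for d in dims)
    phys_nodes = [d.spec.to_physical(d.nodes.eigenvalues) for d in dims]

    responses = None
    for idx in itertools.product(*(range(n) for n in orders)):
        k = np.array([phys_nodes[j][idx[j]] for j in range(len(dims))])
        try:
            y = np.asarray(model(k), dtype=float)
        except Exception as err:
            raise RuntimeError(f"model evaluation failed at physical parameters {k}") from err
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite model output at physical parameters {k}")
        if responses is None:
            responses = np.empty(orders + y.shape)
        responses[idx] = y
    out_shape = responses.shape[len(orders):]

    # c_{n1..nM} = sum_l Y * prod_j u1^(lj) u_{nj+1}^(lj)
    coeff = responses
    for j, d in enumerate(dims):
        A = (d.nodes.eigenvectors * d.nodes.first_components[None, :]).T  # (l, n)
        coeff = np.moveaxis(np.tensordot(A, coeff, axes=(0, j)), 0, j)
    return Surrogate(dims=dims, responses=responses, coefficients=coeff,
                     output_shape=out_shape)


def evaluate(s: Surrogate, theta):
    """Evaluate the truncated expansion at a standard-variable point."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape[-1] != s.n_dims:
        raise ValueError(f"theta must have {s.n_dims} components")
    out = s.coefficients
    for j, d in enumerate(s.dims):
        phi = basis_matrix(d.family, theta[..., j])[0]  # (n,)
        out = np.tensordot(phi, out, axes=(0, 0))
    return out if s.output_shape else float(out)


def moments(s: Surrogate):
    """(mean, variance) per output component, from the coefficients."""
    zero = (0,) * s.n_dims
    mean = s.coefficients[zero]
    axes = tuple(range(s.n_dims))
    var = np.sum(s.coefficients**2, axis=axes) - mean**2
    if not s.output_shape:
        return float(mean), float(var)
    return mean, var


def _variance_mask(s: Surrogate, mask_fn):
    """Sum of squared coefficients over multi-indices selected by mask_fn."""
    grids = np.meshgrid(*(np.arange(n) for n in s.orders), indexing="ij")
    sel = mask_fn(grids)
    c2 = s.coefficients**2
    axes = tuple(range(s.n_dims))
    sel_b = sel.reshape(sel.shape + (1,) * len(s.output_shape))
    return np.sum(np.where(sel_b, c2, 0.0), axis=axes)


def _total_variance(s: Surrogate):
    mean = s.coefficients[(0,) * s.n_dims]
    return np.sum(s.coefficients**2, axis=tuple(range(s.n_dims))) - mean**2


def sobol_first_order(s: Surrogate, i: int):
    """Classical first-order Sobol index of dimension i.

    Sums squared coefficients over multi-indices whose i-th entry is positive
    and all others are zero, divided by the total variance.
    """
    def mask(grids):
        sel = grids[i] > 0
        for j, g in enumerate(grids):
            if j != i:
                sel &= g == 0
        return sel
    return _sobol(s, mask)


def sobol_total_like(s: Surrogate, i: int):
    """Variance share of every multi-index with i-th entry positive.

    This sums over *all* multi-indices whose i-th component exceeds zero
    (interactions included), i.e. the total-effect index.
    """
    return _sobol(s, lambda grids: grids[i] > 0)


def _sobol(s: Surrogate, mask):
    D = _total_variance(s)
    if np.all(D <= 0):
        raise ZeroDivisionError("total variance is zero; Sobol indices undefined")
    part = _variance_mask(s, mask)
    out = np.divide(part, D, out=np.zeros_like(part), where=D > 0)
    return float(out) if not s.output_shape else out
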