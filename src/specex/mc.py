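"""Quasi-Monte-Carlo reference engine.

Sobol-sequence sampling of the standard variables, blocking-method error
estimation for moments, and Gaussian kernel density estimation (Silverman
bandwidth) for output PDFs.  This module provides the independent reference
against which the spectral surrogates are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .transforms import ParameterSpec

__all__ = ["qmc_sample", "blocking_error", "kde", "McResult", "run_mc"]


def qmc_sample(specs: Sequence[ParameterSpec], n: int, seed: int = 0) -> np.ndarray:
    """n low-discrepancy draws of the standard variables; shape (n, M).

    A scrambled Sobol sequence in the unit cube is mapped through each spec's
    standard distribution (affine for uniform, inverse CDF otherwise).
    Deterministic given the scramble seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = list(specs)
    sampler = qmc.Sobol(d=len(specs), scramble=True, rng=np.random.default_rng(seed))
    u = sampler.random(n)
    out = np.empty_like(u)
    for j, spec in enumerate(specs):
        if spec.family == "uniform":
            out[:, j] = 2.0 * u[:, j] - 1.0
        elif spec.family in ("normal", "lognormal"):
            out[:, j] = stats.norm.ppf(u[:, j])
        else:  # poisson counts
            out[:, j] = stats.poisson(spec.params["lam"]).ppf(u[:, j])
    return out


def blocking_error(values, n_blocks: int = 16):
    """Blocking-method estimate of a mean and its error.

    Splits the sample into ``n_blocks`` consecutive blocks (truncating any
    remainder), returns the grand mean of block means and the standard
    deviation of block means divided by sqrt(n_blocks).
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if values.size < n_blocks:
        raise ValueError("fewer samples than blocks")
    bs = values.size // n_blocks
    blocks = values[: bs * n_blocks].reshape(n_blocks, bs)
    means = blocks.mean(axis=1)
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks))


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Robust Silverman rule: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    samples = np.asarray(samples, dtype=float).ravel()
    sd = samples.std(ddof=1)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("zero-variance sample: bandwidth undefined")
    return 0.9 * scale * samples.size ** (-0.2)


def kde(samples, grid, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian-kernel density estimate of the sample on the given grid."""
    samples = np.asarray(samples, dtype=float).ravel()
    grid = np.asarray(grid, dtype=float)
    if np.unique(samples).size < 2:
        raise ValueError("need at least 2 distinct samples")
    h = silverman_bandwidth(samples) if bandwidth is None else bandwidth
    z = (grid[:, None] - samples[None, :]) / h
    return np.exp(-0.5 * z**2).sum(axis=1) / (samples.size * h * np.sqrt(2 * np.pi))


@dataclass
class McResult:
    """Outputs and blocking-method moment estimates of a (Q)MC run."""

    samples: np.ndarray
    mean: np.ndarray
    mean_error: np.ndarray
    variance: np.ndarray
    variance_error: np.ndarray
    n: int
    seed: int


def run_mc(model, specs: Sequence[ParameterSpec], n: int, seed: int = 0,
           n_blocks: int = 16, standard: bool = False) -> McResult:
    """Evaluate ``model`` on a QMC sample and estimate moments with errors.

    ``model`` maps a physical parameter vector to a scalar or array output
    (set ``standard=True`` to pass the standard variables through directly).
    """
    theta = qmc_sample(specs, n, seed)
    specs = list(specs)
    outs = []
    for row in theta:
        k = row if standard else np.array(
            [specs[j].to_physical(row[j]) for j in range(len(specs))])
        outs.append(np.asarray(model(k), dtype=float))
    samples = np.stack(outs)
    flat = samples.reshape(n, -1)
    est = np.array([blocking_error(flat[:, c], n_blocks) for c in range(flat.shape[1])])
    est2 = np.array([blocking_error((flat[:, c] - flat[:, c].mean()) ** 2, n_blocks)
                     for c in range(flat.shape[1])])
    shape = samples.shape[1:]
    return McResult(samples=samples,
                    mean=est[:, 0].reshape(shape) if shape else float(est[0, 0]),
                    mean_error=est[:, 1].reshape(shape) if shape else float(est[0, 1]),
                    variance=est2[:, 0].reshape(shape) if shape else float(est2[0, 0]),
                    variance_error=est2[:, 1].reshape(shape) if shape else float(est2[0, 1]),
                    n=n, seed=seed)
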