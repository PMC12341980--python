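"""Isoprobabilistic transforms between standard variables and physical parameters.

Each uncertain model parameter ``k`` is described by a :class:`ParameterSpec`
naming its distribution family.  The spectral machinery operates on a
*standard* variable ``theta`` — uniform on [-1, 1] for uniformly distributed
parameters, standard normal for normal/lognormal ones, Poisson(lam) for count
parameters — and the spec provides the deterministic map between the two:

* normal(mu, sigma):     k = mu + sigma * theta,            theta ~ N(0, 1)
* uniform(a, b):         k = (b + a)/2 + (b - a) * theta/2, theta ~ U(-1, 1)
* lognormal(mu, sigma):  k = mu * exp(alpha*theta - alpha**2/2),
                         alpha = sqrt(log(1 + sigma**2/mu**2)), theta ~ N(0, 1)
* poisson(lam):          k = theta (counts are already physical)

The lognormal family is parameterised by its *arithmetic* mean and standard
deviation, not by the log-scale location/scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ParameterSpec"]

_FAMILIES = ("uniform", "normal", "lognormal", "poisson")

# basis family orthonormal w.r.t. the standard variable of each distribution
_BASIS_KIND = {
    "uniform": "legendre",
    "normal": "hermite",
    "lognormal": "hermite",
    "poisson": "charlier",
}


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain parameter: distribution family plus hyperparameters."""

    name: str
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        p = self.params
        if self.family == "uniform":
            if not p["a"] < p["b"]:
                raise ValueError(f"uniform requires a < b, got a={p['a']}, b={p['b']}")
        elif self.family in ("normal", "lognormal"):
            if not p["sigma"] > 0:
                raise ValueError("sigma must be > 0")
            if self.family == "lognormal" and not p["mu"] > 0:
                raise ValueError("lognormal requires mu > 0")
        elif self.family == "poisson":
            if not p["lam"] > 0:
                raise ValueError("poisson requires lam > 0")

    # -- constructors ------------------------------------------------------
    @classmethod
    def uniform(cls, name: str, a: float, b: float) -> "ParameterSpec":
        return cls(name, "uniform", {"a": float(a), "b": float(b)})

    @classmethod
    def normal(cls, name: str, mu: float, sigma: float) -> "ParameterSpec":
        return cls(name, "normal", {"mu": float(mu), "sigma": float(sigma)})

    @classmethod
    def lognormal(cls, name: str, mu: float, sigma: float) -> "ParameterSpec":
        return cls(name, "lognormal", {"mu": float(mu), "sigma": float(sigma)})

    @classmethod
    def poisson(cls, name: str, lam: float) -> "ParameterSpec":
        return cls(name, "poisson", {"lam": float(lam)})

    # -- derived properties ------------------------------------------------
    @property
    def basis_kind(self) -> str:
        return _BASIS_KIND[self.family]

    @property
    def alpha(self) -> float:
        """Log-scale spread of the lognormal family."""
        if self.family != "lognormal":
            raise AttributeError("alpha is defined for lognormal specs only")
        mu, sigma = self.params["mu"], self.params["sigma"]
        return math.sqrt(math.log(1.0 + sigma**2 / mu**2))

    @property
    def standard_dist(self):
        """Frozen scipy distribution of the standard variable theta."""
        if self.family == "uniform":
            return stats.uniform(-1.0, 2.0)
        if self.family in ("normal", "lognormal"):
            return stats.norm()
        return stats.poisson(self.params["lam"])

    # -- transforms --------------------------------------------------------
    def to_physical(self, theta):
        """Map the standard variable to the physical parameter."""
        theta = np.asarray(theta, dtype=float)
        p = self.params
        if self.family == "normal":
            out = p["mu"] + p["sigma"] * theta
        elif self.family == "uniform":
            out = 0.5 * (p["b"] + p["a"]) + 0.5 * (p["b"] - p["a"]) * theta
        elif self.family == "lognormal":
            a = self.alpha
            out = p["mu"] * np.exp(a * theta - 0.5 * a * a)
        else:  # poisson: counts are physical already
            out = theta
        return out if out.ndim else float(out)

    def to_standard(self, k):
        """Exact algebraic inverse of :meth:`to_physical`."""
        k = np.asarray(k, dtype=float)
        p = self.params
        if self.family == "normal":
            out = (k - p["mu"]) / p["sigma"]
        elif self.family == "uniform":
            out = (2.0 * k - (p["b"] + p["a"])) / (p["b"] - p["a"])
        elif self.family == "lognormal":
            if np.any(k <= 0):
                raise ValueError("lognormal parameter values must be positive")
            a = self.alpha
            out = (np.log(k / p["mu"]) + 0.5 * a * a) / a
        else:
            out = k
        return out if out.ndim else float(out)

    # -- config (de)serialization -----------------------------------------
    def to_dict(self) -> dict:
        return {"name": self.name, "family": self.family, **self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpec":
        d = dict(d)
        name = d.pop("name")
        family = d.pop("family")
        return cls(name, family, d)
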