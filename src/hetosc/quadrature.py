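"""One-dimensional probability quadrature rules for collocation.

Each rule supplies nodes (standardised parameter values) and weights
normalised against a probability density — uniform on [-1, 1] or the
standard normal — so that ``sum_i w_i f(x_i)`` approximates
``E[f(X)]``.  Downstream code therefore never multiplies by the density
itself.  The Gauss rules integrate polynomials up to degree 2N-1
exactly; the midpoint and inverse-CDF rules are second/first order; the
Monte Carlo rule converges as N^(-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.polynomial import hermite_e as npherm
from numpy.polynomial import legendre as npleg
from scipy import stats

__all__ = [
    "QuadratureRule1D",
    "legendre_rule",
    "midpoint_rule",
    "hermite_rule",
    "inverse_cdf_rule",
    "monte_carlo_rule",
    "make_rule",
]

UNIFORM = "uniform"
NORMAL = "standard_normal"

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class QuadratureRule1D:
    """Nodes and probability-normalised weights for one random direction."""

    kind: str
    nodes: np.ndarray
    weights: np.ndarray
    density: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.nodes.shape != self.weights.shape:
            raise ValueError("nodes and weights must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"probability weights must sum to 1, got {self.weights.sum()!r}"
            )

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    def integrate(self, f) -> float:
        """Approximate E[f(X)] under the rule's density."""
        return float(self.weights @ f(self.nodes))


def _check_n(N: int) -> int:
    N = int(N)
    if N < 1:
        raise ValueError(f"node count must be >= 1, got {N}")
    return N


def legendre_rule(N: int) -> QuadratureRule1D:
    """Gauss-Legendre rule for the uniform density on [-1, 1].

    Nodes are the N roots of the Legendre polynomial P_N; the classical
    weights are halved so they integrate against p(mu) = 1/2.  Exact for
    polynomials of degree <= 2N - 1.
    """
    N = _check_n(N)
    nodes, weights = npleg.leggauss(N)
    order = np.argsort(nodes)
    return QuadratureRule1D("gauss_legendre", nodes[order], weights[order] / 2.0, UNIFORM)


def midpoint_rule(N: int) -> QuadratureRule1D:
    """Composite midpoint rule on [-1, 1]: uniform nodes, weights 1/N."""
    N = _check_n(N)
    i = np.arange(1, N + 1, dtype=float)
    nodes = -1.0 + 2.0 * (i - 0.5) / N
    weights = np.full(N, 1.0 / N)
    return QuadratureRule1D("midpoint", nodes, weights, UNIFORM)


def hermite_rule(N: int) -> QuadratureRule1D:
    """Gauss-Hermite rule for the standard normal density.

    Nodes are the roots of the probabilists' Hermite polynomial He_N
    (He_0 = 1, He_1 = x, He_2 = x^2 - 1, ...); weights are
    N! / (N * He_{N-1}(x_j))^2, which already sum to 1 against the
    normal density.  Exact for polynomials of degree <= 2N - 1.
    """
    N = _check_n(N)
    nodes, weights = npherm.hermegauss(N)
    order = np.argsort(nodes)
    return QuadratureRule1D(
        "gauss_hermite", nodes[order], weights[order] / _SQRT_2PI, NORMAL
    )


def inverse_cdf_rule(N: int, density: str = NORMAL) -> QuadratureRule1D:
    """Equal-weight nodes at the density's (j - 1/2)/N quantiles.

    For the uniform density this reproduces the midpoint rule exactly
    (the CDF is affine); for the normal density the quantile map has an
    unbounded second derivative, which degrades the usual midpoint
    second-order convergence to first order.
    """
    N = _check_n(N)
    q = (np.arange(1, N + 1) - 0.5) / N
    if density == NORMAL:
        nodes = stats.norm.ppf(q)
    elif density == UNIFORM:
        nodes = stats.uniform(loc=-1.0, scale=2.0).ppf(q)
    else:
        raise ValueError(f"unsupported density {density!r}")
    return QuadratureRule1D("inverse_cdf", nodes, np.full(N, 1.0 / N), density)


def monte_carlo_rule(N: int, density: str = NORMAL, *, seed: int) -> QuadratureRule1D:
    """Equal-weight independent draws from the density.

    A seed is required; the same (N, density, seed) always reproduces
    the same rule.  Nodes are sorted ascending (the weights are equal,
    so sorting does not change the rule).
    """
    N = _check_n(N)
    if seed is None:
        raise ValueError("monte_carlo_rule requires an explicit seed")
    rng = np.random.default_rng(seed)
    if density == NORMAL:
        nodes = rng.standard_normal(N)
    elif density == UNIFORM:
        nodes = rng.uniform(-1.0, 1.0, N)
    else:
        raise ValueError(f"unsupported density {density!r}")
    return QuadratureRule1D(
        "monte_carlo", np.sort(nodes), np.full(N, 1.0 / N), density, seed=seed
    )


_RULE_ALIASES = {
    "gauss": "gauss_legendre",
    "gauss_legendre": "gauss_legendre",
    "legendre": "gauss_legendre",
    "midpoint": "midpoint",
    "gauss_hermite": "gauss_hermite",
    "hermite": "gauss_hermite",
    "icdf": "inverse_cdf",
    "inverse_cdf": "inverse_cdf",
    "mc": "monte_carlo",
    "monte_carlo": "monte_carlo",
}


def make_rule(
    kind: str, N: int, density: Optional[str] = None, seed: Optional[int] = None
) -> QuadratureRule1D:
    """Dispatch on a rule-kind name (accepts the common short aliases)."""
    try:
        canonical = _RULE_ALIASES[kind]
    except KeyError:
        raise ValueError(f"unknown rule kind {kind!r}") from None
    if canonical == "gauss_legendre":
        return legendre_rule(N)
    if canonical == "midpoint":
        return midpoint_rule(N)
    if canonical == "gauss_hermite":
        return hermite_rule(N)
    if canonical == "inverse_cdf":
        return inverse_cdf_rule(N, density or NORMAL)
    if seed is None:
        raise ValueError("monte_carlo rule requires a seed")
    return monte_carlo_rule(N, density or NORMAL, seed=seed)
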