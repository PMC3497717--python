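"""Multi-dimensional collocation grids for several heterogeneous parameters.

A :class:`ParameterGrid` holds nodes in standardised-variable space (one
column per heterogeneous direction) and one composite probability weight
per node.  Full tensor products take the Cartesian product of 1-D rules
with product weights; Smolyak sparse grids combine small tensor grids
with signed binomial coefficients and reach comparable accuracy with far
fewer nodes in higher dimension.  Grid nodes map to per-neuron model
parameters through ``value = location + scale * node``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .model import HETEROGENEOUS_PARAMETERS, ModelParameters, NeuronParameterTable
from .quadrature import QuadratureRule1D, legendre_rule, make_rule

__all__ = [
    "HeterogeneityAxis",
    "ParameterGrid",
    "tensor_product",
    "nested_family_size",
    "smolyak_grid",
    "count_distinct_nodes",
    "grid_to_parameters",
    "grid_from_axes",
    "save_grid",
    "load_grid",
]

#: Absolute tolerance under which two node coordinates are considered
#: coincident when merging sparse-grid component points.  Gauss nodes are
#: computed deterministically, so exact duplicates differ only by floating
#: round-off far below this.
MERGE_TOL = 1e-12
_MERGE_DECIMALS = 12


@dataclass(frozen=True)
class HeterogeneityAxis:
    """One heterogeneous direction of the model.

    The physical parameter value at a node x (a standardised variable,
    uniform on [-1, 1] or standard normal) is ``location + scale * x``;
    e.g. applied current Iapp = Im + Is*mu, or sodium conductance
    gNa = 2.8 + sigma*lambda.
    """

    parameter: str
    location: float
    scale: float
    density: str = "uniform"
    rule: str = "gauss_legendre"
    n_nodes: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.parameter not in HETEROGENEOUS_PARAMETERS:
            raise ValueError(
                f"unknown heterogeneous parameter {self.parameter!r}; "
                f"expected one of {HETEROGENEOUS_PARAMETERS}"
            )
        if self.scale < 0:
            raise ValueError("axis scale must be >= 0")

    def make_rule(self) -> QuadratureRule1D:
        return make_rule(self.rule, self.n_nodes, self.density, self.seed)

    @classmethod
    def uniform_range(
        cls, parameter: str, low: float, high: float, rule: str = "gauss_legendre", n_nodes: int = 10
    ) -> "HeterogeneityAxis":
        """Axis for a parameter uniformly distributed on [low, high]."""
        return cls(
            parameter=parameter,
            location=(low + high) / 2.0,
            scale=(high - low) / 2.0,
            density="uniform",
            rule=rule,
            n_nodes=n_nodes,
        )


@dataclass
class ParameterGrid:
    """Node/weight set in standardised-variable space.

    ``nodes`` is a (P, D) array, ``weights`` a length-P array summing to
    one.  Sparse grids may carry negative composite weights; nodes whose
    weights cancel exactly are retained (they are genuine grid points).
    """

    nodes: np.ndarray
    weights: np.ndarray
    provenance: str = "tensor"
    axes: Optional[Sequence[HeterogeneityAxis]] = None

    def __post_init__(self) -> None:
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.nodes.shape[0] != self.weights.size:
            raise ValueError("node row count must equal weight count")
        if self.nodes.shape[0] < 1:
            raise ValueError("grid must contain at least one node")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError(
                f"grid weights must sum to 1, got {self.weights.sum()!r}"
            )
        if self.axes is not None and len(self.axes) != self.ndim:
            raise ValueError("axis count must match node columns")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def ndim(self) -> int:
        return self.nodes.shape[1]

    def integrate(self, f) -> float:
        """Approximate the expectation of f over the grid's density."""
        return float(self.weights @ np.apply_along_axis(f, 1, self.nodes))


def tensor_product(
    rules: Sequence[QuadratureRule1D], axes: Optional[Sequence[HeterogeneityAxis]] = None
) -> ParameterGrid:
    """Full tensor product of 1-D rules: Cartesian nodes, product weights."""
    if len(rules) == 0:
        raise ValueError("tensor_product requires at least one rule")
    node_axes = [r.nodes for r in rules]
    mesh = np.meshgrid(*node_axes, indexing="ij")
    nodes = np.column_stack([m.ravel() for m in mesh])
    wmesh = np.meshgrid(*[r.weights for r in rules], indexing="ij")
    weights = np.ones(nodes.shape[0])
    for w in wmesh:
        weights = weights * w.ravel()
    return ParameterGrid(nodes=nodes, weights=weights, provenance="tensor", axes=axes)


def nested_family_size(i: int) -> int:
    """Node count of level i in the nested rule family: N_i = 2**(i+1) - 1.

    The family is nested in the level index; for Gauss-Legendre rules
    the node *sets* of successive levels share only the origin, and no
    code here assumes geometric inclusion.
    """
    i = int(i)
    if i < 0:
        raise ValueError(f"level index must be >= 0, got {i}")
    return 2 ** (i + 1) - 1


def _merge_key(row: np.ndarray) -> tuple:
    # +0.0 normalises -0.0 so mirrored nodes hash identically
    return tuple(np.round(row, _MERGE_DECIMALS) + 0.0)


def smolyak_grid(
    L: int,
    D: int,
    family: Callable[[int], QuadratureRule1D] = legendre_rule,
    axes: Optional[Sequence[HeterogeneityAxis]] = None,
) -> ParameterGrid:
    """Level-L Smolyak sparse grid in D dimensions.

    Uses the standard combination formula

        A(L, D) = sum_{max(0, L-D+1) <= |i| <= L}
                  (-1)**(L - |i|) * C(D-1, L - |i|) * (U^{i_1} x ... x U^{i_D})

    with 1-D rules of size N_i = 2**(i+1) - 1 drawn from ``family``.
    For D = 2 this reduces to the difference of the |i| = L and
    |i| = L - 1 tensor sums.  Coincident nodes (coordinates equal within
    ``MERGE_TOL``) are merged with weights summed; zero-weight nodes are
    kept.
    """
    L, D = int(L), int(D)
    if L < 0:
        raise ValueError(f"level must be >= 0, got {L}")
    if D < 1:
        raise ValueError(f"dimension must be >= 1, got {D}")

    rules = {lev: family(nested_family_size(lev)) for lev in range(L + 1)}
    accum: dict[tuple, tuple[np.ndarray, float]] = {}
    lo = max(0, L - D + 1)
    for total in range(lo, L + 1):
        coeff = (-1.0) ** (L - total) * math.comb(D - 1, L - total)
        if coeff == 0.0:
            continue
        for multi in _compositions(total, D):
            grid = tensor_product([rules[lev] for lev in multi])
            for row, w in zip(grid.nodes, grid.weights):
                key = _merge_key(row)
                if key in accum:
                    prev_row, prev_w = accum[key]
                    accum[key] = (prev_row, prev_w + coeff * w)
                else:
                    accum[key] = (row, coeff * w)

    nodes = np.array([rw[0] for rw in accum.values()])
    weights = np.array([rw[1] for rw in accum.values()])
    order = np.lexsort(nodes.T[::-1])
    return ParameterGrid(
        nodes=nodes[order],
        weights=weights[order],
        provenance=f"smolyak(level {L})",
        axes=axes,
    )


def _compositions(total: int, D: int):
    """All D-tuples of non-negative integers summing to ``total``."""
    if D == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, D - 1):
            yield (first,) + rest


def count_distinct_nodes(grid: ParameterGrid) -> int:
    """Number of distinct node locations (coordinates within MERGE_TOL)."""
    return len({_merge_key(row) for row in grid.nodes})


def grid_to_parameters(
    grid: ParameterGrid,
    base: ModelParameters,
    axes: Optional[Sequence[HeterogeneityAxis]] = None,
) -> NeuronParameterTable:
    """Map grid nodes to per-neuron parameter values.

    Row k of the table gets ``location_d + scale_d * nodes[k, d]`` for
    each axis d; every other parameter is copied from ``base``.  The
    grid's composite weight becomes the neuron's coupling weight.
    """
    axes = axes if axes is not None else grid.axes
    if axes is None:
        raise ValueError("no heterogeneity axes attached to the grid or supplied")
    if len(axes) != grid.ndim:
        raise ValueError(
            f"grid has {grid.ndim} columns but {len(axes)} axes were given"
        )
    names = [ax.parameter for ax in axes]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate heterogeneous parameter names: {names}")
    per_node = {
        ax.parameter: ax.location + ax.scale * grid.nodes[:, d]
        for d, ax in enumerate(axes)
    }
    return NeuronParameterTable.from_parameters(base, grid.weights, **per_node)


def grid_from_axes(axes: Sequence[HeterogeneityAxis]) -> ParameterGrid:
    """Full tensor grid from each axis's own 1-D rule."""
    return tensor_product([ax.make_rule() for ax in axes], axes=axes)


# ---------------------------------------------------------------------------
# Serialisation: CSV node table + JSON sidecar with axis metadata
# ---------------------------------------------------------------------------

def save_grid(grid: ParameterGrid, csv_path: str | Path) -> None:
    """Write nodes+weight as CSV and axis metadata as a JSON sidecar."""
    csv_path = Path(csv_path)
    ncols = grid.ndim
    header = ",".join([f"x{d}" for d in range(ncols)] + ["weight"])
    data = np.column_stack([grid.nodes, grid.weights])
    np.savetxt(csv_path, data, delimiter=",", header=header, comments="", fmt="%.17g")
    meta = {
        "provenance": grid.provenance,
        "n_nodes": grid.n_nodes,
        "ndim": grid.ndim,
        "axes": None
        if grid.axes is None
        else [
            {
                "parameter": ax.parameter,
                "location": ax.location,
                "scale": ax.scale,
                "density": ax.density,
                "rule": ax.rule,
                "n_nodes": ax.n_nodes,
                "seed": ax.seed,
            }
            for ax in grid.axes
        ],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_grid(csv_path: str | Path) -> ParameterGrid:
    """Read a grid written by :func:`save_grid`."""
    csv_path = Path(csv_path)
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    axes = None
    if meta.get("axes"):
        axes = [HeterogeneityAxis(**ax) for ax in meta["axes"]]
    return ParameterGrid(
        nodes=data[:, :-1],
        weights=data[:, -1],
        provenance=meta.get("provenance", "tensor"),
        axes=axes,
    )
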