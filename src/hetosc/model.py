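"""Reduced pre-Bötzinger complex network model.

The network consists of two-variable relaxation oscillators (membrane
potential ``V`` and persistent-sodium inactivation ``h``), all-to-all
coupled through an instantaneous excitatory synapse.  Each neuron obeys

    C dV_i/dt = -gNa * m(V_i) * h_i * (V_i - VNa) - gl * (V_i - Vl)
                + Isyn_i + Iapp_i,
    dh_i/dt   = (h_inf(V_i) - h_i) / tau(V_i),

with coupling

    Isyn_i = gsyn * (Vsyn_i - V_i) * sum_j w_j * s(V_j).

The weights ``w_j`` are quadrature weights: the sum approximates the
integral of ``s(V)`` against the probability density of the heterogeneous
parameter(s), so a small number of collocation neurons stands in for an
effectively infinite heterogeneous population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParameters",
    "NeuronParameterTable",
    "NetworkState",
    "s_gate",
    "ds_gate",
    "m_gate",
    "dm_gate",
    "hinf_gate",
    "dhinf_gate",
    "tau_gate",
    "synaptic_drive",
    "rhs",
    "rhs_flat",
    "pack_state",
    "unpack_state",
]

#: Names of model parameters that may be made heterogeneous across neurons.
HETEROGENEOUS_PARAMETERS = ("Iapp", "gNa", "gl", "gsyn", "VNa", "Vl", "Vsyn", "C", "eps")


@dataclass(frozen=True)
class ModelParameters:
    """Baseline constants of the reduced pre-Bötzinger neuron.

    Voltages are in mV, conductances and currents in the model's own
    units; no SI conversion is applied.  ``eps`` sets the slow time scale
    of the ``h`` gate (``tau`` is maximal, ``1/eps``, at V = -44 mV).
    ``Iapp`` is the applied-current baseline; heterogeneity is usually
    expressed on top of it as ``Iapp = Im + Is * mu``.
    """

    C: float = 0.21
    gNa: float = 2.8
    gl: float = 2.4
    gsyn: float = 0.3
    VNa: float = 50.0
    Vl: float = -65.0
    Vsyn: float = 0.0
    eps: float = 0.1
    Iapp: float = 17.5

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"capacitance C must be positive, got {self.C}")
        if not self.eps > 0:
            raise ValueError(f"gating rate scale eps must be positive, got {self.eps}")
        for name in ("gNa", "gl", "gsyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        return replace(self, **kwargs)


def _as_node_array(value, n: int) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    return arr


@dataclass
class NeuronParameterTable:
    """Per-neuron parameter values and coupling weights.

    One row per collocation node.  Every model parameter is stored as a
    length-P array (homogeneous parameters are broadcast from the
    baseline), so the right-hand side treats tensor grids, sparse grids
    and plain finite networks identically: a flat node list with one
    composite weight per node.  Sparse-grid composite weights may be
    negative; they are used as-is in the coupling sum.
    """

    weights: np.ndarray
    Iapp: np.ndarray
    C: np.ndarray
    gNa: np.ndarray
    gl: np.ndarray
    gsyn: np.ndarray
    VNa: np.ndarray
    Vl: np.ndarray
    Vsyn: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.size
        for name in HETEROGENEOUS_PARAMETERS:
            setattr(self, name, _as_node_array(getattr(self, name), n))
        if not np.isclose(self.weights.sum(), 1.0, rtol=0.0, atol=1e-12):
            raise ValueError(
                f"coupling weights must sum to 1 (got {self.weights.sum()!r})"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.size

    @classmethod
    def from_parameters(
        cls,
        params: ModelParameters,
        weights,
        **per_node: Mapping[str, np.ndarray] | np.ndarray,
    ) -> "NeuronParameterTable":
        """Build a table from baseline parameters plus per-node overrides.

        ``per_node`` maps parameter names (e.g. ``Iapp``, ``gNa``) to
        length-P arrays; everything else is broadcast from ``params``.
        """
        weights = np.asarray(weights, dtype=float)
        unknown = set(per_node) - set(HETEROGENEOUS_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown per-node parameters: {sorted(unknown)}")
        values = {name: per_node.get(name, getattr(params, name)) for name in HETEROGENEOUS_PARAMETERS}
        return cls(weights=weights, **values)

    def permuted(self, order: np.ndarray) -> "NeuronParameterTable":
        """Return a copy with nodes reordered by ``order``."""
        kw = {name: getattr(self, name)[order] for name in HETEROGENEOUS_PARAMETERS}
        return NeuronParameterTable(weights=self.weights[order], **kw)


@dataclass
class NetworkState:
    """Instantaneous network state: membrane potentials and gates."""

    V: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.atleast_1d(np.asarray(self.V, dtype=float))
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if self.V.shape != self.h.shape:
            raise ValueError("V and h must have equal length")

    @property
    def n_nodes(self) -> int:
        return self.V.size


# ---------------------------------------------------------------------------
# Gating functions
# ---------------------------------------------------------------------------

def s_gate(V):
    """Instantaneous synaptic activation, s(V) = 1 / (1 + exp(-(V+40)/5))."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("s_gate requires finite voltages")
    return expit((V + 40.0) / 5.0)


def ds_gate(V):
    """Derivative of :func:`s_gate` with respect to V."""
    s = s_gate(V)
    return s * (1.0 - s) / 5.0


def m_gate(V):
    """Instantaneous sodium activation, m(V) = 1 / (1 + exp(-(V+37)/6))."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("m_gate requires finite voltages")
    return expit((V + 37.0) / 6.0)


def dm_gate(V):
    m = m_gate(V)
    return m * (1.0 - m) / 6.0


def hinf_gate(V):
    """Steady-state sodium inactivation, h_inf(V) = 1 / (1 + exp((V+44)/6))."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("hinf_gate requires finite voltages")
    return expit(-(V + 44.0) / 6.0)


def dhinf_gate(V):
    h = hinf_gate(V)
    return -h * (1.0 - h) / 6.0


def tau_gate(V, eps: float):
    """Voltage-dependent h time constant, tau(V) = 1/(eps*cosh((V+44)/12)).

    Positive everywhere; maximal (= 1/eps) at V = -44 mV and symmetric
    about that voltage.
    """
    if not eps > 0:
        raise ValueError(f"eps must be positive, got {eps}")
    V = np.asarray(V, dtype=float)
    return 1.0 / (eps * np.cosh((V + 44.0) / 12.0))


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def synaptic_drive(V, weights, gsyn, Vsyn):
    """Per-neuron synaptic current gsyn*(Vsyn - V_i) * sum_j w_j s(V_j).

    ``weights`` are probability (quadrature) weights, so the sum is an
    approximation of the population integral of s(V); ``gsyn`` and
    ``Vsyn`` may be scalars or per-node arrays.
    """
    V = np.asarray(V, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if V.shape != weights.shape:
        raise ValueError(f"V and weights shapes differ: {V.shape} vs {weights.shape}")
    total = float(weights @ s_gate(V))
    return np.asarray(gsyn, dtype=float) * (np.asarray(Vsyn, dtype=float) - V) * total


def rhs_flat(t: float, y: np.ndarray, table: NeuronParameterTable) -> np.ndarray:
    """Time derivative of the packed state vector ``y = [V, h]``.

    This is the form consumed by the ODE integrator.  ``t`` is unused
    (the system is autonomous) but kept for the integrator signature.
    """
    n = table.n_nodes
    V = y[:n]
    h = y[n:]
    s = expit((V + 40.0) / 5.0)
    total = table.weights @ s
    Isyn = table.gsyn * (table.Vsyn - V) * total
    m = expit((V + 37.0) / 6.0)
    hinf = expit(-(V + 44.0) / 6.0)
    dV = (
        -table.gNa * m * h * (V - table.VNa)
        - table.gl * (V - table.Vl)
        + Isyn
        + table.Iapp
    ) / table.C
    dh = (hinf - h) * table.eps * np.cosh((V + 44.0) / 12.0)
    return np.concatenate((dV, dh))


def rhs(state: NetworkState, table: NeuronParameterTable) -> NetworkState:
    """Network vector field as a :class:`NetworkState` of derivatives."""
    if state.n_nodes != table.n_nodes:
        raise ValueError(
            f"state has {state.n_nodes} nodes but table has {table.n_nodes}"
        )
    dy = rhs_flat(0.0, pack_state(state), table)
    n = state.n_nodes
    return NetworkState(V=dy[:n], h=dy[n:])


def pack_state(state: NetworkState) -> np.ndarray:
    return np.concatenate((state.V, state.h))


def unpack_state(y: np.ndarray) -> NetworkState:
    n = y.size // 2
    return NetworkState(V=y[:n], h=y[n:])
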