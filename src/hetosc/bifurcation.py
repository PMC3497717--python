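"""Linear stability, Hopf-point location and synchrony break-up curves.

The heterogeneous network has (for the regimes studied here) a unique
fixed point whose stability changes at two Hopf bifurcations as the mean
applied current Im is varied.  Hopf points are located by bisection on
the sign of the largest real part of the Jacobian spectrum along the
continued fixed-point branch; the loss of the synchronised periodic
orbit ("break-up") is detected by direct simulation, stepping Im
downward and warm-starting each run from the previous final state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .dynamics import (
    FixedPoint,
    FixedPointError,
    NetworkState,
    default_initial_state,
    find_fixed_point,
    integrate,
    synchrony_check,
)
from .model import (
    NeuronParameterTable,
    dhinf_gate,
    dm_gate,
    ds_gate,
    hinf_gate,
    m_gate,
    pack_state,
    s_gate,
)

__all__ = [
    "HopfPoint",
    "BracketError",
    "jacobian",
    "jacobian_flat",
    "max_real_eigenvalue",
    "locate_hopf",
    "trace_hopf_curve",
    "find_breakup",
]


class BracketError(RuntimeError):
    """The scan bracket does not enclose exactly one stability change."""


@dataclass
class HopfPoint:
    """Parameter value at which a conjugate eigenvalue pair crosses the axis."""

    parameter: float
    frequency: float
    bracket_width: float
    held: dict = field(default_factory=dict)
    fixed_point: Optional[FixedPoint] = None


# ---------------------------------------------------------------------------
# Jacobian
# ---------------------------------------------------------------------------

def jacobian_flat(y: np.ndarray, table: NeuronParameterTable) -> np.ndarray:
    """Analytic Jacobian of the packed right-hand side at state ``y``.

    The synaptic coupling contributes a rank-one term
    d(Isyn_i)/dV_j = gsyn_i (Vsyn_i - V_i) w_j s'(V_j) on top of the
    diagonal single-neuron blocks.
    """
    n = table.n_nodes
    V = y[:n]
    h = y[n:]
    s = s_gate(V)
    S = float(table.weights @ s)
    m = m_gate(V)

    # dV-row: diagonal single-neuron part plus rank-one coupling.
    a = (
        -table.gNa * (dm_gate(V) * h * (V - table.VNa) + m * h)
        - table.gl
        - table.gsyn * S
    ) / table.C
    b = table.gsyn * (table.Vsyn - V) / table.C
    c = table.weights * ds_gate(V)
    A = np.diag(a) + np.outer(b, c)
    B = np.diag(-table.gNa * m * (V - table.VNa) / table.C)

    # dh-row: 1/tau written as g(V) = eps*cosh((V+44)/12).
    g = table.eps * np.cosh((V + 44.0) / 12.0)
    gp = table.eps * np.sinh((V + 44.0) / 12.0) / 12.0
    Cmat = np.diag(dhinf_gate(V) * g + (hinf_gate(V) - h) * gp)
    Dmat = np.diag(-g)

    top = np.hstack((A, B))
    bottom = np.hstack((Cmat, Dmat))
    return np.vstack((top, bottom))


def jacobian(state: NetworkState, table: NeuronParameterTable) -> np.ndarray:
    """Jacobian of the network vector field at a :class:`NetworkState`."""
    if state.n_nodes != table.n_nodes:
        raise ValueError("state size does not match parameter table")
    return jacobian_flat(pack_state(state), table)


def max_real_eigenvalue(fixed_point: FixedPoint) -> float:
    """Largest real part over the fixed point's spectrum (sign = stability)."""
    return fixed_point.max_real_eigenvalue


# ---------------------------------------------------------------------------
# Hopf location
# ---------------------------------------------------------------------------

def locate_hopf(
    table_factory: Callable[[float], NeuronParameterTable],
    bracket: tuple[float, float],
    *,
    xtol: float = 1e-6,
    eig_axis_tol: float = 1e-8,
    n_presteps: int = 6,
    held: Optional[dict] = None,
) -> HopfPoint:
    """Bisect the scan parameter to the stability change of the fixed point.

    ``table_factory`` maps a scan-parameter value (e.g. Im) to the
    neuron table; the fixed point is continued through the bracket with
    warm starts, and the bracket is halved on the sign of the maximal
    eigenvalue real part until its width falls below ``xtol``.

    Raises :class:`BracketError` when the endpoint stabilities agree.
    """
    a, b = float(bracket[0]), float(bracket[1])
    if not b > a:
        raise ValueError("bracket must satisfy a < b")

    solved: dict[float, FixedPoint] = {}

    def solve_at(value: float) -> FixedPoint:
        guess = None
        if solved:
            nearest = min(solved, key=lambda v: abs(v - value))
            guess = solved[nearest].state
        fp = find_fixed_point(table_factory(value), guess=guess)
        solved[value] = fp
        return fp

    # Walk the branch from a to b so every bisection start is warm.
    for value in np.linspace(a, b, max(n_presteps, 2)):
        solve_at(float(value))

    sig_a = solved[a].max_real_eigenvalue
    sig_b = solved[b].max_real_eigenvalue
    if np.sign(sig_a) == np.sign(sig_b):
        raise BracketError(
            f"no stability change in bracket [{a}, {b}]: "
            f"max Re(eig) = {sig_a:.3e} and {sig_b:.3e}"
        )

    lo, hi, sig_lo = a, b, sig_a
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        sig_mid = solve_at(mid).max_real_eigenvalue
        if np.sign(sig_mid) == np.sign(sig_lo):
            lo, sig_lo = mid, sig_mid
        else:
            hi = mid

    critical = 0.5 * (lo + hi)
    fp = solve_at(critical)
    eig = fp.eigenvalues
    # the conjugate pair nearest the axis carries the Hopf frequency
    near = eig[np.argsort(np.abs(eig.real))]
    pair = near[np.abs(near.imag) > 0]
    frequency = float(np.abs(pair[0].imag)) if pair.size else 0.0
    n_on_axis = int(np.sum(np.abs(eig.real) < eig_axis_tol))
    if pair.size == 0 or n_on_axis > 2:
        warnings.warn(
            f"eigenvalue structure at the located point is not a clean Hopf "
            f"pair ({n_on_axis} eigenvalues within {eig_axis_tol:g} of the axis)",
            stacklevel=2,
        )
    return HopfPoint(
        parameter=critical,
        frequency=frequency,
        bracket_width=hi - lo,
        held=dict(held or {}),
        fixed_point=fp,
    )


def trace_hopf_curve(
    factory_for: Callable[[float], Callable[[float], NeuronParameterTable]],
    scan_values: Sequence[float],
    initial_bracket: tuple[float, float],
    *,
    xtol: float = 1e-6,
    min_halfwidth: float = 1.0,
) -> list[tuple[float, HopfPoint]]:
    """Follow one Hopf branch as a second parameter is scanned.

    ``factory_for(second)`` returns the Im -> table factory at that value
    of the second parameter (Is or gsyn).  Brackets are re-centred on a
    linear extrapolation of the branch and widened on failure; a lost
    bracket truncates the curve with a warning.
    """
    points: list[tuple[float, HopfPoint]] = []
    bracket = (float(initial_bracket[0]), float(initial_bracket[1]))
    for second in scan_values:
        second = float(second)
        factory = factory_for(second)
        if len(points) >= 2:
            # extrapolate the branch to centre the next bracket
            (s0, hp0), (s1, hp1) = points[-2], points[-1]
            slope = (hp1.parameter - hp0.parameter) / (s1 - s0) if s1 != s0 else 0.0
            centre = hp1.parameter + slope * (second - s1)
            half = max(min_halfwidth, 2.0 * abs(hp1.parameter - hp0.parameter))
            bracket = (centre - half, centre + half)
        hp = None
        half = 0.5 * (bracket[1] - bracket[0])
        for _attempt in range(4):
            try:
                hp = locate_hopf(factory, bracket, xtol=xtol, held={"scan": second})
                break
            except (BracketError, FixedPointError):
                centre = 0.5 * (bracket[0] + bracket[1])
                half *= 2.0
                bracket = (centre - half, centre + half)
        if hp is None:
            warnings.warn(
                f"Hopf branch lost at scan value {second}; curve truncated",
                stacklevel=2,
            )
            break
        points.append((second, hp))
        half = max(min_halfwidth, 0.5 * (bracket[1] - bracket[0]))
        bracket = (hp.parameter - half, hp.parameter + half)
    return points


# ---------------------------------------------------------------------------
# Break-up of the synchronised orbit
# ---------------------------------------------------------------------------

def find_breakup(
    table_factory: Callable[[float], NeuronParameterTable],
    im_values: Sequence[float],
    *,
    settle_time: float = 300.0,
    window: float = 80.0,
    sample_dt: float = 0.05,
    abs_tol: float = 1e-8,
    rel_tol: float = 1e-8,
) -> Optional[float]:
    """First Im (stepping down ``im_values``) where synchrony is lost.

    Each step integrates ``settle_time`` units from the previous final
    state before an ``window``-unit sampled stretch is scored by
    :func:`synchrony_check`.  Returns None when the whole sweep stays
    synchronised.  The sweep must start synchronised.
    """
    im_values = [float(v) for v in im_values]
    if any(b >= a for a, b in zip(im_values, im_values[1:])):
        raise ValueError("im_values must be strictly decreasing")

    state = None
    for k, im in enumerate(im_values):
        table = table_factory(im)
        if state is None:
            state = default_initial_state(table)
        settled = integrate(
            state, table, (0.0, settle_time),
            abs_tol=abs_tol, rel_tol=rel_tol,
            t_eval=np.array([0.0, settle_time]),
        )
        t_eval = np.arange(0.0, window + sample_dt, sample_dt)
        sampled = integrate(
            settled.final_state(), table, (0.0, window),
            abs_tol=abs_tol, rel_tol=rel_tol, t_eval=t_eval,
        )
        verdict = synchrony_check(sampled)
        if not verdict.synchronized:
            if k == 0:
                raise ValueError(
                    f"sweep must start in the synchronised regime; "
                    f"not synchronised at Im={im}"
                )
            return im
        state = sampled.final_state()
    return None
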