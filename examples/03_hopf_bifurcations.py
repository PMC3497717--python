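"""Locate the Hopf bifurcations that bound the oscillatory regime.

As the mean applied current Im is varied at fixed heterogeneity spread
(Is = 7.5) and coupling (gsyn = 0.3), the network's unique fixed point
loses and regains stability in two Hopf bifurcations.  Each is located
by continuing the fixed point in Im and bisecting on the sign of the
largest real part of the Jacobian spectrum.
"""

from hetosc import ModelParameters, NeuronParameterTable, locate_hopf
from hetosc.quadrature import legendre_rule

params = ModelParameters()
rule = legendre_rule(40)


def table_at(Im):
    return NeuronParameterTable.from_parameters(
        params, rule.weights, Iapp=Im + 7.5 * rule.nodes
    )


upper = locate_hopf(table_at, (30.0, 36.0))
lower = locate_hopf(table_at, (4.0, 8.0))
print(f"upper Hopf: Im = {upper.parameter:.6f}, "
      f"crossing frequency {upper.frequency:.4f} rad/unit time")
print(f"lower Hopf: Im = {lower.parameter:.6f}, "
      f"crossing frequency {lower.frequency:.4f} rad/unit time")
print(f"\nSynchronised oscillations exist for Im between roughly "
      f"{lower.parameter:.2f} and {upper.parameter:.2f};")
print("outside this interval the population sits at a stable steady state.")
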