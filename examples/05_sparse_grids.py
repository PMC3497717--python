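"""Smolyak sparse grids for four simultaneously heterogeneous parameters.

With D heterogeneous parameters a full tensor grid needs N^D neurons.
Smolyak sparse grids combine small tensor grids with signed coefficients
and reach comparable accuracy with far fewer neurons.  Here applied
current, sodium conductance and the two reversal potentials are all
uniformly distributed, and the collective period is computed on full
and sparse grids.
"""

from hetosc import (
    ModelParameters,
    count_distinct_nodes,
    find_period,
    grid_to_parameters,
    smolyak_grid,
    tensor_product,
)
from hetosc.experiments import four_parameter_axes
from hetosc.quadrature import legendre_rule

params = ModelParameters()
axes = four_parameter_axes()
print("heterogeneous parameters:",
      ", ".join(f"{ax.parameter} in [{ax.location-ax.scale:g}, {ax.location+ax.scale:g}]"
                for ax in axes))

print("\nsparse-grid sizes (2-D): "
      f"A(2,2) = {count_distinct_nodes(smolyak_grid(2, 2))} nodes, "
      f"A(3,2) = {count_distinct_nodes(smolyak_grid(3, 2))} nodes "
      "(vs 121 for the full 11x11 tensor grid)")


def period(grid):
    table = grid_to_parameters(grid, params, axes)
    return find_period(table, abs_tol=1e-9, rel_tol=1e-9).period


reference = period(smolyak_grid(3, 4))
print(f"\nreference period (level-3 sparse grid, "
      f"{smolyak_grid(3, 4).n_nodes} neurons): {reference:.10f}\n")
print(f"{'grid':>12}  {'neurons':>8}  {'period error':>13}")
for label, grid in [
    ("tensor 2^4", tensor_product([legendre_rule(2)] * 4)),
    ("tensor 3^4", tensor_product([legendre_rule(3)] * 4)),
    ("sparse A(1,4)", smolyak_grid(1, 4)),
    ("sparse A(2,4)", smolyak_grid(2, 4)),
]:
    print(f"{label:>12}  {grid.n_nodes:>8}  {abs(period(grid) - reference):13.3e}")
print("\nAt a matched neuron budget the sparse grid is far more accurate:")
print("how the retained neurons are chosen matters more than how many.")
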