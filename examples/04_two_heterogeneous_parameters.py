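"""Two heterogeneous parameters: choosing nodes for a normal direction.

Applied current stays uniform (10 Gauss-Legendre nodes); the sodium
conductance gNa = 2.8 + 0.25*lambda is normally distributed.  Three ways
of picking M values of lambda are compared: random draws (Monte Carlo),
equal-probability quantiles (inverse CDF), and Gauss-Hermite nodes.
The full network is the tensor product: 10*M coupled neurons.
"""

from hetosc import ModelParameters, NeuronParameterTable, find_period, tensor_product
from hetosc.quadrature import (
    hermite_rule,
    inverse_cdf_rule,
    legendre_rule,
    monte_carlo_rule,
)

params = ModelParameters()
mu_rule = legendre_rule(10)
Im, Is, sigma = 25.0, 7.5, 0.25


def period(lambda_rule):
    grid = tensor_product([mu_rule, lambda_rule])
    table = NeuronParameterTable.from_parameters(
        params, grid.weights,
        Iapp=Im + Is * grid.nodes[:, 0],
        gNa=params.gNa + sigma * grid.nodes[:, 1],
    )
    return find_period(table, abs_tol=1e-9, rel_tol=1e-9).period


reference = period(hermite_rule(40))
print(f"reference period (Gauss-Hermite M=40): {reference:.10f}\n")
print(f"{'M':>3}  {'Monte Carlo':>13}  {'inverse CDF':>13}  {'Gauss-Hermite':>13}")
for M in (4, 8, 16):
    errs = (
        abs(period(monte_carlo_rule(M, seed=0)) - reference),
        abs(period(inverse_cdf_rule(M)) - reference),
        abs(period(hermite_rule(M)) - reference),
    )
    print(f"{M:>3}  {errs[0]:13.3e}  {errs[1]:13.3e}  {errs[2]:13.3e}")
print("\nErrors in the collective period: random sampling converges as")
print("M^-1/2, quantile sampling as M^-1, Gauss-Hermite spectrally fast.")
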