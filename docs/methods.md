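# Methods

## Model

The unit of the network is a two-variable relaxation oscillator for the
burst envelope of a pre-Bötzinger complex neuron: a fast membrane
potential `V` (mV) driven by a persistent sodium current with
instantaneous activation `m(V)` and slow inactivation `h`, a leak
current, synaptic input and an applied current.  The gating functions
are fixed sigmoids/hyperbolic forms:

- `s(V) = 1/(1+exp(-(V+40)/5))` — instantaneous synaptic activation;
- `m(V) = 1/(1+exp(-(V+37)/6))` — sodium activation (algebraic, no ODE);
- `h∞(V) = 1/(1+exp((V+44)/6))`, `τ(V) = 1/(ε cosh((V+44)/12))` — the
  slow gate's target and time constant, `τ` maximal (`1/ε`) at −44 mV.

Baseline constants (model units throughout, no SI conversion): `C=0.21`,
`gNa=2.8`, `gl=2.4`, `gsyn=0.3`, `VNa=50`, `Vl=−65`, `Vsyn=0`, `ε=0.1`.
Coupling is all-to-all and excitatory; `h` started in `[0,1]` stays
there because `h∞ ∈ (0,1)` and `τ > 0`.

Spiking currents are deliberately absent (high `V` means "bursting",
low `V` "quiescent"), and the synapse carries no state of its own.

## Collocation reduction

When the population is synchronised (or at rest), the state is a smooth
function of each heterogeneous parameter, so the population coupling
integral `∫ s(V(μ,t)) p(μ) dμ` can be discretised by quadrature.  Every
rule in `quadrature.py` is *probability-normalised*: its weights sum to
one and already absorb the density, so downstream code never multiplies
by `p(μ)` or `q(λ)`.  Available rules per direction:

| rule | density | nodes | order |
|---|---|---|---|
| `legendre_rule(N)` | uniform(−1,1) | Legendre roots | exact to degree 2N−1 |
| `hermite_rule(N)` | standard normal | probabilists' Hermite roots | exact to degree 2N−1 |
| `midpoint_rule(N)` | uniform(−1,1) | uniform spacing | O(N⁻²) |
| `inverse_cdf_rule(N)` | either | (j−½)/N quantiles | O(N⁻¹) for the normal* |
| `monte_carlo_rule(N, seed)` | either | random draws | O(N⁻¹ᐟ²) |

*The quantile map of the normal has an unbounded second derivative,
which degrades the nominal midpoint order to first; on the uniform
density the rule coincides with `midpoint_rule` exactly.  Monte Carlo
rules require an explicit seed; no global random state is consulted.

Nodes map to physical parameters by `value = location + scale·node`
(e.g. `Iapp = Im + Is·μ`, `gNa = 2.8 + σλ`).  A
`NeuronParameterTable` broadcasts every model constant to a per-node
array, so finite networks, tensor grids and sparse grids all flow
through one right-hand-side path with a flat node list and one
composite weight per node.  Sparse-grid composite weights can be
negative; the coupling sum uses them as-is.

## Grids in several heterogeneous dimensions

Full tensor grids take the Cartesian product of 1-D rules with product
weights.  Sparse grids use the Smolyak combination formula in its
standard general-D form

    A(L, D) = Σ_{max(0, L−D+1) ≤ |i| ≤ L}
              (−1)^{L−|i|} · C(D−1, L−|i|) · (U^{i₁} ⊗ … ⊗ U^{i_D}),

with 1-D rules of size `N_i = 2^{i+1} − 1`; at `D = 2` this reduces to
the difference of the `|i| = L` and `|i| = L−1` tensor sums.  The size
family is nested in the level index only — Gauss-Legendre node *sets*
of different sizes share only the origin, and nothing assumes geometric
inclusion.  Component-grid points are merged when all coordinates agree
within `1e-12` absolute (safe: Gauss nodes are computed
deterministically via the Golub–Welsch eigenvalue route in NumPy);
nodes whose combined weight cancels to zero are retained as geometric
grid points.  Distinct-node counts for the standard cases: the 11×11
tensor grid has 121 points, `A(2,2)` has 21, `A(3,2)` has 73, and
`A(6,10)` has 764,365 (under one million, so a level-6 calculation with
ten heterogeneous parameters remains desk-scale).

## Time integration and period measurement

Integration uses `scipy.integrate.solve_ivp` with DOP853 and default
tolerances absolute `1e-10`, relative `1e-12` (both configurable; the
unusual ordering is kept deliberately as the pairing under which the
reference period below was established).  The collocation error under
study can sit far below ordinary solver accuracy, which is why the
defaults are tight; studies whose assertions live at coarser levels use
documented looser settings (`1e-8`–`1e-10`) for speed.

Initial conditions are not part of the problem statement (the
synchronised orbit is strongly attracting), so the default start is
deterministic: `V_i = Vl + 5 + 5·ξ_i` with `ξ_i` an equispaced spread
over `[−1, 1]`, and `h_i = h∞(V_i)`.  The default transient discard is
100 time units (roughly twelve cycles of the 8-unit rhythm).

The period is measured on a Poincaré section of the weighted mean
voltage `V̄(t) = Σ w_i V_i`: the section level defaults to the midpoint
of the post-transient `V̄` range (the estimate is insensitive to the
level across the central half of that range), crossings are located by
the solver's dense output root-finder, and the period is the mean
spacing of successive upward crossings after the spacing has settled to
a relative `1e-9`.  A flat `V̄` or fewer than three crossings raises a
"no oscillation" error.  With a 100-node Gauss-Legendre grid at
`Im=17.5`, `Is=7.5` this machinery reproduces the continuum-limit
period 8.040104851819 to ~1e-11.

## Fixed points, Hopf location, break-up

Steady states solve `rhs = 0` by damped Newton (backtracking line
search, residual tolerance `1e-10`) with the closed-form Jacobian: the
coupling contributes a rank-one term
`∂Isyn_i/∂V_j = gsyn(Vsyn−V_i)·w_j·s′(V_j)` on top of diagonal 2×2
single-neuron blocks.  Without a user guess, Newton starts from the
best few of fifteen uniform-voltage candidates; a failing user guess
falls back to the same scan.  In the regimes studied the fixed point is
unique, so this lands on the same point from any reasonable start.

Hopf bifurcations are detected on the fixed-point branch (not by
periodic-orbit continuation): the branch is continued in the scan
parameter with warm starts, and the parameter is bisected on the sign
of the largest real part of the Jacobian spectrum to a bracket width of
`1e-6`, with an eigenvalue-axis tolerance of `1e-8` for the clean-pair
diagnostic.  Two-parameter Hopf curves re-centre each bracket on a
linear extrapolation of the branch and widen it on failure, truncating
with a warning if the branch is lost.

Loss of the synchronised orbit is found by direct simulation, stepping
the mean drive `Im` downward (default step 0.25, 300-unit settle per
step, both configurable — no stepping protocol is prescribed by the
problem) and warm-starting each run from the previous final state.  The
operational synchrony criterion: each node's upward crossings of its own
mid-range voltage level are counted over the interior of the sampled
window (counting between the first and last reference crossings avoids
spurious off-by-one counts from window edges), and the network is
synchronised when all counts agree and matched crossing times spread by
less than a quarter period.  The quarter-period bound is a choice; it
fires somewhat before hard cycle-count divergence in very heterogeneous
populations, which is acceptable for a qualitative break-up curve.
Break-up sweeps default to solver tolerances `1e-8`/`1e-8` since the
verdict is a yes/no flag, not a spectral quantity.  Near the lower Hopf
the periodic orbit is of canard type and its amplitude explodes almost
discontinuously; no code assumes period continuity there, and sweeps
that need that region should use small `Im` steps.

## Convergence studies

Each study in `experiments.py` measures period or Hopf-location error
over a node-count sweep against a high-resolution reference computed
the same way, then fits an ordinary-least-squares slope to log₁₀ error
versus log₁₀ N.  The reference's own error is estimated from a
half-resolution rerun, and points below 10× that estimate are excluded
from the fit (they sit on the integration/bisection floor and would
bias the slope); the floor and the points used are recorded in the
study metadata.  Default reference sizes: Gauss-Legendre N=200 for the
one-parameter period study, M=60 Gauss-Hermite for the normal
direction, a level-4 sparse grid for the four-parameter study.  Monte
Carlo runs are repeated over an explicit seed list (default 0…9) and
absolute errors are averaged (averaging signed errors would understate
the sampling error).  Expected orders, confirmed by the test suite:
midpoint period error N⁻², lower-Hopf midpoint error N⁻¹ (the upper
point gives N⁻², an asymmetry reproduced but not explained here), Monte
Carlo M⁻¹ᐟ², inverse-CDF M⁻¹, with Gauss rules saturating at the
reference floor within ~10–20 nodes per direction.

The test suite runs these studies at documented reduced sizes (e.g.
N ∈ {10…80} against a Gauss N=50 reference for the period study,
N ∈ {10…160} for the lower Hopf, M ∈ {2…32} for the two-parameter
study, tensor 3⁴ vs sparse level 2 against a level-3 reference for the
four-parameter comparison) — chosen as the smallest sweeps on which the
fitted orders are stable.

## What the study conditions do and do not emulate

All inputs are synthetic by construction: the model *is* the object of
study and carries no external data.  The standard conditions are
`Iapp` uniform on [10, 25] (`Im=17.5`, `Is=7.5`), `gNa` normal with
mean 2.8 and σ=0.25 where a second heterogeneity is present, and the
four-axis uniform setup (`Iapp` ∈ [17.5, 32.5], `gNa` ∈ [2.55, 3.05],
`Vsyn` ∈ [−1, 1], `VNa` ∈ [49, 51]).  Passing tests show that the
collocation machinery reproduces the continuum-limit dynamics of *this*
reduced model; they say nothing about spiking-level dynamics, about
correlated heterogeneity (all directions are assumed independent), or
about regimes where the population desynchronises and the
state-vs-parameter map loses smoothness — there the method's central
assumption fails by design, and the package only reports the loss of
synchrony rather than characterising the complex oscillations beyond
it.

## Known limitations

- Hopf detection relies on the fixed-point branch being unique and
  continuable through the bracket; branch switching and periodic-orbit
  (Floquet) continuation are not implemented.
- Sparse grids use only the Gauss-Legendre nested-size family;
  Clenshaw-Curtis/Gauss-Patterson families and dimension-adaptive
  refinement are out of scope.
- Quadrature for discrete densities (e.g. degree distributions of
  non-all-to-all networks) is not provided.
- The break-up criterion is operational, not dynamical; its curve can
  shift slightly with the sweep rate, settle time and offset bound.
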