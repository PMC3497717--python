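"""Tests for Jacobians, Hopf location, Hopf curves and break-up sweeps."""

import numpy as np
import pytest

from hetosc import (
    HeterogeneityAxis,
    ModelParameters,
    NetworkState,
    NeuronParameterTable,
    find_breakup,
    grid_to_parameters,
    jacobian,
    legendre_rule,
    locate_hopf,
    tensor_product,
    trace_hopf_curve,
)
from hetosc.bifurcation import BracketError, jacobian_flat
from hetosc.model import hinf_gate, pack_state, rhs_flat
from hetosc.quadrature import hermite_rule

from conftest import iapp_factory, iapp_table


def finite_difference_jacobian(y, table, step=1e-6):
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        plus, minus = y.copy(), y.copy()
        plus[j] += step
        minus[j] -= step
        J[:, j] = (rhs_flat(0.0, plus, table) - rhs_flat(0.0, minus, table)) / (2 * step)
    return J


class TestJacobian:
    def _random_table_and_state(self, seed):
        rng = np.random.default_rng(seed)
        axes = [
            HeterogeneityAxis("Iapp", 17.5, 7.5, n_nodes=3),
            HeterogeneityAxis("gNa", 2.8, 0.25, density="standard_normal",
                              rule="gauss_hermite", n_nodes=2),
        ]
        grid = tensor_product([legendre_rule(3), hermite_rule(2)], axes=axes)
        table = grid_to_parameters(grid, ModelParameters())
        y = np.concatenate(
            [rng.uniform(-60, -20, table.n_nodes), rng.uniform(0.1, 0.9, table.n_nodes)]
        )
        return table, y

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        table, y = self._random_table_and_state(seed)
        J = jacobian_flat(y, table)
        J_fd = finite_difference_jacobian(y, table)
        scale = 1.0 + np.abs(J_fd)
        assert np.max(np.abs(J - J_fd) / scale) < 1e-6

    def test_uncoupled_network_is_block_diagonal(self, params):
        rule = legendre_rule(4)
        table = NeuronParameterTable.from_parameters(
            params, rule.weights, Iapp=17.5 + 7.5 * rule.nodes, gsyn=0.0
        )
        V = np.linspace(-55, -30, 4)
        J = jacobian(NetworkState(V=V, h=hinf_gate(V)), table)
        # only (i,i), (i,i+n), (i+n,i), (i+n,i+n) entries may be nonzero
        mask = np.zeros_like(J, dtype=bool)
        n = 4
        for i in range(n):
            mask[i, i] = mask[i, i + n] = mask[i + n, i] = mask[i + n, i + n] = True
        assert np.all(J[~mask] == 0.0)

    def test_permutation_similarity(self, params):
        rng = np.random.default_rng(5)
        rule = legendre_rule(5)
        table = iapp_table(rule, 17.5, 7.5, params)
        y = np.concatenate([rng.uniform(-60, -20, 5), rng.uniform(0.1, 0.9, 5)])
        perm = rng.permutation(5)
        table_p = table.permuted(perm)
        y_p = np.concatenate([y[:5][perm], y[5:][perm]])
        # full-state permutation matrix acting on (V, h) blocks
        P = np.zeros((10, 10))
        for new, old in enumerate(perm):
            P[new, old] = 1.0
            P[new + 5, old + 5] = 1.0
        J = jacobian_flat(y, table)
        J_p = jacobian_flat(y_p, table_p)
        assert np.allclose(J_p, P @ J @ P.T, atol=1e-12)


class TestLocateHopf:
    def test_upper_hopf_location(self, params):
        hp = locate_hopf(iapp_factory(legendre_rule(20), 7.5, params), (30.0, 36.0))
        assert hp.parameter == pytest.approx(33.1262, abs=1e-3)
        assert hp.bracket_width < 1e-6
        assert hp.frequency > 0

    def test_bracket_choice_invariance(self, params):
        factory = iapp_factory(legendre_rule(10), 7.5, params)
        a = locate_hopf(factory, (30.0, 36.0))
        b = locate_hopf(factory, (31.5, 34.5))
        assert abs(a.parameter - b.parameter) < 5e-6

    def test_clean_conjugate_pair_at_hopf(self, params):
        hp = locate_hopf(iapp_factory(legendre_rule(10), 7.5, params), (30.0, 36.0))
        eig = hp.fixed_point.eigenvalues
        near_axis = eig[np.abs(eig.real) < 1e-4]
        assert near_axis.size == 2
        assert np.all(np.abs(near_axis.imag) > 0.1)

    def test_zero_spread_matches_single_self_coupled_neuron(self, params):
        net = locate_hopf(iapp_factory(legendre_rule(8), 0.0, params), (28.0, 33.0))
        single = locate_hopf(iapp_factory(legendre_rule(1), 0.0, params), (28.0, 33.0))
        assert net.parameter == pytest.approx(single.parameter, abs=5e-6)

    def test_missing_sign_change_raises(self, params):
        with pytest.raises(BracketError):
            locate_hopf(iapp_factory(legendre_rule(8), 7.5, params), (20.0, 25.0))


class TestTwoParameterTrends:
    def test_heterogeneity_widens_oscillatory_interval(self, params):
        """Raising the spread Is pushes the upper Hopf to higher Im and the
        lower Hopf to lower Im."""
        rule = legendre_rule(10)
        upper = {
            Is: locate_hopf(iapp_factory(rule, Is, params), (28.0, 40.0)).parameter
            for Is in (2.0, 10.0)
        }
        lower = {
            Is: locate_hopf(iapp_factory(rule, Is, params), (3.0, 16.0)).parameter
            for Is in (2.0, 10.0)
        }
        assert upper[10.0] > upper[2.0]
        assert lower[10.0] < lower[2.0]

    def test_stronger_coupling_moves_both_hopfs_down(self, params):
        rule = legendre_rule(10)

        def factory(gsyn):
            def make(Im):
                return NeuronParameterTable.from_parameters(
                    params, rule.weights, Iapp=Im + 7.5 * rule.nodes, gsyn=gsyn
                )
            return make

        up_weak = locate_hopf(factory(0.2), (28.0, 40.0)).parameter
        up_strong = locate_hopf(factory(0.4), (28.0, 40.0)).parameter
        lo_weak = locate_hopf(factory(0.2), (3.0, 10.0)).parameter
        lo_strong = locate_hopf(factory(0.4), (3.0, 10.0)).parameter
        assert up_strong < up_weak
        assert lo_strong < lo_weak

    def test_trace_hopf_curve_follows_branch(self, params):
        rule = legendre_rule(10)
        points = trace_hopf_curve(
            lambda Is: iapp_factory(rule, Is, params), [2.0, 6.0, 10.0], (28.0, 36.0)
        )
        assert len(points) == 3
        im_values = [hp.parameter for _, hp in points]
        assert im_values == sorted(im_values)  # upper branch rises with Is


class TestBreakup:
    def test_strong_heterogeneity_breaks_up_above_lower_hopf(self, params):
        factory = iapp_factory(legendre_rule(10), 14.0, params)
        critical = find_breakup(
            factory, np.arange(28.0, 14.0 - 1e-9, -2.0),
            settle_time=150.0, window=80.0,
        )
        assert critical is not None
        assert critical > 8.0  # far above the lower Hopf

    def test_mild_heterogeneity_stays_synchronized(self, params):
        factory = iapp_factory(legendre_rule(10), 4.0, params)
        critical = find_breakup(
            factory, np.arange(28.0, 12.0 - 1e-9, -2.0),
            settle_time=150.0, window=80.0,
        )
        assert critical is None

    def test_breakup_involves_lowest_drive_nodes(self, params):
        """Past break-up the deviant cycle counts belong to the neurons
        with the lowest applied current."""
        from hetosc import default_initial_state, integrate, synchrony_check

        table = iapp_table(legendre_rule(10), 14.0, 14.0, params)
        settled = integrate(
            default_initial_state(table), table, (0.0, 300.0),
            t_eval=np.array([0.0, 300.0]), abs_tol=1e-8, rel_tol=1e-8,
        )
        sampled = integrate(
            settled.final_state(), table, (0.0, 100.0),
            t_eval=np.arange(0.0, 100.0, 0.05), abs_tol=1e-8, rel_tol=1e-8,
        )
        verdict = synchrony_check(sampled)
        assert not verdict.synchronized
        counts = verdict.cycle_counts
        majority = np.bincount(counts).argmax()
        deviants = np.flatnonzero(counts != majority)
        assert deviants.size > 0
        assert np.all(deviants < 5)  # nodes are sorted by ascending Iapp

    def test_must_start_synchronized(self, params):
        factory = iapp_factory(legendre_rule(10), 14.0, params)
        with pytest.raises(ValueError):
            find_breakup(factory, [14.0, 12.0], settle_time=150.0, window=80.0)
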