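"""Tests for integration, period measurement, fixed points and synchrony."""

import numpy as np
import pytest

from hetosc import (
    ModelParameters,
    NetworkState,
    NeuronParameterTable,
    default_initial_state,
    find_fixed_point,
    find_period,
    integrate,
    legendre_rule,
    population_mean,
    population_variance,
    save_trajectory,
    synchrony_check,
)
from hetosc.dynamics import NoOscillationError
from hetosc.model import hinf_gate

from conftest import iapp_table

# Loosened-but-ample solver settings for tests whose assertions live at
# the 1e-7 level or coarser; the defaults (1e-10/1e-12) are exercised in
# the acceptance tests.
FAST = dict(abs_tol=1e-10, rel_tol=1e-10)


def single_neuron_table(Im, gsyn=0.3, params=None):
    params = params or ModelParameters()
    return NeuronParameterTable.from_parameters(
        params, [1.0], Iapp=Im, gsyn=gsyn
    )


class TestPopulationObservables:
    def test_constant_population(self):
        w = np.full(4, 0.25)
        V = np.full(4, -52.0)
        assert population_mean(V, w) == pytest.approx(-52.0)
        assert population_variance(V, w) == pytest.approx(0.0, abs=1e-25)

    def test_hand_values(self):
        V = np.array([-60.0, -20.0])
        w = np.array([0.5, 0.5])
        assert population_mean(V, w) == pytest.approx(-40.0)
        assert population_variance(V, w) == pytest.approx(400.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(-60, -20, 6)
        w = legendre_rule(6).weights
        perm = rng.permutation(6)
        assert population_variance(V[perm], w[perm]) == pytest.approx(
            population_variance(V, w), rel=1e-13
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            population_mean(np.zeros(3), np.full(2, 0.5))


class TestIntegrate:
    def test_zero_spread_trajectories_coincide(self, params):
        """With no heterogeneity and identical starts, every node follows
        the single self-coupled neuron trajectory."""
        rule = legendre_rule(5)
        table = iapp_table(rule, 17.5, 0.0, params)
        V0 = np.full(5, -55.0)
        state = NetworkState(V=V0, h=hinf_gate(V0))
        t_eval = np.linspace(0.0, 40.0, 200)
        traj = integrate(state, table, (0.0, 40.0), t_eval=t_eval, **FAST)
        assert np.max(np.ptp(traj.V, axis=1)) < 1e-8

        single = single_neuron_table(17.5, params=params)
        s0 = NetworkState(V=[-55.0], h=hinf_gate(np.array([-55.0])))
        ref = integrate(s0, single, (0.0, 40.0), t_eval=t_eval, **FAST)
        assert np.max(np.abs(traj.V[:, 0] - ref.V[:, 0])) < 1e-7

    def test_h_stays_in_unit_interval(self, baseline_table):
        traj = integrate(
            default_initial_state(baseline_table), baseline_table, (0.0, 60.0),
            t_eval=np.linspace(0.0, 60.0, 400), **FAST,
        )
        assert traj.h.min() >= 0.0 and traj.h.max() <= 1.0

    def test_dimension_mismatch(self, baseline_table):
        state = NetworkState(V=np.zeros(3), h=np.zeros(3))
        with pytest.raises(ValueError):
            integrate(state, baseline_table, (0.0, 1.0))


class TestFindPeriod:
    def test_zero_spread_equals_single_neuron(self, params):
        """Is=0 collapses the network onto one self-coupled oscillator."""
        net = find_period(iapp_table(legendre_rule(8), 17.5, 0.0, params), **FAST)
        single = find_period(single_neuron_table(17.5, params=params), **FAST)
        assert net.period == pytest.approx(single.period, rel=1e-8)

    def test_section_level_independence(self, baseline_table):
        """The period does not depend on where the Poincaré section is
        placed within the central part of the mean-voltage range."""
        base = find_period(baseline_table, **FAST)
        for shift in (-5.0, +5.0):
            est = find_period(
                baseline_table, section_level=base.section_level + shift, **FAST
            )
            assert est.period == pytest.approx(base.period, rel=1e-8)

    def test_quiescent_network_raises(self, params):
        # an uncoupled neuron at high drive sits at a stable fixed point
        table = single_neuron_table(38.0, gsyn=0.0, params=params)
        with pytest.raises(NoOscillationError):
            find_period(table, **FAST)

    def test_single_neuron_period_decreases_with_drive(self, params):
        """For the uncoupled neuron the period falls monotonically as the
        applied current rises through the oscillatory range."""
        periods = [
            find_period(single_neuron_table(Im, gsyn=0.0, params=params), **FAST).period
            for Im in (15.0, 18.0, 22.0, 28.0)
        ]
        assert all(a > b for a, b in zip(periods, periods[1:]))

    def test_spectral_rule_outconverges_midpoint(self, params):
        """Refining a Gauss grid 10->40 changes the period far less than
        refining a midpoint grid 40->160: spectral vs second-order."""
        from hetosc import midpoint_rule

        g10 = find_period(iapp_table(legendre_rule(10), 17.5, 7.5, params), **FAST)
        g40 = find_period(iapp_table(legendre_rule(40), 17.5, 7.5, params), **FAST)
        m40 = find_period(iapp_table(midpoint_rule(40), 17.5, 7.5, params), **FAST)
        m160 = find_period(iapp_table(midpoint_rule(160), 17.5, 7.5, params), **FAST)
        assert abs(g40.period - g10.period) < 0.01 * abs(m160.period - m40.period)


class TestFixedPoint:
    def test_residual_contract(self, baseline_table):
        fp = find_fixed_point(baseline_table)
        assert fp.residual_norm < 1e-10
        assert fp.eigenvalues.shape == (2 * baseline_table.n_nodes,)

    def test_single_uncoupled_point_lies_on_nullclines(self, params):
        table = single_neuron_table(15.0, gsyn=0.0, params=params)
        fp = find_fixed_point(table)
        V, h = fp.state.V[0], fp.state.h[0]
        # h-nullcline: h = hinf(V); V-nullcline: dV/dt = 0 at that h
        assert h == pytest.approx(float(hinf_gate(V)), abs=1e-10)
        assert fp.residual_norm < 1e-10

    def test_unique_across_guesses(self, params):
        """Over the single-neuron drive range there is one fixed point:
        Newton lands on it from different starting voltages."""
        for Im in (10.0, 20.0, 38.0):
            table = single_neuron_table(Im, gsyn=0.0, params=params)
            found = []
            for v0 in (-65.0, -40.0, -15.0):
                state = NetworkState(V=[v0], h=hinf_gate(np.array([v0])))
                found.append(find_fixed_point(table, guess=state).state.V[0])
            assert np.ptp(found) < 1e-8

    def test_high_drive_uncoupled_is_stable(self, params):
        fp = find_fixed_point(single_neuron_table(38.0, gsyn=0.0, params=params))
        assert fp.stable


class TestSynchrony:
    def _sampled(self, table, t_settle=200.0, window=80.0):
        settled = integrate(
            default_initial_state(table), table, (0.0, t_settle),
            t_eval=np.array([0.0, t_settle]), abs_tol=1e-8, rel_tol=1e-8,
        )
        return integrate(
            settled.final_state(), table, (0.0, window),
            t_eval=np.arange(0.0, window, 0.05), abs_tol=1e-8, rel_tol=1e-8,
        )

    def test_baseline_network_is_synchronized(self, baseline_table):
        verdict = synchrony_check(self._sampled(baseline_table))
        assert verdict.conclusive and verdict.synchronized
        assert np.all(verdict.cycle_counts == verdict.cycle_counts[0])

    def test_weak_coupling_desynchronizes(self, params):
        table = NeuronParameterTable.from_parameters(
            params, legendre_rule(10).weights,
            Iapp=12.0 + 7.5 * legendre_rule(10).nodes, gsyn=0.05,
        )
        verdict = synchrony_check(self._sampled(table))
        assert not verdict.synchronized

    def test_single_node_trivially_synchronized(self, params):
        verdict = synchrony_check(self._sampled(single_neuron_table(17.5, params=params)))
        assert verdict.synchronized

    def test_short_window_is_inconclusive(self, baseline_table):
        short = self._sampled(baseline_table, window=10.0)
        verdict = synchrony_check(short)
        assert not verdict.conclusive


def test_trajectory_export(tmp_path, baseline_table):
    traj = integrate(
        default_initial_state(baseline_table), baseline_table, (0.0, 5.0),
        t_eval=np.linspace(0.0, 5.0, 50), **FAST,
    )
    path = tmp_path / "traj.csv"
    save_trajectory(traj, path, {"Im": 17.5, "Is": 7.5})
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    assert data.shape == (50, 1 + 2 * baseline_table.n_nodes)
    assert np.allclose(data[:, 0], traj.times)
    meta = (tmp_path / "traj.json").read_text()
    assert "Im" in meta and "weights" in meta
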