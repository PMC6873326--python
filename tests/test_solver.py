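"""Solver tests: assembly, Hines elimination, convergence, conservation."""

import numpy as np
import pytest

from colsim.cells import CompartmentTree, SynapseSpec
from colsim.errors import ConfigurationError, NumericDivergenceError, SingularSystemError
from colsim.solver import (
    SolverState,
    SynapticEvent,
    TreeSystem,
    advance_step,
    assemble_system,
    compile_forest,
    detect_spikes,
    hines_solve,
    initial_state,
    step_forest,
)
from conftest import passive_template, random_tree


def _dense_assembly(template, state, dt):
    """Independent dense construction of the Crank-Nicolson system."""
    tree = template.tree
    n = tree.n_comp
    C = tree.capacitance()
    gl = tree.leak_conductance()
    L = np.zeros((n, n))
    for i in range(1, n):
        p = tree.parent[i]
        g = tree.axial_conductance()[i]
        L[i, i] += g
        L[p, p] += g
        L[i, p] -= g
        L[p, i] -= g
    A = np.diag(C / dt + 0.5 * gl) + 0.5 * L
    rhs = (C / dt - 0.5 * gl) * state.V - 0.5 * (L @ state.V) + gl * tree.leak_reversal
    return A, rhs


class TestAssembleSystem:
    def test_single_compartment_matches_scalar_trapezoid(self, passive_single):
        dt = 25e-6
        state = initial_state(compile_forest(passive_single))
        state.V = np.array([-0.040])
        system = assemble_system(passive_single, state, dt)
        V1 = hines_solve(system)
        tree = passive_single.tree
        tau = tree.membrane_resistivity[0] * tree.membrane_capacitance[0]
        E = tree.leak_reversal[0]
        # closed-form trapezoidal update of dV/dt = -(V-E)/tau
        a = dt / (2 * tau)
        expected = ((1 - a) * state.V[0] + 2 * a * E) / (1 + a)
        assert V1[0] == pytest.approx(expected, rel=1e-12)

    def test_equal_voltages_on_identical_pair_stay_equal(self):
        tree = CompartmentTree([-1, 0], 30e-6, 2e-6, 1.0, 1.0, 0.01, -0.065)
        tmpl = passive_template(tree)
        state = initial_state(compile_forest(tmpl))
        state.V = np.array([-0.030, -0.030])
        system = assemble_system(tmpl, state, 25e-6)
        assert system.rhs[0] == pytest.approx(system.rhs[1], rel=1e-12)
        V1 = hines_solve(system)
        assert V1[0] == pytest.approx(V1[1], rel=1e-14)

    def test_seven_compartment_tree_matches_dense_assembly(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 7)
        tmpl = passive_template(tree)
        state = initial_state(compile_forest(tmpl))
        state.V = rng.uniform(-0.08, 0.0, 7)
        dt = 25e-6
        system = assemble_system(tmpl, state, dt)
        A_dense, rhs_dense = _dense_assembly(tmpl, state, dt)
        np.testing.assert_allclose(system.dense(), A_dense, rtol=1e-12)
        np.testing.assert_allclose(system.rhs, rhs_dense, rtol=1e-12)

    def test_zero_dt_rejected(self, passive_single):
        state = initial_state(compile_forest(passive_single))
        with pytest.raises(ConfigurationError):
            assemble_system(passive_single, state, 0.0)


class TestHinesSolve:
    def test_identity_returns_rhs(self):
        rhs = np.array([1.0, 2.0, 3.0])
        system = TreeSystem(
            diag=np.ones(3), off=np.zeros(3), rhs=rhs.copy(),
            parent=np.array([-1, 0, 1]),
        )
        np.testing.assert_allclose(hines_solve(system), rhs)

    def test_matches_dense_lu_on_100_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            tree = random_tree(rng, n)
            tmpl = passive_template(tree)
            state = initial_state(compile_forest(tmpl))
            state.V = rng.uniform(-0.08, 0.02, n)
            system = assemble_system(tmpl, state, 25e-6)
            x_hines = hines_solve(system)
            x_dense = np.linalg.solve(system.dense(), system.rhs)
            np.testing.assert_allclose(x_hines, x_dense, rtol=1e-10)

    def test_zero_pivot_raises(self):
        system = TreeSystem(
            diag=np.array([1.0, 0.0]), off=np.array([0.0, 0.5]),
            rhs=np.ones(2), parent=np.array([-1, 0]),
        )
        with pytest.raises(SingularSystemError):
            hines_solve(system)

    def test_chain_relaxes_to_common_leak_reversal(self):
        tree = CompartmentTree([-1, 0, 1], 50e-6, 2e-6, 1.0, 1.0, 0.01, -0.065)
        tmpl = passive_template(tree)
        forest = compile_forest(tmpl)
        state = initial_state(forest)
        state.V = np.array([-0.02, -0.09, 0.01])
        for _ in range(20000):
            state, _ = step_forest(forest, state, 25e-6)
        np.testing.assert_allclose(state.V, -0.065, atol=1e-9)


class TestAdvanceStep:
    def test_passive_decay_matches_analytic_rc(self, passive_single):
        forest = compile_forest(passive_single)
        tree = passive_single.tree
        tau = tree.membrane_resistivity[0] * tree.membrane_capacitance[0]
        E, V0 = tree.leak_reversal[0], -0.020
        dt, k = 100e-6, 50
        state = initial_state(forest)
        state.V = np.array([V0])
        for _ in range(k):
            state = advance_step(passive_single, state, dt)
        analytic = (V0 - E) * np.exp(-k * dt / tau) + E
        # trapezoidal rule: O(dt^2) local accuracy
        assert state.V[0] == pytest.approx(analytic, abs=5e-7)

    def test_second_order_convergence_under_dt_halving(self, passive_single):
        forest = compile_forest(passive_single)
        tree = passive_single.tree
        tau = tree.membrane_resistivity[0] * tree.membrane_capacitance[0]
        E, V0, T = tree.leak_reversal[0], -0.020, 5e-3
        analytic = (V0 - E) * np.exp(-T / tau) + E
        errors = []
        for dt in (200e-6, 100e-6, 50e-6):
            state = initial_state(forest)
            state.V = np.array([V0])
            for _ in range(int(round(T / dt))):
                state = advance_step(passive_single, state, dt)
            errors.append(abs(state.V[0] - analytic))
        r1 = errors[0] / errors[1]
        r2 = errors[1] / errors[2]
        assert 3.0 < r1 < 5.0  # ~4x error reduction per dt halving
        assert 3.0 < r2 < 5.0

    def test_zero_dt_forbidden(self, passive_single):
        state = initial_state(compile_forest(passive_single))
        with pytest.raises(ConfigurationError):
            advance_step(passive_single, state, 0.0)

    def test_zero_weight_event_is_null_perturbation(self, hh_single):
        forest = compile_forest(hh_single)
        s0 = initial_state(forest)
        a = advance_step(hh_single, s0.copy(), 25e-6, [])
        b = advance_step(hh_single, s0.copy(), 25e-6,
                         [SynapticEvent(0, 0, 0.0)])
        np.testing.assert_array_equal(a.V, b.V)
        np.testing.assert_array_equal(a.syn_rise, b.syn_rise)

    def test_time_tracks_step_count(self, passive_single):
        state = initial_state(compile_forest(passive_single))
        dt = 25e-6
        for _ in range(7):
            state = advance_step(passive_single, state, dt)
        assert state.step_count == 7
        assert state.time == pytest.approx(7 * dt, rel=1e-15)

    def test_gate_states_stay_in_unit_interval(self, hh_single):
        forest = compile_forest(hh_single)
        state = initial_state(forest)
        rng = np.random.default_rng(5)
        state.V = np.array([0.05])  # far from rest: fast gate swings
        for _ in range(500):
            state = advance_step(hh_single, state, 25e-6)
            assert np.all(state.gates >= 0.0) and np.all(state.gates <= 1.0)

    def test_charge_conserved_in_sealed_leakless_tree(self):
        # no leak (Rm huge), no channels: total capacitor charge is constant
        rng = np.random.default_rng(11)
        tree = CompartmentTree(
            parent=[-1, 0, 0, 1, 1],
            length=rng.uniform(30e-6, 80e-6, 5),
            diameter=rng.uniform(1e-6, 5e-6, 5),
            axial_resistivity=1.0,
            membrane_resistivity=1e12,  # effectively sealed membrane
            membrane_capacitance=0.01,
            leak_reversal=0.0,
        )
        tmpl = passive_template(tree)
        forest = compile_forest(tmpl)
        state = initial_state(forest)
        state.V = rng.uniform(-0.08, 0.02, 5)
        C = tree.capacitance()
        q0 = float(C @ state.V)
        for _ in range(200):
            state, _ = step_forest(forest, state, 25e-6)
            q = float(C @ state.V)
            assert q == pytest.approx(q0, rel=1e-12)

    def test_divergence_names_offending_compartment(self, passive_single):
        forest = compile_forest(passive_single)
        state = initial_state(forest)
        state.V = np.array([np.nan])
        with pytest.raises(NumericDivergenceError, match="compartment 0"):
            step_forest(forest, state, 25e-6)

    def test_trajectories_bitwise_deterministic(self, hh_single):
        forest = compile_forest(hh_single)

        def run():
            state = initial_state(forest)
            out = []
            for s in range(200):
                d = (np.array([0]), np.array([2e-7])) if s == 50 else None
                state, _ = step_forest(forest, state, 25e-6, d)
                out.append(state.V.copy())
            return np.concatenate(out)

        np.testing.assert_array_equal(run(), run())


class TestDetectSpikes:
    def test_no_crossing(self):
        assert detect_spikes([-0.07], [-0.07]) == []

    def test_upward_crossing_emits_gid(self):
        assert detect_spikes([-0.01], [0.01], threshold=0.0) == [0]

    def test_held_above_threshold_emits_once(self):
        trace = [-0.05, 0.01, 0.02, 0.015, -0.06]
        emitted = []
        for before, after in zip(trace[:-1], trace[1:]):
            emitted += detect_spikes([before], [after])
        assert emitted == [0]  # one emission, at the first crossing

    def test_gid_mapping(self):
        got = detect_spikes([-0.01, -0.07, -0.01], [0.02, -0.07, 0.01],
                            gids=np.array([10, 11, 12]))
        assert got == [10, 12]
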