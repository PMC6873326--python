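"""Unit tests for morphologies, channels and membrane currents."""

import math

import numpy as np
import pytest

from colsim.cells import (
    COMPARTMENT_RANGE,
    MAX_CHANNELS_PER_COMPARTMENT,
    CellTemplate,
    ChannelSpec,
    CompartmentTree,
    GateSpec,
    RateFunction,
    SQUID_K,
    SynapseSpec,
    gate_steady_state,
    membrane_current,
    synapse_peak_norm,
)
from colsim.errors import ConfigurationError, DegenerateGateError, OrderingError


class TestCompartmentTree:
    def test_rejects_non_hines_ordering(self):
        with pytest.raises(OrderingError):
            CompartmentTree([-1, 2, 1], 1e-5, 1e-6, 1.0, 1.0, 0.01, -0.065)

    def test_rejects_two_roots(self):
        with pytest.raises(OrderingError):
            CompartmentTree([-1, -1], 1e-5, 1e-6, 1.0, 1.0, 0.01, -0.065)

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(ConfigurationError):
            CompartmentTree([-1], 0.0, 1e-6, 1.0, 1.0, 0.01, -0.065)

    def test_surface_area_is_open_cylinder(self):
        tree = CompartmentTree([-1], 30e-6, 20e-6, 1.0, 1.0, 0.01, -0.065)
        assert tree.surface_area()[0] == pytest.approx(math.pi * 20e-6 * 30e-6)

    def test_axial_conductance_uses_child_geometry(self):
        tree = CompartmentTree(
            [-1, 0], [10e-6, 50e-6], [10e-6, 2e-6], 1.0, 1.0, 0.01, -0.065
        )
        expected = math.pi * (2e-6) ** 2 / (4 * 1.0 * 50e-6)
        assert tree.axial_conductance()[1] == pytest.approx(expected)
        assert tree.axial_conductance()[0] == 0.0


class TestGateSteadyState:
    def test_symmetric_rates_give_half_open(self):
        gate = GateSpec(1, RateFunction("const", 100.0), RateFunction("const", 100.0))
        x_inf, tau = gate_steady_state(gate, -0.065)
        assert x_inf == pytest.approx(0.5)
        assert tau == pytest.approx(0.005)

    def test_zero_alpha_closes_gate(self):
        gate = GateSpec(1, RateFunction("const", 0.0), RateFunction("const", 500.0))
        x_inf, tau = gate_steady_state(gate, -0.065)
        assert x_inf == 0.0
        assert tau == pytest.approx(0.002)

    def test_degenerate_gate_raises(self):
        gate = GateSpec(1, RateFunction("const", 0.0), RateFunction("const", 0.0))
        with pytest.raises(DegenerateGateError):
            gate_steady_state(gate, -0.065)

    def test_squid_potassium_rates_match_hand_evaluation(self):
        # independent evaluation of the classic delayed-rectifier rates at
        # V = -65 mV, in mV/ms units converted to SI:
        #   alpha_n = 0.01 (v+55) / (1 - exp(-(v+55)/10)) ms^-1, v = -65 mV
        #   beta_n  = 0.125 exp(-(v+65)/80) ms^-1
        v_mv = -65.0
        alpha_ms = 0.01 * (v_mv + 55.0) / (1.0 - math.exp(-(v_mv + 55.0) / 10.0))
        beta_ms = 0.125 * math.exp(-(v_mv + 65.0) / 80.0)
        alpha_si, beta_si = alpha_ms * 1e3, beta_ms * 1e3

        gate = SQUID_K.gates[0]
        assert gate.alpha(-0.065) == pytest.approx(alpha_si, rel=1e-12)
        assert gate.beta(-0.065) == pytest.approx(beta_si, rel=1e-12)
        x_inf, tau = gate_steady_state(gate, -0.065)
        assert x_inf == pytest.approx(alpha_si / (alpha_si + beta_si), rel=1e-12)
        assert tau == pytest.approx(1.0 / (alpha_si + beta_si), rel=1e-12)

    def test_linoid_singularity_is_removable(self):
        r = RateFunction("linoid", A=1e4, Vh=-0.055, k=0.010)
        assert r(-0.055) == pytest.approx(1e4 * 0.010, rel=1e-9)
        near = r(-0.055 + 1e-12)
        assert near == pytest.approx(1e4 * 0.010, rel=1e-6)

    @pytest.mark.parametrize("form,kwargs", [
        ("exp", dict(A=100.0, Vh=-0.05, k=-0.02)),
        ("sigmoid", dict(A=300.0, Vh=-0.04, k=0.01)),
        ("linoid", dict(A=1e4, Vh=-0.05, k=0.012)),
    ])
    def test_rates_nonnegative_on_physiological_range(self, form, kwargs):
        r = RateFunction(form, **kwargs)
        V = np.linspace(-0.12, 0.08, 401)
        assert np.all(r(V) >= 0.0)


def _one_channel_template(gmax, erev, n_gates=0):
    tree = CompartmentTree([-1], 30e-6, 20e-6, 1.0, 1.0, 0.01, -0.065)
    gates = tuple(
        GateSpec(1, RateFunction("const", 100.0), RateFunction("const", 100.0))
        for _ in range(n_gates)
    )
    chan = ChannelSpec("c", gmax, erev, gates)
    return CellTemplate("t", 2, True, tree, [[chan]], [[]], 0), tree, chan


class TestMembraneCurrent:
    def test_zero_at_leak_equilibrium(self, passive_single):
        I = membrane_current(passive_single, 0, -0.065, [], [(0.0, 0.0)])
        assert I == 0.0

    def test_single_channel_fully_open(self):
        tmpl, tree, chan = _one_channel_template(10.0, 0.0, n_gates=1)
        V = -0.02
        area = tree.surface_area()[0]
        expected = tree.leak_conductance()[0] * (V + 0.065) + 10.0 * area * (V - 0.0)
        assert membrane_current(tmpl, 0, V, [[1.0]], []) == pytest.approx(expected)

    def test_fourteen_channel_sum_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        tree = CompartmentTree([-1], 30e-6, 20e-6, 1.0, 1.0, 0.01, -0.065)
        chans, states = [], []
        for i in range(MAX_CHANNELS_PER_COMPARTMENT):
            ng = int(rng.integers(1, 4))
            gates = tuple(
                GateSpec(int(rng.integers(1, 5)),
                         RateFunction("const", 100.0), RateFunction("const", 50.0))
                for _ in range(ng)
            )
            chans.append(ChannelSpec(f"c{i}", float(rng.uniform(0.1, 100)),
                                     float(rng.uniform(-0.09, 0.05)), gates))
            states.append([float(rng.uniform(0, 1)) for _ in range(ng)])
        tmpl = CellTemplate("t", 2, True, tree, [chans], [[]], 0)
        V = -0.03
        area = tree.surface_area()[0]
        # independent term-by-term oracle
        expected = tree.leak_conductance()[0] * (V + 0.065)
        for ch, st in zip(chans, states):
            frac = 1.0
            for g, x in zip(ch.gates, st):
                frac *= x ** g.exponent
            expected += ch.max_conductance_density * area * frac * (V - ch.reversal)
        got = membrane_current(tmpl, 0, V, states, [])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linear_in_each_conductance(self):
        tmpl, tree, chan = _one_channel_template(10.0, 0.0, n_gates=1)
        tmpl2, _, _ = _one_channel_template(20.0, 0.0, n_gates=1)
        V = -0.02
        leak = membrane_current(tmpl, 0, V, [[0.0]], [])
        d1 = membrane_current(tmpl, 0, V, [[1.0]], []) - leak
        d2 = membrane_current(tmpl2, 0, V, [[1.0]], []) - leak
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_state_length_mismatch_raises(self, hh_single):
        with pytest.raises(ConfigurationError):
            membrane_current(hh_single, 0, -0.065, [[0.5]], [(0, 0)])

    def test_synaptic_term_uses_peak_normalised_conductance(self):
        tree = CompartmentTree([-1], 30e-6, 20e-6, 1.0, 1.0, 0.01, -0.065)
        spec = SynapseSpec(0.5e-3, 3e-3, 0.0)
        tmpl = CellTemplate("t", 2, True, tree, [[]], [[spec]], 0)
        V, xr, xd = -0.03, 0.2e-9, 0.8e-9
        expected = tree.leak_conductance()[0] * (V + 0.065) + \
            synapse_peak_norm(spec) * (xd - xr) * (V - 0.0)
        assert membrane_current(tmpl, 0, V, [], [(xr, xd)]) == pytest.approx(expected)


class TestFixtureTemplates:
    def test_twelve_types_six_exc_six_inh(self, fixture_set):
        assert len(fixture_set.templates) == 12
        exc = sum(t.excitatory for t in fixture_set.templates.values())
        assert exc == 6

    def test_compartment_and_channel_caps(self, fixture_set):
        lo, hi = COMPARTMENT_RANGE
        for t in fixture_set.templates.values():
            assert lo <= t.n_comp <= hi
            assert max(len(c) for c in t.channels) <= MAX_CHANNELS_PER_COMPARTMENT
            assert 2 <= t.layer <= 6

    def test_templates_reproducible_and_json_roundtrip(self, tmp_path, fixture_set):
        from colsim.fixtures import generate_fixture_set

        again = generate_fixture_set(1)
        for name, t in fixture_set.templates.items():
            assert again.templates[name].to_dict() == t.to_dict()
            p = tmp_path / f"{name}.json"
            t.to_json(p)
            assert CellTemplate.from_json(p).to_dict() == t.to_dict()

    def test_rate_functions_nonnegative_across_all_fixture_gates(self, fixture_set):
        V = np.linspace(-0.12, 0.08, 101)
        for t in fixture_set.templates.values():
            seen = set()
            for comp in t.channels:
                for ch in comp:
                    if id(ch) in seen:
                        continue
                    seen.add(id(ch))
                    for g in ch.gates:
                        assert np.all(g.alpha(V) >= 0)
                        assert np.all(g.beta(V) >= 0)
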