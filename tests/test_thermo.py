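"""Thermodynamic consistency: energies, rate derivation, detailed balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plecswitch.dynamics import Model, ModelConfig, build_rhs
from plecswitch.network import build_full_network
from plecswitch.thermo import (
    EnergyParams,
    EnergyTable,
    ParameterSet,
    boltzmann_distribution,
    check_detailed_balance,
    derive_rate_constants,
    is_consistent,
)


def table_for(network, **energy_overrides):
    return EnergyTable.from_params(network, EnergyParams(**energy_overrides))


class TestRateDerivation:
    def test_zero_energy_gives_symmetric_rates(self, two_state_network):
        et = EnergyTable({"A": 0.0, "B": 0.0}, {"ab": 0.0})
        ps = derive_rate_constants(two_state_network, et, {"conf": 1.0})
        assert ps.kf["ab"] == pytest.approx(1.0)
        assert ps.kr["ab"] == pytest.approx(1.0)

    def test_equilibrium_constant_from_energy_gap(self, two_state_network):
        et = EnergyTable({"A": 0.0, "B": -math.log(10)}, {"ab": -math.log(10)})
        ps = derive_rate_constants(two_state_network, et, {"conf": 1.0})
        assert ps.kf["ab"] / ps.kr["ab"] == pytest.approx(10.0)

    def test_missing_energy_names_the_reaction(self, two_state_network):
        et = EnergyTable({"A": 0.0, "B": 0.0}, {})
        with pytest.raises(KeyError, match="ab"):
            derive_rate_constants(two_state_network, et, {"conf": 1.0})

    @settings(max_examples=15, deadline=None)
    @given(
        d_conf=st.floats(-2, 2),
        d_tp=st.floats(-2, 2),
        d_td=st.floats(-2, 2),
        d_coop=st.floats(-1, 1),
    )
    def test_wegscheider_holds_for_arbitrary_energies(
        self, d_conf, d_tp, d_td, d_coop
    ):
        """Rates derived from any energy table satisfy detailed balance."""
        network = build_full_network()
        base = EnergyParams()
        et = EnergyTable.from_params(
            network,
            EnergyParams(
                e_conf_T=base.e_conf_T + d_conf,
                b_TP=base.b_TP + d_tp,
                b_TD=base.b_TD + d_td,
                e_coop=base.e_coop + d_coop,
            ),
        )
        ps = derive_rate_constants(network, et)
        res = check_detailed_balance(network, ps)
        assert max(res.values()) < 1e-9


class TestDetailedBalanceCheck:
    def test_triangle_perturbation_gives_log_residual_ln2(self, triangle_network):
        et = EnergyTable(
            {"A": 0.0, "B": 0.3, "C": -0.4},
            {"ab": 0.3, "bc": -0.7, "ca": 0.4},
        )
        ps = derive_rate_constants(triangle_network, et, {"conf": 1.0})
        assert is_consistent(triangle_network, ps)
        ps.kf["bc"] *= 2.0
        res = check_detailed_balance(triangle_network, ps)
        assert max(res.values()) == pytest.approx(math.log(2), abs=1e-12)

    def test_perturbation_touches_only_containing_cycles(self, baseline_model):
        net, ps = baseline_model.network, baseline_model.params.copy()
        from plecswitch.network import find_null_cycles

        cycles = find_null_cycles(net)
        target = next(iter(cycles[0]))
        ps.kf[target] *= 3.0
        res = check_detailed_balance(net, ps)
        for idx, cyc in enumerate(cycles):
            if target in cyc:
                expected = abs(cyc[target]) * math.log(3)
                assert res[idx] == pytest.approx(expected, abs=1e-9)
            else:
                assert res[idx] < 1e-9

    def test_zero_rate_on_cycle_is_an_error(self, triangle_network):
        et = EnergyTable(
            {"A": 0.0, "B": 0.0, "C": 0.0}, {"ab": 0.0, "bc": 0.0, "ca": 0.0}
        )
        ps = derive_rate_constants(triangle_network, et, {"conf": 1.0})
        ps.kr["ab"] = 0.0  # kf > 0, kr = 0: undefined log-ratio
        with pytest.raises(ValueError, match="zero rate"):
            check_detailed_balance(triangle_network, ps)

    def test_fully_disabled_reactions_drop_out_of_cycles(self, triangle_network):
        et = EnergyTable(
            {"A": 0.0, "B": 0.0, "C": 0.0}, {"ab": 0.0, "bc": 0.0, "ca": 0.0}
        )
        ps = derive_rate_constants(triangle_network, et, {"conf": 1.0})
        ps.kf["ab"] = 0.0
        ps.kr["ab"] = 0.0  # knocked out: the triangle is no longer a cycle
        assert check_detailed_balance(triangle_network, ps) == {}

    def test_acyclic_network_is_trivially_consistent(self, two_state_network):
        et = EnergyTable({"A": 0.0, "B": 1.0}, {"ab": 1.0})
        ps = derive_rate_constants(two_state_network, et, {"conf": 1.0})
        assert check_detailed_balance(two_state_network, ps) == {}
        assert is_consistent(two_state_network, ps)


class TestBoltzmann:
    def test_two_equal_states_split_evenly(self, two_state_network):
        et = EnergyTable({"A": 0.0, "B": 0.0}, {"ab": 0.0})
        eq = boltzmann_distribution(two_state_network, et, {"M": 1.0})
        assert eq["A"] == pytest.approx(0.5)
        assert eq["B"] == pytest.approx(0.5)

    def test_energy_gap_ln9_gives_ninety_ten(self, two_state_network):
        et = EnergyTable({"A": 0.0, "B": math.log(9)}, {"ab": math.log(9)})
        eq = boltzmann_distribution(two_state_network, et, {"M": 1.0})
        assert eq["A"] == pytest.approx(0.9, rel=1e-12)
        assert eq["B"] == pytest.approx(0.1, rel=1e-12)

    def test_totals_recovered_per_moiety(self, triangle_network):
        et = EnergyTable(
            {"A": 0.2, "B": -0.5, "C": 1.0}, {"ab": -0.7, "bc": 1.5, "ca": -0.8}
        )
        eq = boltzmann_distribution(triangle_network, et, {"M": 2.5})
        assert sum(eq.values()) == pytest.approx(2.5, rel=1e-10)

    def test_open_subnetwork_rejected(self, baseline_model):
        net = baseline_model.network  # contains synthesis/degradation
        with pytest.raises(ValueError, match="not closed"):
            boltzmann_distribution(
                net, baseline_model.energy_table,
                {t: 1.0 for t in net.moiety_tags()},
            )


class TestEquilibriumLimit:
    def test_closed_binding_subnetwork_reaches_boltzmann(self):
        """Long-time integration of the PleC--DivK binding/conformational
        sub-network reproduces the free-energy-minimizing distribution."""
        from scipy.integrate import solve_ivp
        from plecswitch.network import BuildOptions, build_full_network

        net = build_full_network(BuildOptions(include_syn_deg=False))
        sub = net.subnetwork(
            {"PleC", "DivK"},
            kinetic_classes={"binding", "conformational"},
        )
        model = Model(ModelConfig(variant="full"))
        ps = model.params
        f = build_rhs(sub, ps)
        x0 = np.zeros(sub.n_species)
        x0[sub.index("PleC_R0_00")] = 1.0
        x0[sub.index("DivK")] = 1.0
        x0[sub.index("DivKp")] = 0.5
        # constraints from the reference state: in a binding-only network
        # DivK and DivK~P are separately conserved
        expected = boltzmann_distribution(
            sub, model.energy_table, x0=x0
        )
        sol = solve_ivp(
            lambda t, x: f(x), (0.0, 2000.0), x0, method="LSODA",
            rtol=1e-11, atol=1e-13,
        )
        final = sol.y[:, -1]
        for i, sp in enumerate(sub.species):
            ref = expected[sp.id]
            if ref > 1e-12:
                assert final[i] == pytest.approx(ref, rel=1e-6), sp.id
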