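"""Mass-action dynamics: rhs assembly, integration, steady states."""

import numpy as np
import pytest

from plecswitch.dynamics import (
    Model,
    ModelConfig,
    SteadyStateError,
    build_rhs,
    find_steady_state,
    hill_activation,
    integrate,
)
from plecswitch.network import Reaction
from plecswitch.thermo import DEFAULT_NAMED, ParameterSet

from conftest import make_network, make_species


def brute_force_rhs(model, x):
    """Independent per-reaction summation used as the oracle for the
    vectorized right-hand side."""
    net, pm = model.network, model.params
    dx = np.zeros_like(x)
    for r in net.reactions:
        fwd = pm.kf[r.id]
        for sid, n in r.reactants.items():
            fwd *= x[net.index(sid)] ** n
        if r.kinetic_class == "hill-regulated":
            nm = pm.named
            L = x[net.index("DivL")]
            fwd *= nm["hill_vmax"] * L ** nm["hill_n"] / (
                nm["hill_K"] ** nm["hill_n"] + L ** nm["hill_n"]
            )
        rev = 0.0
        if r.reversible:
            rev = pm.kr[r.id]
            for sid, n in r.products.items():
                rev *= x[net.index(sid)] ** n
        rate = fwd - rev
        for sid, n in r.reactants.items():
            dx[net.index(sid)] -= n * rate
        for sid, n in r.products.items():
            dx[net.index(sid)] += n * rate
    return dx


class TestRhs:
    def test_first_order_decay_rates(self):
        sp = make_species("A", "B")
        net = make_network(
            sp, [Reaction("ab", {"A": 1}, {"B": 1}, False, "conformational", "k")]
        )
        ps = ParameterSet(kf={"ab": 2.0}, kr={"ab": 0.0}, named=dict(DEFAULT_NAMED))
        f = build_rhs(net, ps)
        dx = f(np.array([3.0, 0.0]))
        assert dx[0] == pytest.approx(-6.0)
        assert dx[1] == pytest.approx(6.0)

    @pytest.mark.parametrize("variant", ["full", "reduced"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_vectorized_rhs_matches_per_reaction_oracle(self, variant, seed):
        model = Model(ModelConfig(variant=variant))
        rng = np.random.default_rng(seed)
        for _ in range(20):
            x = rng.uniform(0.0, 2.0, model.network.n_species)
            f = model.f(x)
            scale = max(1.0, np.abs(f).max())
            assert np.abs(f - brute_force_rhs(model, x)).max() < 1e-12 * scale

    def test_jacobian_matches_finite_differences(self, baseline_model):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.05, 1.0, baseline_model.network.n_species)
        J = baseline_model.jac(x)
        f0 = baseline_model.f(x)
        eps = 1e-7
        for i in range(0, baseline_model.network.n_species, 5):
            xp = x.copy()
            xp[i] += eps
            col = (baseline_model.f(xp) - f0) / eps
            assert np.abs(J[:, i] - col).max() < 1e-4

    def test_closed_network_moiety_derivative_is_zero(self):
        model = Model(ModelConfig(variant="full"))
        rng = np.random.default_rng(7)
        x = rng.uniform(0.0, 1.0, model.network.n_species)
        dx = model.f(x)
        for tag in ("PleC", "DivJ", "DivL", "CckA", "CpdR"):
            w = model.network.moiety_vector(tag)
            assert abs(w @ dx) < 1e-12


class TestHill:
    def test_zero_input_gives_zero_rate(self, baseline_model):
        assert hill_activation(0.0, baseline_model.params) == 0.0

    def test_half_maximum_at_K(self, baseline_model):
        nm = baseline_model.params.named
        vmax = nm["hill_vmax"] * nm["k_cp_ck"] if "k_cp_ck" in nm else None
        at_K = hill_activation(nm["hill_K"], baseline_model.params)
        at_inf = hill_activation(1e6 * nm["hill_K"], baseline_model.params)
        assert at_K == pytest.approx(0.5 * at_inf, rel=1e-6)

    def test_monotone_saturation(self, baseline_model):
        L = np.linspace(0.0, 5.0, 50)
        vals = hill_activation(L, baseline_model.params)
        assert np.all(np.diff(vals) >= -1e-15)

    def test_invalid_hill_constants_rejected(self, baseline_model):
        with pytest.raises(ValueError):
            hill_activation(1.0, {"hill_K": -1.0, "hill_n": 2, "hill_vmax": 1})
        with pytest.raises(ValueError):
            hill_activation(1.0, {"hill_K": 0.1, "hill_n": 0.5, "hill_vmax": 1})


class TestIntegration:
    def test_reversible_isomerization_relaxes_to_half(self, baseline_model):
        # A<->B with kf = kr embedded as a 2-species model via build_rhs
        sp = make_species("A", "B")
        net = make_network(
            sp, [Reaction("ab", {"A": 1}, {"B": 1}, True, "conformational", "k")]
        )
        ps = ParameterSet(kf={"ab": 1.0}, kr={"ab": 1.0}, named=dict(DEFAULT_NAMED))
        from scipy.integrate import solve_ivp

        f = build_rhs(net, ps)
        sol = solve_ivp(lambda t, x: f(x), (0, 50.0), [1.0, 0.0], rtol=1e-10,
                        atol=1e-12)
        assert sol.y[:, -1] == pytest.approx([0.5, 0.5], rel=1e-6)

    def test_plec_total_constant_along_trajectory(self, fast_config):
        model = Model(fast_config.updated("DivJ_tot", 0.4))
        x0 = model.initial_state("swarmer")
        _, X = integrate(model, x0, 500.0, n_points=40)
        w = model.network.moiety_vector("PleC")
        totals = X @ w
        assert np.abs(totals - 1.0).max() < 1e-6

    def test_negative_initial_state_rejected(self, baseline_model):
        x0 = baseline_model.initial_state("swarmer")
        x0[0] = -0.1
        with pytest.raises(ValueError):
            integrate(baseline_model, x0, 1.0)


class TestSteadyState:
    def test_derivative_small_at_steady_state(self, fast_config):
        model = Model(fast_config)
        x, stable = find_steady_state(model, model.initial_state("swarmer"))
        assert np.abs(model.f(x)).max() < model.config.ss_tol
        assert stable

    def test_monostable_regime_multi_start_agreement(self, fast_config):
        """Well above the fold every start relaxes to the same state."""
        model = Model(fast_config.updated("DivJ_tot", 1.0))
        rng = np.random.default_rng(11)
        ref, _ = find_steady_state(model, model.initial_state("swarmer"))
        for policy in ("swarmer", "stalked"):
            x0 = model.project_totals(
                model.initial_state(policy)
                + rng.uniform(0, 0.05, model.network.n_species)
            )
            x, _ = find_steady_state(model, x0)
            assert model.observable("pleC_kinase_fraction", x) == pytest.approx(
                model.observable("pleC_kinase_fraction", ref), abs=1e-6
            )

    def test_bistable_regime_direction_dependent_states(self, fast_config):
        """Inside the hysteresis window a low-DivK~P history and a
        high-DivK~P history settle on distinct stable states."""
        # reach the low branch the way a cell would: DivJ rising gradually
        m0 = Model(fast_config.updated("DivJ_tot", 0.0))
        x, _ = find_steady_state(m0, m0.initial_state("swarmer"))
        for J in (0.1, 0.2, 0.225):
            model = Model(fast_config.updated("DivJ_tot", J))
            x, lo_stable = find_steady_state(model, x, polish_only=True)
        lo = x
        hi, hi_stable = find_steady_state(model, model.initial_state("stalked"))
        assert lo_stable and hi_stable
        gap = model.observable("pleC_kinase_fraction", hi) - model.observable(
            "pleC_kinase_fraction", lo
        )
        assert gap > 0.15

    def test_totals_track_divj_but_plec_stays_fixed(self, fast_config):
        """With turnover on, total DivK/CtrA/PleD at steady state depend on
        DivJ while total PleC remains at 1."""
        totals = {}
        for J, policy in ((0.0, "swarmer"), (1.0, "stalked")):
            model = Model(fast_config.updated("DivJ_tot", J))
            x, _ = find_steady_state(model, model.initial_state(policy))
            totals[J] = {
                tag: model.moiety_total(tag, x)
                for tag in ("PleC", "DivK", "CtrA", "PleD")
            }
        assert totals[0.0]["PleC"] == pytest.approx(1.0, rel=1e-6)
        assert totals[1.0]["PleC"] == pytest.approx(1.0, rel=1e-6)
        for tag in ("DivK", "CtrA", "PleD"):
            assert abs(totals[1.0][tag] - totals[0.0][tag]) > 0.05 * max(
                totals[0.0][tag], 0.1
            ), tag
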