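"""Mutant transformations and their thermodynamic consistency."""

import math

import pytest

from plecswitch.dynamics import Model
from plecswitch.genotypes import (
    MUTANTS,
    apply_mutant,
    steady_state_fractions,
)
from plecswitch.thermo import check_detailed_balance


class TestApplyMutant:
    def test_wild_type_is_identity(self, fast_config):
        assert apply_mutant(fast_config, "wild_type") == fast_config

    def test_divj_deletion_zeroes_the_total(self, fast_config):
        cfg = apply_mutant(fast_config, "delta_divJ")
        assert cfg.get_param("DivJ_tot") == 0.0

    def test_unphosphorylatable_divk_kills_transfer_rates(self, fast_config):
        cfg = apply_mutant(fast_config, "divK_D53N")
        model = Model(cfg)
        for r in model.network.reactions:
            if r.scale_group in ("transfer_dk", "k_trans_j"):
                assert model.params.kf[r.id] == 0.0
                assert model.params.kr[r.id] == 0.0

    def test_autokinase_dead_plec_keeps_conformational_switching(
        self, fast_config
    ):
        cfg = apply_mutant(fast_config, "pleC_F778L")
        model = Model(cfg)
        auto = [r for r in model.network.reactions
                if r.kinetic_class == "autophosphorylation"
                and "PleC" in r.id or r.id.startswith("auto:PleC")]
        conf = [r for r in model.network.reactions
                if r.kinetic_class == "conformational" and "PleC" in r.id]
        assert all(model.params.kf[r.id] == 0.0
                   for r in model.network.reactions
                   if r.id.startswith("auto:PleC"))
        assert all(model.params.kf[r.id] > 0.0 for r in conf)

    def test_allosteric_null_equalizes_binding_energies(self, fast_config):
        cfg = apply_mutant(fast_config, "divK_D90G")
        assert cfg.energy.b_TK == cfg.energy.b_RK
        assert cfg.energy.b_TP == cfg.energy.b_RP
        # DivL binding weakened by the configured factor
        assert cfg.energy.b_LP == pytest.approx(
            fast_config.energy.b_LP + math.log(100.0)
        )

    def test_divk_x_keeps_wild_type_divl_binding(self, fast_config):
        cfg = apply_mutant(fast_config, "divK_X")
        assert cfg.energy.b_LP == fast_config.energy.b_LP
        assert cfg.energy.b_TP == cfg.energy.b_RP

    def test_combinations_compose(self, fast_config):
        cfg = apply_mutant(fast_config, "pleC_Tn5_divK_D90G")
        assert cfg.get_param("PleC_tot") == 0.0
        assert cfg.energy.b_TP == cfg.energy.b_RP

    def test_unknown_mutant_rejected(self, fast_config):
        with pytest.raises(KeyError, match="unknown mutant"):
            apply_mutant(fast_config, "divK_imaginary")

    @pytest.mark.parametrize("name", sorted(MUTANTS))
    def test_every_mutant_preserves_detailed_balance(self, fast_config, name):
        cfg = apply_mutant(fast_config, name)
        model = Model(cfg)
        res = check_detailed_balance(model.network, model.params)
        assert max(res.values(), default=0.0) < 1e-9


class TestFractions:
    def test_fractions_bounded_for_every_genotype(self, fast_config):
        for name in ("wild_type", "pleC_Tn5", "delta_divJ"):
            fr = steady_state_fractions(fast_config, name, 0.8)
            for key, value in fr.items():
                assert -1e-9 <= value <= 1.0 + 1e-9, (name, key)

    def test_plec_null_has_no_kinase_signal(self, fast_config):
        fr = steady_state_fractions(fast_config, "pleC_Tn5", 1.2)
        assert fr["pleC_kinase_fraction"] == 0.0
        assert fr["pleDp_fraction"] < 0.01
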