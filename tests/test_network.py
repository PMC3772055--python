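"""Structural tests of the reaction-network builders."""

import numpy as np
import pytest

from plecswitch.network import (
    PLEC_CORE_TAGS,
    SUBNETWORK_TAGS,
    BuildOptions,
    Reaction,
    build_full_network,
    build_reduced_network,
    find_null_cycles,
    stoichiometric_matrix,
)


class TestSpeciesEnumeration:
    def test_full_model_state_count(self, full_network):
        assert full_network.n_species == 52

    def test_signaling_subnetwork_count(self, full_network):
        sub = full_network.subnetwork(SUBNETWORK_TAGS)
        assert sub.n_species == 38

    def test_core_before_and_after_reduction(self, full_network, reduced_network):
        assert full_network.subnetwork(PLEC_CORE_TAGS).n_species == 28
        assert reduced_network.subnetwork(PLEC_CORE_TAGS).n_species == 20

    def test_reduced_lumps_only_singly_occupied_dimers(
        self, full_network, reduced_network
    ):
        lost = set(full_network.species_ids) - set(reduced_network.species_ids)
        assert len(lost) == 8
        for sid in lost:
            sp = full_network.species_by_id(sid)
            n_dk = sum(1 for x in sp.sites if x in ("K", "P"))
            assert n_dk == 1 and "0" in sp.sites

    def test_unique_ids_and_moiety_tags(self, full_network):
        ids = full_network.species_ids
        assert len(set(ids)) == len(ids)
        for sp in full_network.species:
            assert sp.moieties, sp.id

    def test_concerted_transition_no_hybrid_conformations(self, full_network):
        # every PleC dimer state carries a single conformation label
        for sp in full_network.species:
            if "PleC" in sp.moieties:
                assert sp.conformation in ("R", "T")
                assert sp.sites is not None and len(sp.sites) == 2

    def test_observables_shared_between_variants(
        self, full_network, reduced_network
    ):
        full_obs = set(full_network.observable_weights())
        red_obs = set(reduced_network.observable_weights())
        for name in (
            "pleC_kinase_fraction",
            "divKp_fraction",
            "pleDp_fraction",
            "ctrAp_fraction",
        ):
            assert name in full_obs and name in red_obs


class TestBuilderContracts:
    @pytest.mark.parametrize(
        "options",
        [
            BuildOptions(n_sites=3),
            BuildOptions(allow_hybrid=True),
            BuildOptions(ligands=("DivK",)),
        ],
    )
    def test_mwc_assumptions_enforced(self, options):
        with pytest.raises(ValueError):
            build_full_network(options)

    def test_single_hill_regulated_reaction(self, full_network, reduced_network):
        for net in (full_network, reduced_network):
            hills = [r for r in net.reactions if r.kinetic_class == "hill-regulated"]
            assert len(hills) == 1

    def test_moiety_balance_outside_turnover(self, full_network):
        full_network.check_moiety_balance()  # raises on imbalance

    def test_closed_system_conserves_every_moiety(self, closed_network):
        S = stoichiometric_matrix(closed_network)
        for tag in closed_network.moiety_tags():
            w = closed_network.moiety_vector(tag)
            assert np.allclose(w @ S, 0.0, atol=1e-12), tag

    def test_turnover_breaks_only_synthesized_moieties(self, full_network):
        conserved = set(full_network.conserved_moieties())
        assert conserved == {"PleC", "DivJ", "DivL", "CckA", "CpdR"}


class TestStoichiometry:
    def test_single_reaction_column(self, two_state_network):
        S = stoichiometric_matrix(two_state_network)
        assert S.shape == (2, 1)
        assert list(S[:, 0]) == [-1.0, 1.0]

    def test_plec_moiety_in_left_null_space(self, closed_network):
        S = stoichiometric_matrix(closed_network)
        w = closed_network.moiety_vector("PleC")
        assert np.allclose(w @ S, 0.0, atol=1e-12)

    def test_rank_nullity_matches_conservation_count(self, closed_network):
        S = stoichiometric_matrix(closed_network)
        rank = np.linalg.matrix_rank(S)
        n_laws = S.shape[0] - rank
        # independent conservation laws must at least cover the moieties
        assert n_laws >= len(closed_network.conserved_moieties())
        assert rank + n_laws == closed_network.n_species


class TestNullCycles:
    def test_single_reversible_reaction_has_no_cycle(self, two_state_network):
        assert find_null_cycles(two_state_network) == []

    def test_triangle_has_one_independent_cycle(self, triangle_network):
        cycles = find_null_cycles(triangle_network)
        assert len(cycles) == 1
        assert set(cycles[0]) == {"ab", "bc", "ca"}

    def test_cycle_vectors_annihilate_stoichiometry(self, full_network):
        cycles = find_null_cycles(full_network)
        assert cycles, "full network must contain null cycles"
        S = stoichiometric_matrix(full_network)
        rid_to_col = {r.id: j for j, r in enumerate(full_network.reactions)}
        for cyc in cycles:
            v = np.zeros(full_network.n_reactions)
            for rid, coeff in cyc.items():
                v[rid_to_col[rid]] = coeff
            assert np.allclose(S @ v, 0.0, atol=1e-12)

    def test_cycle_count_equals_reversible_nullity(self, full_network):
        rev_cols = [
            j for j, r in enumerate(full_network.reactions) if r.reversible
        ]
        S = stoichiometric_matrix(full_network)[:, rev_cols]
        expected = S.shape[1] - np.linalg.matrix_rank(S)
        assert len(find_null_cycles(full_network)) == expected

    def test_irreversible_reactions_excluded(self, full_network):
        cycles = find_null_cycles(full_network)
        irr = {r.id for r in full_network.reactions if not r.reversible}
        for cyc in cycles:
            assert not set(cyc) & irr
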