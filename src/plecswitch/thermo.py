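"""Free-energy assignment, thermodynamically consistent rates, detailed balance.

Every species is assigned a baseline free energy (RT = 1 throughout), built
additively from structural components: a conformational penalty for the
kinase (T) fold, a per-phospho-group energy, conformation-dependent
site-binding energies, and a configurational-entropy term ``-ln g`` for the
degeneracy of mixed site occupancies.  Reversible reactions then receive

    kf = scale * multiplicity,      kr = kf * exp(dG0),

with ``dG0 = sum(E_products) - sum(E_reactants)``, so ``kf/kr = K_eq =
exp(-dG0)`` and detailed balance holds around every null cycle by
construction (Wegscheider's condition).  Irreversible reactions (ATP-driven
autophosphorylation, hydrolysis with phosphate release, synthesis,
degradation, the phenomenological Hill step) carry their scale directly and
are excluded from cycle analysis.

The substrate preference at the heart of the switch -- DivK~P stabilizes
the kinase conformation more than DivK does -- lives purely in the binding
energies ``b_TP`` versus ``b_TK`` (relative to their phosphatase-form
counterparts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .network import ReactionNetwork, Species, find_null_cycles

__all__ = [
    "EnergyParams",
    "EnergyTable",
    "ParameterSet",
    "DEFAULT_SCALES",
    "species_energy",
    "build_energy_table",
    "derive_rate_constants",
    "check_detailed_balance",
    "is_consistent",
    "boltzmann_distribution",
]

#: residual above which a parameter set is declared thermodynamically
#: inconsistent (log-space; double precision over a few dozen factors)
DETAILED_BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class EnergyParams:
    """Baseline free energies (units of RT) of the model's building blocks.

    ``b_XY`` is the free-energy change for ligand Y binding to one site of
    conformation X; the DivK~P preference gap for the kinase form is
    ``(b_RP - b_TP) - (b_RK - b_TK)``.
    """

    e_conf_T: float = 5.3  # T (kinase) fold penalty of the empty dimer
    e_hisP: float = 5.0  # phospho-His group energy
    a_dkp: float = 2.0  # phospho-Asp on DivK
    a_pdp: float = 2.0  # phospho-Asp on PleD
    b_RK: float = 1.8  # DivK binding to a phosphatase-form site (weak)
    b_RP: float = -1.5  # DivK~P binding to a phosphatase-form site
    b_TK: float = -0.8  # DivK binding to a kinase-form site
    b_TP: float = -5.7  # DivK~P binding to a kinase-form site
    b_TD: float = -5.5  # PleD docking at a phospho-His kinase site
    e_coop: float = 1.5  # penalty on singly-DivK-occupied dimers (binding
    #   cooperativity; large values concentrate the population on the empty
    #   and doubly-occupied states that the reduced variant keeps)
    e_dim_pd: float = -2.0  # PleD~P dimerization
    b_LP: float = -3.5  # DivK~P binding to DivL
    b_JK: float = -3.0  # DivK binding to DivJ
    b_ck: float = -2.0  # CckA--substrate encounter complexes

    def preference_gap(self) -> float:
        """Extra kinase-fold stabilization by DivK~P relative to DivK."""
        return (self.b_RP - self.b_TP) - (self.b_RK - self.b_TK)

    def with_preference_gap(self, gap: float) -> "EnergyParams":
        """Shift ``b_TP`` so the DivK~P preference gap equals ``gap``."""
        return replace(self, b_TP=self.b_RP - gap - (self.b_RK - self.b_TK))


#: default kinetic scales (forward-rate magnitudes) per reaction scale group.
#: Binding and conformational steps are fast relative to catalysis, which
#: also keeps the reduced (rapid-binding) variant close to the full model.
DEFAULT_SCALES = {
    "bind_dk": 100.0,
    "bind_pd": 100.0,
    "exch_pd": 0.05,
    "conf": 100.0,
    "transfer_dk": 15.0,
    "transfer_pd": 5.0,
    "k_auto": 0.65,
    "k_hyd": 20.0,
    "k_hyd_his": 0.55,
    "k_adph_dk": 0.04,
    "k_adph_pd": 0.5,
    "bind_j": 100.0,
    "k_trans_j": 2.5,
    "dim_pd": 20.0,
    "bind_dl": 100.0,
    "k_cp_ck": 2.0,
    "k_ck_cp": 0.5,
    "k_ck_ck1": 2.0,
    "k_ck_xf1": 10.0,
    "k_ck_xf2": 10.0,
    "bind_ck": 100.0,
    "k_cp_ch1": 5.0,
    "k_cp_ch2": 5.0,
    "k_syn_dk": 0.015,
    "k_deg_dk": 0.01,
    "k_syn_pd": 0.01,
    "k_deg_pd": 0.02,
    "k_syn_ct": 0.02,
    "k_deg_ct": 0.02,
    "k_deg_ct_cp": 1.0,
}


def species_energy(sp: Species, ep: EnergyParams) -> float:
    """Baseline free energy of a species from its structural composition."""
    if sp.sites is not None:  # PleC dimer state
        e = 0.0
        if sp.conformation == "T":
            e += ep.e_conf_T
        e += sp.his_p * ep.e_hisP
        for lig in sp.sites:
            if lig == "K":
                e += ep.b_TK if sp.conformation == "T" else ep.b_RK
            elif lig == "P":
                e += (ep.b_TP if sp.conformation == "T" else ep.b_RP) + ep.a_dkp
            elif lig == "D":
                e += ep.b_TD
        n_dk = sum(1 for l in sp.sites if l in ("K", "P"))
        if n_dk == 1 and "0" in sp.sites:
            e += ep.e_coop
        return e - math.log(sp.degeneracy)
    table = {
        "DivK": 0.0,
        "DivKp": ep.a_dkp,
        "DivJ": 0.0,
        "DivJ_DivK": ep.b_JK,
        "PleD": 0.0,
        "PleDp": ep.a_pdp,
        "PleDp2": 2 * ep.a_pdp + ep.e_dim_pd,
        "DivL": 0.0,
        "DivL_DivKp": ep.a_dkp + ep.b_LP - math.log(2),
        "DivL_DivKp2": 2 * (ep.a_dkp + ep.b_LP),
        "CckA_P": 0.0,
        "CckA_K": 0.0,
        "CckA_Kp": 0.0,
        "CckA_Kp_CtrA": ep.b_ck,
        "CckA_Kp_CpdR": ep.b_ck,
        "CckA_P_CtrAp": ep.b_ck,
        "CckA_P_CpdRp": ep.b_ck,
        "CtrA": 0.0,
        "CtrAp": 0.0,
        "CpdR": 0.0,
        "CpdRp": 0.0,
    }
    return table[sp.id]


@dataclass
class EnergyTable:
    """Per-species baseline energies and per-reaction standard dG0 (RT)."""

    species_energy: dict  # species id -> energy
    reaction_dG0: dict  # reaction id -> dG0 (reversible reactions only)

    @classmethod
    def from_params(
        cls, network: ReactionNetwork, params: EnergyParams
    ) -> "EnergyTable":
        energies = {s.id: species_energy(s, params) for s in network.species}
        dG0 = {}
        for r in network.reactions:
            if not r.reversible:
                continue
            dG0[r.id] = sum(
                n * energies[sid] for sid, n in r.products.items()
            ) - sum(n * energies[sid] for sid, n in r.reactants.items())
        return cls(energies, dG0)


def build_energy_table(
    network: ReactionNetwork, params: EnergyParams | None = None
) -> EnergyTable:
    return EnergyTable.from_params(network, params or EnergyParams())


@dataclass
class ParameterSet:
    """Forward/reverse rate constants plus named model constants.

    ``kf[rid]``/``kr[rid]`` are per-reaction; ``named`` carries totals
    (``DivJ_tot``, ``PleC_tot``, ...) and Hill constants.  For reversible
    reactions ``kf/kr = exp(-dG0)`` by construction.
    """

    kf: dict
    kr: dict
    named: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.named[key]

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.kf), dict(self.kr), dict(self.named))

    def to_dict(self) -> dict:
        return {"kf": dict(self.kf), "kr": dict(self.kr), "named": dict(self.named)}

    def xpp_par_lines(self) -> list:
        """Parameter assignments in the XPPAUT ``par`` format."""
        lines = [
            f"par {name}={value:.12g}" for name, value in sorted(self.named.items())
        ]
        for rid in sorted(self.kf):
            lines.append(f"par kf_{_sanitize(rid)}={self.kf[rid]:.12g}")
            if self.kr.get(rid, 0.0) != 0.0:
                lines.append(f"par kr_{_sanitize(rid)}={self.kr[rid]:.12g}")
        return lines


def _sanitize(rid: str) -> str:
    return (
        rid.replace(":", "_").replace("+", "_").replace("-", "_").replace(".", "_")
    )


DEFAULT_NAMED = {
    "DivJ_tot": 0.0,
    "PleC_tot": 1.0,
    "DivL_tot": 0.5,
    "CckA_tot": 0.5,
    "CpdR_tot": 0.5,
    "hill_K": 0.1,
    "hill_n": 2.0,
    "hill_vmax": 1.0,
}


def derive_rate_constants(
    network: ReactionNetwork,
    energies: EnergyTable,
    kinetic_scales: dict | None = None,
    named: dict | None = None,
) -> ParameterSet:
    """Thermodynamically consistent rates from energies and kinetic scales.

    ``kinetic_scales`` maps either a reaction id or its scale group to the
    forward-rate magnitude; reversible reactions get ``kr = kf*exp(dG0)``,
    irreversible ones take their scale directly.
    """
    scales = dict(DEFAULT_SCALES)
    if kinetic_scales:
        scales.update(kinetic_scales)
    kf, kr = {}, {}
    for r in network.reactions:
        scale = scales.get(r.id, scales.get(r.scale_group))
        if scale is None:
            raise KeyError(f"no kinetic scale for reaction {r.id!r} "
                           f"(group {r.scale_group!r})")
        if scale < 0:
            raise ValueError(f"negative kinetic scale for {r.id!r}")
        f = scale * r.multiplicity
        kf[r.id] = f
        if r.reversible:
            if r.id not in energies.reaction_dG0:
                raise KeyError(
                    f"reversible reaction {r.id!r} has no free-energy assignment"
                )
            kr[r.id] = f * math.exp(energies.reaction_dG0[r.id])
        else:
            kr[r.id] = 0.0
    nm = dict(DEFAULT_NAMED)
    if named:
        nm.update(named)
    return ParameterSet(kf=kf, kr=kr, named=nm)


def check_detailed_balance(network: ReactionNetwork, params: ParameterSet) -> dict:
    """Log-residual of the Wegscheider condition for every null cycle.

    Cycles are recomputed on the *active* reversible sub-network: reactions
    with kf = kr = 0 (e.g. knocked out by a mutant) are treated as absent.
    A cycle reaction with exactly one of kf, kr zero has an undefined
    log-ratio and raises.
    """
    active = lambda r: not (
        params.kf.get(r.id, 0.0) == 0.0 and params.kr.get(r.id, 0.0) == 0.0
    )
    cycles = find_null_cycles(network, reaction_filter=active)
    residuals = {}
    for idx, cyc in enumerate(cycles):
        total = 0.0
        for rid, coeff in cyc.items():
            f, r = params.kf[rid], params.kr[rid]
            if f <= 0.0 or r <= 0.0:
                raise ValueError(
                    f"zero rate constant on cycle reaction {rid!r}: "
                    "detailed-balance residual undefined"
                )
            total += coeff * (math.log(f) - math.log(r))
        residuals[idx] = abs(total)
    return residuals


def is_consistent(network: ReactionNetwork, params: ParameterSet,
                  tol: float = DETAILED_BALANCE_TOL) -> bool:
    res = check_detailed_balance(network, params)
    return max(res.values(), default=0.0) < tol


# ---------------------------------------------------------------------------
# equilibrium oracle


def boltzmann_distribution(
    network: ReactionNetwork,
    energies: EnergyTable,
    totals: dict | None = None,
    species_subset=None,
    x0=None,
) -> dict:
    """Equilibrium concentrations of a closed sub-network.

    Minimizes the ideal-solution free energy subject to the network's
    conserved quantities; the stationary condition is ``x_i = exp(-E_i +
    sum_m lambda_m w_mi)`` with one chemical potential ``lambda_m`` per
    conservation law, fixed by the totals.  For a set of unimolecular
    interconversions this reduces to fractions proportional to
    ``exp(-E_i)`` normalized within the moiety.

    Constraints come either from ``totals`` (per-moiety, sufficient when
    the moiety vectors span the conservation space) or from a reference
    state ``x0``, from which every conserved quantity -- including ones the
    moiety tags do not distinguish, such as separately conserved phospho
    forms in a binding-only network -- is evaluated exactly.

    Raises if the sub-network is not closed (contains irreversible, driven
    or synthesis/degradation reactions).
    """
    from .network import stoichiometric_matrix

    sub_ids = set(species_subset) if species_subset is not None else set(
        network.species_ids
    )
    for r in network.reactions:
        involved = set(r.reactants) | set(r.products)
        if involved & sub_ids and not r.reversible:
            raise ValueError(
                f"sub-network is not closed: irreversible reaction {r.id!r} "
                "touches it"
            )
    sps = [s for s in network.species if s.id in sub_ids]
    E = np.array([energies.species_energy[s.id] for s in sps])
    if x0 is not None:
        import sympy

        sub = network.subnetwork(set().union(*(s.moiety_tags for s in sps)))
        order = {sid: k for k, sid in enumerate(sub.species_ids)}
        S = stoichiometric_matrix(sub)
        basis = sympy.Matrix(S.astype(int)).T.nullspace()
        W = np.array(
            [[float(v[order[s.id]]) for s in sps] for v in basis]
        )
        x0 = np.asarray(x0, dtype=float)
        b = W @ x0
    else:
        tags = [t for t in totals]
        for s in sps:
            if not set(s.moieties) <= set(tags):
                raise ValueError(
                    f"species {s.id} carries a moiety without a specified total"
                )
        W = np.array(
            [[s.moieties.get(t, 0) for s in sps] for t in tags], dtype=float
        )
        b = np.array([float(totals[t]) for t in tags])
        if np.any(b <= 0):
            raise ValueError("moiety totals must be positive")

    lam = np.zeros(W.shape[0])

    def conc(l):
        return np.exp(-E + W.T @ l)

    for _ in range(200):
        x = conc(lam)
        scale_b = np.maximum(np.abs(b), 1.0)
        g = W @ x - b
        if np.max(np.abs(g) / scale_b) < 1e-14:
            break
        J = (W * x) @ W.T
        try:
            step = np.linalg.solve(J, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, g, rcond=None)[0]
        # damped Newton on the dual (convex) problem
        t = 1.0
        while t > 1e-6:
            x_new = conc(lam - t * step)
            g_new = W @ x_new - b
            if np.linalg.norm(g_new) < np.linalg.norm(g):
                break
            t /= 2
        lam = lam - t * step
    x = conc(lam)
    if np.max(np.abs(W @ x - b) / np.maximum(np.abs(b), 1.0)) > 1e-10:
        raise RuntimeError("equilibrium solve did not converge")
    return {s.id: x[i] for i, s in enumerate(sps)}
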