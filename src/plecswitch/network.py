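"""Reaction-network construction for the PleC bistable switch model.

The model describes the *Caulobacter crescentus* swarmer-to-stalked decision
circuit: the bifunctional histidine kinase PleC (a homodimer that flips
concertedly, MWC-style, between a phosphatase conformation R and a kinase
conformation T under the influence of its own response regulator DivK), the
starter kinase DivJ, the diguanylate cyclase PleD, and the downstream
DivL--CckA--CtrA/CpdR phosphorelay.

Species enumeration
-------------------
The PleC dimer is described by three structural coordinates:

* conformation ``R`` (phosphatase) or ``T`` (kinase);
* the occupancy multiset of its two indistinguishable ligand sites, each
  ``0`` (empty), ``K`` (DivK), ``P`` (DivK~P) or ``D`` (PleD);
* the number ``h`` of phosphorylated His residues (0--2).  Phospho-His is
  carried only by the kinase conformation (autophosphorylation is a kinase
  activity, and a phosphorylated His is taken to lock the kinase fold), and
  each bound PleD molecule docks onto one phospho-His, so ``#D <= h``.

This yields 6 R states, 6+9+10 T states (h = 0, 1, 2), of which 24 carry no
PleD and 7 carry PleD.  With DivK, DivK~P, DivJ and the DivJ.DivK complex the
PleC--DivK core has 28 state variables; adding PleD, PleD~P, the active
PleD~P dimer and the 7 PleC.PleD complexes gives the 38-species
PleC--DivJ--DivK--PleD sub-network; the 14 downstream species (DivL and its
one- and two-ligand DivK~P complexes, CckA in phosphatase/kinase/kinase~P
forms, four CckA-substrate complexes, CtrA, CtrA~P, CpdR, CpdR~P) complete
the 52-variable full model.

The reduced variant drops the 8 singly-DivK-occupied dimer states (rapid
ligand-binding limit; double occupancy is reached through direct cooperative
binding steps), replacing the 28 core equations by 20.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "BuildOptions",
    "build_full_network",
    "build_reduced_network",
    "stoichiometric_matrix",
    "find_null_cycles",
]

# canonical ligand ordering inside a dimer site multiset
_LIG_ORDER = {"0": 0, "K": 1, "P": 2, "D": 3}
_MOIETY_OF_LIG = {"K": "DivK", "P": "DivK", "D": "PleD"}

#: kinetic classes a reaction may carry
KINETIC_CLASSES = frozenset(
    {
        "binding",
        "conformational",
        "autophosphorylation",
        "phosphotransfer",
        "hydrolysis",
        "synthesis",
        "degradation",
        "hill-regulated",
    }
)

PLEC_CORE_TAGS = frozenset({"PleC", "DivK", "DivJ"})
SUBNETWORK_TAGS = frozenset({"PleC", "DivK", "DivJ", "PleD"})


@dataclass(frozen=True)
class Species:
    """A chemical species (free protein, enzyme state or complex)."""

    id: str
    role: str  # "free-protein" | "enzyme-state" | "complex"
    moieties: dict = field(default_factory=dict, hash=False)  # tag -> count
    phospho_marks: frozenset = frozenset()
    # PleC dimer structural coordinates (None for non-PleC species)
    conformation: str | None = None  # "R" (phosphatase) or "T" (kinase)
    sites: tuple | None = None  # canonical 2-tuple of site ligands
    his_p: int | None = None  # number of phospho-His residues

    @property
    def moiety_tags(self) -> frozenset:
        return frozenset(self.moieties)

    @property
    def degeneracy(self) -> int:
        """Configurational degeneracy of the state (distinct site labelings)."""
        if self.sites is not None and self.sites[0] != self.sites[1]:
            return 2
        if self.id == "DivL_DivKp":  # DivL dimer, one of two sites occupied
            return 2
        return 1

    def __repr__(self) -> str:  # keep test output readable
        return f"Species({self.id})"


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: dict = field(hash=False)  # species id -> stoichiometry
    products: dict = field(hash=False)
    reversible: bool = True
    kinetic_class: str = "binding"
    scale_group: str = "misc"
    multiplicity: int = 1  # forward statistical factor

    def __post_init__(self):
        if self.kinetic_class not in KINETIC_CLASSES:
            raise ValueError(f"unknown kinetic class {self.kinetic_class!r}")

    def __repr__(self) -> str:
        arrow = "<->" if self.reversible else "->"
        lhs = " + ".join(
            (f"{n} " if n > 1 else "") + s for s, n in self.reactants.items()
        ) or "0"
        rhs = " + ".join(
            (f"{n} " if n > 1 else "") + s for s, n in self.products.items()
        ) or "0"
        return f"Reaction({self.id}: {lhs} {arrow} {rhs})"


@dataclass(frozen=True)
class BuildOptions:
    """Structural choices for the network builder.

    ``n_sites`` and ``allow_hybrid`` exist to make the MWC assumptions
    explicit: the concerted model admits exactly two indistinguishable sites
    and no mixed-conformation dimers, and the builder refuses anything else.
    ``pled_requires_hisP`` encodes the assumption that PleD docks onto a
    phosphorylated His of the kinase conformation (so a kinase dimer without
    phospho-His cannot bind PleD).
    """

    n_sites: int = 2
    allow_hybrid: bool = False
    include_syn_deg: bool = True
    pled_requires_hisP: bool = True
    degrade_complexes: bool = False
    ligands: tuple = ("DivK", "DivKp")

    def validate(self):
        if self.n_sites != 2:
            raise ValueError(
                "the concerted (MWC) homodimer model supports exactly 2 sites"
            )
        if self.allow_hybrid:
            raise ValueError(
                "hybrid-conformation dimers contradict the concerted "
                "(all-subunits-together) transition assumption"
            )
        if tuple(self.ligands) != ("DivK", "DivKp"):
            raise ValueError("ligands must be (DivK, DivKp)")
        if not self.pled_requires_hisP:
            raise ValueError(
                "pled_requires_hisP=False would change the species count; "
                "only the documented 38/52-species enumeration is supported"
            )


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    variant: str  # "full" | "reduced"
    options: BuildOptions = field(default_factory=BuildOptions)

    def __post_init__(self):
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")
        self._index = {sid: i for i, sid in enumerate(ids)}
        self._cycles = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def species_ids(self) -> list:
        return [s.id for s in self.species]

    def index(self, species_id: str) -> int:
        return self._index[species_id]

    def species_by_id(self, species_id: str) -> Species:
        return self.species[self._index[species_id]]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def moiety_vector(self, tag: str) -> np.ndarray:
        """Copy-number weight of conserved moiety ``tag`` in each species."""
        return np.array([float(s.moieties.get(tag, 0)) for s in self.species])

    def moiety_tags(self) -> list:
        tags = []
        for s in self.species:
            for t in s.moieties:
                if t not in tags:
                    tags.append(t)
        return tags

    def conserved_moieties(self) -> list:
        """Tags whose weighted totals are invariant under every reaction."""
        S = stoichiometric_matrix(self)
        out = []
        for tag in self.moiety_tags():
            w = self.moiety_vector(tag)
            if np.all(np.abs(w @ S) < 1e-12):
                out.append(tag)
        return out

    def subnetwork(
        self,
        tags,
        kinetic_classes=None,
        include_syn_deg: bool = True,
    ) -> "ReactionNetwork":
        """Extract the sub-network of species whose moieties all lie in ``tags``.

        Reactions survive when every participating species survives and,
        optionally, when their kinetic class is in ``kinetic_classes``.
        """
        tags = set(tags)
        keep = [s for s in self.species if set(s.moieties) <= tags and s.moieties]
        keep_ids = {s.id for s in keep}
        rxns = []
        for r in self.reactions:
            if not set(r.reactants) | set(r.products) <= keep_ids:
                continue
            if kinetic_classes is not None and r.kinetic_class not in kinetic_classes:
                continue
            if not include_syn_deg and r.kinetic_class in ("synthesis", "degradation"):
                continue
            rxns.append(r)
        return ReactionNetwork(keep, rxns, variant=self.variant, options=self.options)

    # -- structure --------------------------------------------------------
    def check_moiety_balance(self):
        """Every reaction outside synthesis/degradation balances all moieties."""
        for r in self.reactions:
            if r.kinetic_class in ("synthesis", "degradation"):
                continue
            bal: dict = {}
            for sid, n in r.reactants.items():
                for tag, w in self.species_by_id(sid).moieties.items():
                    bal[tag] = bal.get(tag, 0) - n * w
            for sid, n in r.products.items():
                for tag, w in self.species_by_id(sid).moieties.items():
                    bal[tag] = bal.get(tag, 0) + n * w
            bad = {t: v for t, v in bal.items() if v != 0}
            if bad:
                raise ValueError(f"moiety imbalance in {r.id}: {bad}")

    def observable_weights(self) -> dict:
        """Named linear observables as (weight-vector, normalizing moiety).

        The normalizing moiety, when not None, turns the weighted sum into a
        fraction of that moiety's current total (computed from the same
        state, so it remains correct when synthesis/degradation moves the
        total around).
        """
        n = self.n_species
        obs = {}

        def vec(pred_or_pairs):
            w = np.zeros(n)
            if callable(pred_or_pairs):
                for i, s in enumerate(self.species):
                    w[i] = pred_or_pairs(s)
            else:
                for sid, wt in pred_or_pairs:
                    w[self._index[sid]] = wt
            return w

        obs["pleC_kinase_fraction"] = (
            vec(lambda s: 1.0 if s.conformation == "T" else 0.0),
            "PleC",
        )
        obs["pleC_phosphatase_fraction"] = (
            vec(lambda s: 1.0 if s.conformation == "R" else 0.0),
            "PleC",
        )
        obs["divKp_free"] = (vec([("DivKp", 1.0)]), None)
        # phosphorylated DivK, free and bound (on PleC sites, on DivL)
        def _divkp_weight(s: Species) -> float:
            if s.id == "DivKp":
                return 1.0
            if s.sites is not None:
                return float(sum(1 for x in s.sites if x == "P"))
            if s.id == "DivL_DivKp":
                return 1.0
            if s.id == "DivL_DivKp2":
                return 2.0
            return 0.0

        obs["divKp_fraction"] = (vec(_divkp_weight), "DivK")
        obs["pleDp"] = (vec([("PleDp", 1.0), ("PleDp2", 2.0)]), None)
        obs["pleDp_fraction"] = (vec([("PleDp", 1.0), ("PleDp2", 2.0)]), "PleD")
        obs["ctrAp"] = (vec([("CtrAp", 1.0), ("CckA_P_CtrAp", 1.0)]), None)
        obs["ctrAp_fraction"] = (
            vec([("CtrAp", 1.0), ("CckA_P_CtrAp", 1.0)]),
            "CtrA",
        )
        obs["cpdRp_fraction"] = (
            vec([("CpdRp", 1.0), ("CckA_P_CpdRp", 1.0)]),
            "CpdR",
        )
        obs["divL_active"] = (vec([("DivL", 1.0)]), None)
        obs["cckA_kinase_fraction"] = (
            vec(
                [
                    ("CckA_K", 1.0),
                    ("CckA_Kp", 1.0),
                    ("CckA_Kp_CtrA", 1.0),
                    ("CckA_Kp_CpdR", 1.0),
                ]
            ),
            "CckA",
        )
        obs["divK_bound_pleC"] = (
            vec(
                lambda s: float(sum(1 for x in s.sites if x in ("K", "P")))
                if s.sites is not None
                else 0.0
            ),
            None,
        )
        # drop observables that reference species absent from a sub-network
        present = {
            name: (w, norm)
            for name, (w, norm) in obs.items()
            if np.any(w != 0) or name in ("divKp_free",)
        }
        return present

    def find_null_cycles(self):
        return find_null_cycles(self)


# ---------------------------------------------------------------------------
# dimer-state helpers


def _canon(sites) -> tuple:
    return tuple(sorted(sites, key=_LIG_ORDER.__getitem__))


def dimer_id(conf: str, h: int, sites) -> str:
    return f"PleC_{conf}{h}_{''.join(_canon(sites))}"


def _dimer_species(conf: str, h: int, sites) -> Species:
    sites = _canon(sites)
    moieties = {"PleC": 1}
    for lig in sites:
        if lig in _MOIETY_OF_LIG:
            tag = _MOIETY_OF_LIG[lig]
            moieties[tag] = moieties.get(tag, 0) + 1
    marks = {f"hisP{i}" for i in range(1, h + 1)}
    marks |= {f"divK_aspP{i}" for i in range(1, sites.count("P") + 1)}
    role = "complex" if any(l != "0" for l in sites) else "enzyme-state"
    return Species(
        id=dimer_id(conf, h, sites),
        role=role,
        moieties=moieties,
        phospho_marks=frozenset(marks),
        conformation=conf,
        sites=sites,
        his_p=h,
    )


def _enumerate_dimer_states(reduced: bool):
    """All valid PleC dimer states (optionally without singly-DivK states)."""
    out = []
    for conf in ("R", "T"):
        h_values = (0,) if conf == "R" else (0, 1, 2)
        for h in h_values:
            ligs = ["0", "K", "P"]
            if conf == "T" and h >= 1:
                ligs.append("D")
            for sites in itertools.combinations_with_replacement(ligs, 2):
                if sites.count("D") > h:
                    continue
                if reduced:
                    # drop singly-DivK-occupied intermediates
                    n_dk = sum(1 for x in sites if x in ("K", "P"))
                    if n_dk == 1 and "0" in sites:
                        continue
                out.append(_dimer_species(conf, h, sites))
    return out


def _free_species():
    mk = lambda i, role, moi, marks=():  Species(
        id=i, role=role, moieties=moi, phospho_marks=frozenset(marks)
    )
    return [
        mk("DivK", "free-protein", {"DivK": 1}),
        mk("DivKp", "free-protein", {"DivK": 1}, ("divK_aspP1",)),
        mk("DivJ", "free-protein", {"DivJ": 1}),
        mk("DivJ_DivK", "complex", {"DivJ": 1, "DivK": 1}),
        mk("PleD", "free-protein", {"PleD": 1}),
        mk("PleDp", "free-protein", {"PleD": 1}, ("pleD_aspP1",)),
        mk("PleDp2", "complex", {"PleD": 2}, ("pleD_aspP1", "pleD_aspP2")),
        mk("DivL", "free-protein", {"DivL": 1}),
        mk("DivL_DivKp", "complex", {"DivL": 1, "DivK": 1}, ("divK_aspP1",)),
        mk("DivL_DivKp2", "complex", {"DivL": 1, "DivK": 2},
           ("divK_aspP1", "divK_aspP2")),
        mk("CckA_P", "enzyme-state", {"CckA": 1}),
        mk("CckA_K", "enzyme-state", {"CckA": 1}),
        mk("CckA_Kp", "enzyme-state", {"CckA": 1}, ("hisP1",)),
        mk("CckA_Kp_CtrA", "complex", {"CckA": 1, "CtrA": 1}, ("hisP1",)),
        mk("CckA_Kp_CpdR", "complex", {"CckA": 1, "CpdR": 1}, ("hisP1",)),
        mk("CckA_P_CtrAp", "complex", {"CckA": 1, "CtrA": 1}, ("ctrA_aspP1",)),
        mk("CckA_P_CpdRp", "complex", {"CckA": 1, "CpdR": 1}, ("cpdR_aspP1",)),
        mk("CtrA", "free-protein", {"CtrA": 1}),
        mk("CtrAp", "free-protein", {"CtrA": 1}, ("ctrA_aspP1",)),
        mk("CpdR", "free-protein", {"CpdR": 1}),
        mk("CpdRp", "free-protein", {"CpdR": 1}, ("cpdR_aspP1",)),
    ]


# ---------------------------------------------------------------------------
# reaction assembly


def _replace_site(sites, old: str, new: str) -> tuple:
    s = list(sites)
    s[s.index(old)] = new
    return _canon(s)


def _build_reactions(dimers, present, reduced: bool, opts: BuildOptions):
    """Assemble the reaction list against the available dimer states."""
    LIG_FREE = {"K": "DivK", "P": "DivKp"}
    rxns = []
    seen = set()

    def add(rid, reac, prod, reversible, kclass, group, mult=1):
        if rid in seen:
            return
        seen.add(rid)
        rxns.append(
            Reaction(
                id=rid,
                reactants=dict(reac),
                products=dict(prod),
                reversible=reversible,
                kinetic_class=kclass,
                scale_group=group,
                multiplicity=mult,
            )
        )

    def decompose(conf, h, sites):
        """Map a dimer state onto available species, shedding single DivK
        ligands as free molecules when the intermediate is lumped away."""
        sid = dimer_id(conf, h, sites)
        if sid in present:
            return {sid: 1}
        n_dk = sum(1 for x in sites if x in ("K", "P"))
        if reduced and n_dk == 1 and "0" in sites:
            lig = next(x for x in sites if x in ("K", "P"))
            stripped = _replace_site(sites, lig, "0")
            out = {dimer_id(conf, h, stripped): 1}
            out[LIG_FREE[lig]] = out.get(LIG_FREE[lig], 0) + 1
            return out
        raise KeyError(sid)

    dimer_states = [(s.conformation, s.his_p, s.sites) for s in dimers]

    # --- DivK / DivK~P binding to PleC sites
    for conf, h, sites in dimer_states:
        n_free = sites.count("0")
        if n_free == 0:
            continue
        for lig, free_sp in LIG_FREE.items():
            prod_sites = _replace_site(sites, "0", lig)
            pid = dimer_id(conf, h, prod_sites)
            sid = dimer_id(conf, h, sites)
            if pid not in present:
                if reduced and n_free == 2:
                    # cooperative double-binding shortcut past the lumped
                    # singly-occupied intermediate
                    for lig2, free_sp2 in LIG_FREE.items():
                        if _LIG_ORDER[lig2] < _LIG_ORDER[lig]:
                            continue  # unordered ligand pair, emit once
                        both = _replace_site(prod_sites, "0", lig2)
                        bid = dimer_id(conf, h, both)
                        if bid not in present:
                            continue
                        reac = {sid: 1}
                        for f in (free_sp, free_sp2):
                            reac[f] = reac.get(f, 0) + 1
                        add(
                            f"bind2:{sid}+{free_sp}+{free_sp2}",
                            reac,
                            {bid: 1},
                            True,
                            "binding",
                            "bind_dk",
                            mult=2 if lig != lig2 else 1,
                        )
                continue
            add(
                f"bind:{sid}+{free_sp}",
                {sid: 1, free_sp: 1},
                {pid: 1},
                True,
                "binding",
                "bind_dk",
                mult=n_free,
            )

    # --- reduced variant: cooperative DivK+PleD double binding past the
    #     lumped singly-DivK intermediates
    if reduced:
        for conf, h, sites in dimer_states:
            if conf != "T" or h < 1 or sites != ("0", "0"):
                continue
            sid = dimer_id(conf, h, sites)
            for lig, free_sp in LIG_FREE.items():
                both = _canon((lig, "D"))
                bid = dimer_id(conf, h, both)
                if bid not in present:
                    continue
                add(
                    f"bind2:{sid}+{free_sp}+PleD",
                    {sid: 1, free_sp: 1, "PleD": 1},
                    {bid: 1},
                    True,
                    "binding",
                    "bind_pd",
                    mult=2,
                )
            if h >= 2:
                bid = dimer_id(conf, h, ("D", "D"))
                if bid in present:
                    add(
                        f"bind2:{sid}+PleD+PleD",
                        {sid: 1, "PleD": 2},
                        {bid: 1},
                        True,
                        "binding",
                        "bind_pd",
                        mult=1,
                    )

    # --- reduced variant: PleD/DivK exchange on fully occupied kinase
    #     dimers (composite of unbinding + binding through the lumped
    #     singly-occupied intermediate)
    if reduced:
        for conf, h, sites in dimer_states:
            if conf != "T" or h < 1 or "0" in sites:
                continue
            if sites.count("D") >= h:
                continue  # no spare phospho-His to dock another PleD
            for lig, free_sp in LIG_FREE.items():
                if lig not in sites:
                    continue
                tid = dimer_id(conf, h, _replace_site(sites, lig, "D"))
                if tid not in present:
                    continue
                sid = dimer_id(conf, h, sites)
                add(
                    f"exch:{sid}+PleD-{free_sp}",
                    {sid: 1, "PleD": 1},
                    {tid: 1, free_sp: 1},
                    True,
                    "binding",
                    "exch_pd",
                    mult=sites.count(lig),
                )

    # --- PleD binding (requires a free site and a spare phospho-His)
    for conf, h, sites in dimer_states:
        if conf != "T" or h < 1:
            continue
        if sites.count("0") == 0 or sites.count("D") >= h:
            continue
        prod = dimer_id(conf, h, _replace_site(sites, "0", "D"))
        sid = dimer_id(conf, h, sites)
        if prod not in present:
            continue
        add(
            f"bind:{sid}+PleD",
            {sid: 1, "PleD": 1},
            {prod: 1},
            True,
            "binding",
            "bind_pd",
            mult=sites.count("0"),
        )

    # --- concerted conformational transitions (h = 0 only; a phospho-His
    #     locks the kinase fold)
    for conf, h, sites in dimer_states:
        if conf != "R":
            continue
        tid = dimer_id("T", 0, sites)
        if tid not in present:
            continue
        add(
            f"conf:{dimer_id('R', 0, sites)}",
            {dimer_id("R", 0, sites): 1},
            {tid: 1},
            True,
            "conformational",
            "conf",
        )

    # --- autophosphorylation of the kinase conformation (ATP-driven)
    for conf, h, sites in dimer_states:
        if conf != "T" or h >= 2:
            continue
        pid = dimer_id("T", h + 1, sites)
        if pid not in present:
            continue
        sid = dimer_id(conf, h, sites)
        add(
            f"auto:{sid}",
            {sid: 1},
            {pid: 1},
            False,
            "autophosphorylation",
            "k_auto",
            mult=2 - h,
        )

    # --- phosphotransfer PleC~P -> bound DivK
    for conf, h, sites in dimer_states:
        if conf != "T" or h < 1 or "K" not in sites:
            continue
        prod_sites = _replace_site(sites, "K", "P")
        if prod_sites.count("D") > h - 1:
            continue  # remaining phospho-His must still cover docked PleD
        sid = dimer_id(conf, h, sites)
        try:
            prod = decompose("T", h - 1, prod_sites)
        except KeyError:
            continue
        add(
            f"xferdk:{sid}",
            {sid: 1},
            prod,
            True,
            "phosphotransfer",
            "transfer_dk",
            mult=sites.count("K"),
        )

    # --- phosphotransfer PleC~P -> docked PleD (transfer and release)
    for conf, h, sites in dimer_states:
        if conf != "T" or h < 1 or "D" not in sites:
            continue
        left_sites = _replace_site(sites, "D", "0")
        sid = dimer_id(conf, h, sites)
        try:
            prod = decompose("T", h - 1, left_sites)
        except KeyError:
            continue
        prod = dict(prod)
        prod["PleDp"] = prod.get("PleDp", 0) + 1
        add(
            f"xferpd:{sid}",
            {sid: 1},
            prod,
            True,
            "phosphotransfer",
            "transfer_pd",
            mult=sites.count("D"),
        )

    # --- hydrolysis of bound DivK~P by the phosphatase conformation
    for conf, h, sites in dimer_states:
        if conf != "R" or "P" not in sites:
            continue
        pid = dimer_id("R", 0, _replace_site(sites, "P", "K"))
        if pid not in present:
            continue
        sid = dimer_id(conf, h, sites)
        add(
            f"hyd:{sid}",
            {sid: 1},
            {pid: 1},
            False,
            "hydrolysis",
            "k_hyd",
            mult=sites.count("P"),
        )

    # --- phospho-His lability: spontaneous hydrolysis of undocked
    #     phospho-His (restores the conformational exit from the kinase fold)
    for conf, h, sites in dimer_states:
        if conf != "T" or h == 0:
            continue
        n_labile = h - sites.count("D")  # PleD-docked phospho-His is shielded
        if n_labile <= 0:
            continue
        pid = dimer_id("T", h - 1, sites)
        if pid not in present:
            continue
        sid = dimer_id(conf, h, sites)
        add(
            f"hydh:{sid}",
            {sid: 1},
            {pid: 1},
            False,
            "hydrolysis",
            "k_hyd_his",
            mult=n_labile,
        )

    # --- spontaneous receiver-domain dephosphorylation
    add("adph:DivKp", {"DivKp": 1}, {"DivK": 1}, False, "hydrolysis", "k_adph_dk")
    add("adph:PleDp", {"PleDp": 1}, {"PleD": 1}, False, "hydrolysis", "k_adph_pd")

    # --- DivJ: binding and (ATP-driven, lumped) phosphotransfer to DivK
    add(
        "bind:DivJ+DivK",
        {"DivJ": 1, "DivK": 1},
        {"DivJ_DivK": 1},
        True,
        "binding",
        "bind_j",
    )
    add(
        "xferdk:DivJ_DivK",
        {"DivJ_DivK": 1},
        {"DivJ": 1, "DivKp": 1},
        False,
        "phosphotransfer",
        "k_trans_j",
    )

    # --- PleD~P dimerization (the active diguanylate cyclase)
    add(
        "dim:PleDp",
        {"PleDp": 2},
        {"PleDp2": 1},
        True,
        "binding",
        "dim_pd",
    )

    # --- DivK~P binding to and inactivating DivL
    add(
        "bind:DivL+DivKp",
        {"DivL": 1, "DivKp": 1},
        {"DivL_DivKp": 1},
        True,
        "binding",
        "bind_dl",
        mult=2,
    )
    add(
        "bind:DivL_DivKp+DivKp",
        {"DivL_DivKp": 1, "DivKp": 1},
        {"DivL_DivKp2": 1},
        True,
        "binding",
        "bind_dl",
        mult=1,
    )

    # --- DivL promotes the CckA kinase form (the single Hill-regulated step)
    add(
        "hill:CckA_P",
        {"CckA_P": 1},
        {"CckA_K": 1},
        False,
        "hill-regulated",
        "k_cp_ck",
    )
    add(
        "conf:CckA_K",
        {"CckA_K": 1},
        {"CckA_P": 1},
        False,
        "conformational",
        "k_ck_cp",
    )

    # --- CckA autophosphorylation and phosphorelay (ChpT lumped into CckA)
    add(
        "auto:CckA_K",
        {"CckA_K": 1},
        {"CckA_Kp": 1},
        False,
        "autophosphorylation",
        "k_ck_ck1",
    )
    for sub, subp, cplx_k, cplx_p, xfer_scale, hyd_scale in (
        ("CtrA", "CtrAp", "CckA_Kp_CtrA", "CckA_P_CtrAp", "k_ck_xf1", "k_cp_ch1"),
        ("CpdR", "CpdRp", "CckA_Kp_CpdR", "CckA_P_CpdRp", "k_ck_xf2", "k_cp_ch2"),
    ):
        add(
            f"bind:CckA_Kp+{sub}",
            {"CckA_Kp": 1, sub: 1},
            {cplx_k: 1},
            True,
            "binding",
            "bind_ck",
        )
        add(
            f"xfer:{cplx_k}",
            {cplx_k: 1},
            {"CckA_K": 1, subp: 1},
            False,
            "phosphotransfer",
            xfer_scale,
        )
        add(
            f"bind:CckA_P+{subp}",
            {"CckA_P": 1, subp: 1},
            {cplx_p: 1},
            True,
            "binding",
            "bind_ck",
        )
        add(
            f"hyd:{cplx_p}",
            {cplx_p: 1},
            {"CckA_P": 1, sub: 1},
            False,
            "hydrolysis",
            hyd_scale,
        )

    # --- synthesis and degradation (free proteins only)
    if opts.include_syn_deg:
        add("syn:DivK", {}, {"DivK": 1}, False, "synthesis", "k_syn_dk")
        add("deg:DivK", {"DivK": 1}, {}, False, "degradation", "k_deg_dk")
        add("deg:DivKp", {"DivKp": 1}, {}, False, "degradation", "k_deg_dk")
        add("syn:PleD", {}, {"PleD": 1}, False, "synthesis", "k_syn_pd")
        add("deg:PleD", {"PleD": 1}, {}, False, "degradation", "k_deg_pd")
        add("deg:PleDp", {"PleDp": 1}, {}, False, "degradation", "k_deg_pd")
        add("syn:CtrA", {}, {"CtrA": 1}, False, "synthesis", "k_syn_ct")
        add("deg:CtrA", {"CtrA": 1}, {}, False, "degradation", "k_deg_ct")
        add("deg:CtrAp", {"CtrAp": 1}, {}, False, "degradation", "k_deg_ct")
        # unphosphorylated (active) CpdR turns on the ClpXP route for CtrA
        add(
            "deg:CtrA+CpdR",
            {"CtrA": 1, "CpdR": 1},
            {"CpdR": 1},
            False,
            "degradation",
            "k_deg_ct_cp",
        )
        add(
            "deg:CtrAp+CpdR",
            {"CtrAp": 1, "CpdR": 1},
            {"CpdR": 1},
            False,
            "degradation",
            "k_deg_ct_cp",
        )
    return rxns


def _assemble(variant: str, opts: BuildOptions) -> ReactionNetwork:
    opts.validate()
    reduced = variant == "reduced"
    dimers = _enumerate_dimer_states(reduced)
    species = dimers + _free_species()
    present = {s.id for s in species}
    reactions = _build_reactions(dimers, present, reduced, opts)
    net = ReactionNetwork(species, reactions, variant=variant, options=opts)
    net.check_moiety_balance()
    n_hill = sum(1 for r in net.reactions if r.kinetic_class == "hill-regulated")
    if n_hill != 1:
        raise AssertionError(f"expected exactly one Hill-regulated reaction, got {n_hill}")
    return net


def build_full_network(options: BuildOptions | None = None) -> ReactionNetwork:
    """Assemble the full 52-species model."""
    return _assemble("full", options or BuildOptions())


def build_reduced_network(options: BuildOptions | None = None) -> ReactionNetwork:
    """Assemble the reduced model (20-variable PleC--DivK core)."""
    return _assemble("reduced", options or BuildOptions())


# ---------------------------------------------------------------------------
# stoichiometry


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Species x reactions matrix of net stoichiometric changes."""
    S = np.zeros((network.n_species, network.n_reactions))
    for j, r in enumerate(network.reactions):
        for sid, n in r.reactants.items():
            S[network.index(sid), j] -= n
        for sid, n in r.products.items():
            S[network.index(sid), j] += n
    return S


def find_null_cycles(network: ReactionNetwork, reaction_filter=None):
    """Integer basis of null cycles among the reversible reactions.

    A null cycle is a combination of reversible reactions with zero net
    stoichiometric change; around each one, detailed balance requires the
    product of forward rate constants to equal the product of reverse rate
    constants.  Returns a list of ``{reaction_id: integer coefficient}``
    maps (the coefficient sign gives the orientation).
    """
    import sympy

    rev = [
        r
        for r in network.reactions
        if r.reversible and (reaction_filter is None or reaction_filter(r))
    ]
    if not rev:
        return []
    cache_key = frozenset(r.id for r in rev)
    if network._cycles is None:
        network._cycles = {}
    if cache_key in network._cycles:
        return network._cycles[cache_key]
    cols = []
    for r in rev:
        col = np.zeros(network.n_species, dtype=int)
        for sid, n in r.reactants.items():
            col[network.index(sid)] -= n
        for sid, n in r.products.items():
            col[network.index(sid)] += n
        cols.append(col)
    S = sympy.Matrix(np.array(cols, dtype=int).T)
    basis = S.nullspace()
    cycles = []
    for v in basis:
        denoms = [sympy.fraction(x)[1] for x in v]
        scale = sympy.lcm([d for d in denoms]) if denoms else 1
        ints = [int(x * scale) for x in v]
        g = math.gcd(*[abs(i) for i in ints if i != 0]) if any(ints) else 1
        cyc = {
            rev[k].id: ints[k] // g for k in range(len(rev)) if ints[k] != 0
        }
        cycles.append(cyc)
    network._cycles[cache_key] = cycles
    return cycles
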