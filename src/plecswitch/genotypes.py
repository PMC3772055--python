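"""Mutant genotypes as parameter transformations, and figure-level experiments.

Each mutant of the *Caulobacter* literature is encoded as a transformation
of the model configuration (totals, kinetic scales, or free energies):

* ``delta_divJ``      -- DivJ deleted: ``DivJ_tot = 0``.
* ``divK_D53N``       -- DivK that cannot accept a phosphoryl group: every
  DivK phosphotransfer rate (from DivJ and from PleC) set to zero.
* ``pleC_F778L``      -- PleC without autokinase activity: the His
  autophosphorylation rate set to zero (the conformational switch itself
  is untouched, which is the point of this genotype).
* ``pleC_Tn5``        -- PleC null: ``PleC_tot = 0``.
* ``divK_D90G``       -- DivK that is no longer an allosteric inducer: the
  kinase-conformation binding energies are set equal to their
  phosphatase-form values (so binding no longer biases the fold), with all
  equilibrium constants re-derived from the energy table -- detailed
  balance is preserved by construction; in addition its binding to DivL is
  weakened by a configurable factor on the dissociation constant.
* ``divK_X``          -- hypothetical mutant: like ``divK_D90G`` but with
  wild-type DivL binding.

Combinations compose left to right (``delta_divJ_divK_D53N``,
``pleC_Tn5_divK_D90G``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bifurcation import ModelFamily, bistable_interval, sweep_branch, trace_region_boundary
from .dynamics import Model, ModelConfig, SteadyStateError, find_steady_state
from .thermo import check_detailed_balance

__all__ = [
    "MutantSpec",
    "MUTANTS",
    "apply_mutant",
    "steady_state_fractions",
    "run_experiment",
    "STALKED_DIVJ",
    "SWARMER_DIVJ",
]

#: DivJ_tot representing a stalked cell (above the upper fold of the
#: baseline bistable interval) and a swarmer cell (DivJ absent)
STALKED_DIVJ = 1.2
SWARMER_DIVJ = 0.0

#: default weakening factor on the DivK~P--DivL dissociation constant for
#: divK_D90G (qualitative weakening; the precise factor is a model choice)
DIVL_WEAKEN_FACTOR = 100.0


@dataclass(frozen=True)
class MutantSpec:
    """A named genotype with its parameter overrides.

    ``scale_overrides`` and ``named_overrides`` assign values; the
    ``allosteric_null`` flag equalizes kinase/phosphatase binding energies
    of DivK and DivK~P; ``divL_weaken`` multiplies the DivK~P--DivL
    dissociation constant.
    """

    name: str
    scale_overrides: tuple = ()
    named_overrides: tuple = ()
    allosteric_null: bool = False
    divL_weaken: float = 1.0

    def compose(self, other: "MutantSpec") -> "MutantSpec":
        return MutantSpec(
            name=f"{self.name}_{other.name}",
            scale_overrides=self.scale_overrides + other.scale_overrides,
            named_overrides=self.named_overrides + other.named_overrides,
            allosteric_null=self.allosteric_null or other.allosteric_null,
            divL_weaken=self.divL_weaken * other.divL_weaken,
        )


def _base_mutants() -> dict:
    wild_type = MutantSpec("wild_type")
    delta_divJ = MutantSpec("delta_divJ", named_overrides=(("DivJ_tot", 0.0),))
    divK_D53N = MutantSpec(
        "divK_D53N", scale_overrides=(("transfer_dk", 0.0), ("k_trans_j", 0.0))
    )
    pleC_F778L = MutantSpec("pleC_F778L", scale_overrides=(("k_auto", 0.0),))
    pleC_Tn5 = MutantSpec("pleC_Tn5", named_overrides=(("PleC_tot", 0.0),))
    divK_D90G = MutantSpec(
        "divK_D90G", allosteric_null=True, divL_weaken=DIVL_WEAKEN_FACTOR
    )
    divK_X = MutantSpec("divK_X", allosteric_null=True)
    out = {
        m.name: m
        for m in (
            wild_type,
            delta_divJ,
            divK_D53N,
            pleC_F778L,
            pleC_Tn5,
            divK_D90G,
            divK_X,
        )
    }
    out["delta_divJ_divK_D53N"] = delta_divJ.compose(divK_D53N)
    out["pleC_Tn5_divK_D90G"] = pleC_Tn5.compose(divK_D90G)
    return out


MUTANTS = _base_mutants()


def apply_mutant(config: ModelConfig, mutant) -> ModelConfig:
    """Transform a configuration into the given genotype.

    Accepts a mutant name or a :class:`MutantSpec`.  The returned
    configuration is re-verified for detailed balance (energy-level edits
    re-derive every equilibrium constant, so this passes by construction;
    the check guards against future edits breaking that property).
    """
    if isinstance(mutant, str):
        try:
            mutant = MUTANTS[mutant]
        except KeyError:
            raise KeyError(
                f"unknown mutant {mutant!r}; known: {sorted(MUTANTS)}"
            ) from None
    cfg = config
    for k, v in mutant.scale_overrides:
        cfg = cfg.updated(k, v)
    for k, v in mutant.named_overrides:
        cfg = cfg.updated(k, v)
    if mutant.allosteric_null:
        ep = cfg.energy
        cfg = replace(cfg, energy=replace(ep, b_TK=ep.b_RK, b_TP=ep.b_RP))
    if mutant.divL_weaken != 1.0:
        ep = cfg.energy
        cfg = replace(
            cfg, energy=replace(ep, b_LP=ep.b_LP + math.log(mutant.divL_weaken))
        )
    model = Model(cfg)
    residuals = check_detailed_balance(model.network, model.params)
    worst = max(residuals.values(), default=0.0)
    if worst > 1e-9:
        raise ValueError(
            f"mutant {mutant.name} breaks detailed balance (residual {worst:.2e})"
        )
    return cfg


FRACTION_OBSERVABLES = (
    "pleC_kinase_fraction",
    "divKp_fraction",
    "ctrAp_fraction",
    "pleDp_fraction",
)


def steady_state_fractions(
    config: ModelConfig, mutant, divJ_level: float, policy: str | None = None
) -> dict:
    """The four phenotype fractions at a given DivJ level.

    Each phosphoform is normalized by its moiety total, so values lie in
    [0, 1].  The start policy defaults to the cell type the DivJ level
    implies (stalked above the baseline transition, swarmer at zero).
    """
    cfg = apply_mutant(config, mutant).updated("DivJ_tot", divJ_level)
    model = Model(cfg)
    if policy is None:
        policy = "stalked" if divJ_level > 0.5 else "swarmer"
    x, _ = find_steady_state(model, model.initial_state(policy))
    obs = model.observables(x)
    return {k: obs[k] for k in FRACTION_OBSERVABLES}


# ---------------------------------------------------------------------------
# figure-level experiments


def _divk_titration(config: ModelConfig, k_syn_values, observables=("pleDp",)):
    """Sweep the DivK synthesis rate, reporting steady-state total DivK and
    the requested observables (the model's knob for total DivK is the
    synthesis constant)."""
    rows = []
    model = Model(config.updated("k_syn_dk", float(k_syn_values[0])))
    x, _ = find_steady_state(model, model.initial_state("swarmer"))
    for ks in k_syn_values:
        model = Model(config.updated("k_syn_dk", float(ks)))
        try:
            xs, st = find_steady_state(model, x, polish_only=True)
            if not st:
                raise SteadyStateError("unstable")
        except SteadyStateError:
            try:
                xs, st = find_steady_state(model, x)
            except SteadyStateError:
                # re-seed from scratch if continuation hit a stiff pocket
                xs, st = find_steady_state(model, model.initial_state("swarmer"))
        x = xs
        row = {"k_syn_dk": ks, "DivK_tot": model.moiety_total("DivK", x)}
        for ob in observables:
            row[ob] = model.observable(ob, x)
        rows.append(row)
    return pd.DataFrame(rows)


def _two_branch_frame(config, parameter, values, observables):
    fwd = sweep_branch(config, parameter, values, "forward")
    bwd = sweep_branch(config, parameter, values, "backward")
    frames = []
    for br, tag in ((fwd, "forward"), (bwd, "backward")):
        df = br.observables[[parameter] + list(observables)].copy()
        df["direction"] = tag
        df["stable"] = br.stable
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _scale_sweep(config, parameter, values, observable="ctrAp_fraction"):
    rows = []
    model = Model(config.updated(parameter, float(values[0])))
    x, _ = find_steady_state(model, model.initial_state("swarmer"))
    for v in values:
        model = Model(config.updated(parameter, float(v)))
        try:
            xs, st = find_steady_state(model, x, polish_only=True)
            if not st:
                raise SteadyStateError("unstable")
        except SteadyStateError:
            xs, st = find_steady_state(model, x)
        x = xs
        rows.append({parameter: v, observable: model.observable(observable, x)})
    return pd.DataFrame(rows)


def run_experiment(name: str, config: ModelConfig | None = None, fast: bool = False) -> dict:
    """Run one of the named figure-level computational experiments.

    Returns a dict of named DataFrames.  ``fast`` shrinks grids for test
    runs; defaults aim at plot-quality resolution.
    """
    cfg = config or ModelConfig(variant="reduced")
    n = 31 if fast else 81
    jmax = 2.0
    jvals = np.linspace(0.0, jmax, n)
    handlers = {
        "fig3": _exp_fig3,
        "fig4": _exp_fig4,
        "fig5": _exp_fig5,
        "fig6": _exp_fig6,
        "fig7": _exp_fig7,
        "fig8": _exp_fig8,
        "fig9": _exp_fig9,
    }
    if name not in handlers:
        raise KeyError(f"unknown experiment {name!r}; known: {sorted(handlers)}")
    return handlers[name](cfg, jvals, fast)


def _exp_fig3(cfg, jvals, fast):
    """Signal-response curves of the core module vs total DivJ."""
    full_cfg = replace(cfg, variant="full")
    obs = ["pleC_kinase_fraction", "divKp_fraction", "pleDp_fraction", "divK_bound_pleC"]
    return {"branches": _two_branch_frame(full_cfg, "DivJ_tot", jvals, obs)}


def _exp_fig4(cfg, jvals, fast):
    """Steady-state PleD~P against total DivK in three genotypes."""
    npts = 13 if fast else 25
    ks = np.geomspace(0.002, 0.45, npts)
    out = {}
    for tag, mutant, J in (
        ("delta_divJ_divK_D53N", "delta_divJ_divK_D53N", 0.0),
        ("delta_divJ", "delta_divJ", 0.0),
        ("wild_type", "wild_type", 0.02),
    ):
        mcfg = apply_mutant(cfg, mutant).updated("DivJ_tot", J)
        out[tag] = _divk_titration(mcfg, ks, observables=("pleDp", "pleC_kinase_fraction"))
    return out


def _exp_fig5(cfg, jvals, fast):
    """Two-parameter bistable region and three one-parameter sections."""
    k2 = np.geomspace(0.004, 0.4, 12 if fast else 24)
    region = trace_region_boundary(
        cfg, "DivJ_tot", "k_syn_dk", (0.0, jvals[-1]), k2,
        n1=21 if fast else 41, refine_projection=not fast,
    )
    sections = {}
    for ks in (0.005, 0.015, 0.12):
        sec_cfg = cfg.updated("k_syn_dk", ks)
        sections[f"k_syn_dk={ks}"] = _two_branch_frame(
            sec_cfg, "DivJ_tot", jvals, ["pleC_kinase_fraction"]
        )
    return {"region_grid": region.grid, "region_boundary": region.boundary,
            "projection_bounds": pd.DataFrame([{
                "k_syn_dk_min": region.projection_bounds[0],
                "k_syn_dk_max": region.projection_bounds[1]}]),
            **{f"section_{k}": v for k, v in sections.items()}}


def _exp_fig6(cfg, jvals, fast):
    """Downstream module (DivL, CckA, CtrA~P, CpdR~P) vs total DivJ."""
    obs = ["divL_active", "cckA_kinase_fraction", "ctrAp_fraction", "cpdRp_fraction"]
    return {"branches": _two_branch_frame(cfg, "DivJ_tot", jvals, obs)}


def _exp_fig7(cfg, jvals, fast):
    """CtrA~P vs CckA-module rate constants in the delta-divJ background."""
    dj = apply_mutant(cfg, "delta_divJ")
    npts = 9 if fast else 17
    out = {}
    for par in ("k_cp_ck", "k_ck_ck1", "k_cp_ch1"):
        base = dj.get_param(par)
        vals = np.geomspace(base / 30.0, base * 30.0, npts)
        out[par] = _scale_sweep(dj, par, vals)
    # wild-type stalked reference level
    wt = steady_state_fractions(cfg, "wild_type", STALKED_DIVJ)
    out["wild_type_reference"] = pd.DataFrame([wt])
    return out


def _exp_fig8(cfg, jvals, fast):
    """Wild type vs divK_D90G branches; pleC_Tn5 vs the double mutant."""
    obs = ["divKp_fraction", "pleDp_fraction", "pleC_kinase_fraction", "ctrAp_fraction"]
    out = {}
    for tag in ("wild_type", "divK_D90G", "pleC_Tn5", "pleC_Tn5_divK_D90G"):
        out[tag] = _two_branch_frame(apply_mutant(cfg, tag), "DivJ_tot", jvals, obs)
    return out


def _exp_fig9(cfg, jvals, fast):
    """Four-fraction panels for wild type and three kinase-defective mutants."""
    rows = []
    for tag in ("wild_type", "pleC_F778L", "divK_D90G", "divK_X"):
        fr = steady_state_fractions(cfg, tag, STALKED_DIVJ)
        fr.update({"genotype": tag, "DivJ_tot": STALKED_DIVJ})
        rows.append(fr)
    return {"fractions": pd.DataFrame(rows)}
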