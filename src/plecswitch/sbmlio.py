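"""Minimal SBML Level 3 export/import for the reaction network.

The writer emits species, compartments, parameters and reactions with
mass-action kinetic laws in MathML (the single Hill-regulated step carries
its Hill expression explicitly).  The reader recovers the structural
content -- species and reactions with stoichiometries -- which is what the
round-trip contract guarantees; kinetic laws are parsed back only as the
rate-constant parameter values.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .network import ReactionNetwork
from .thermo import ParameterSet

__all__ = ["export_sbml", "import_sbml_structure", "SbmlStructure"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _math(expr_root: ET.Element) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(expr_root)
    return math


def _ci(name: str) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _apply(op: str, *args) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}apply")
    el.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    for a in args:
        el.append(a)
    return el


def _times(*args):
    if len(args) == 1:
        return args[0]
    return _apply("times", *args)


def _sanitize(rid: str) -> str:
    out = []
    for ch in rid:
        out.append(ch if ch.isalnum() or ch == "_" else "_")
    s = "".join(out)
    return s if s[0].isalpha() or s[0] == "_" else "r_" + s


def export_sbml(network: ReactionNetwork, params: ParameterSet | None = None,
                path=None) -> str:
    """Serialize the network (and rates, if given) as SBML Level 3.

    Returns the XML text; also writes it to ``path`` when given.
    """
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model",
                          {"id": f"plec_switch_{network.variant}"})
    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "constant": "true", "spatialDimensions": "3",
                   "size": "1"})
    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(
            species_el,
            f"{{{SBML_NS}}}species",
            {
                "id": sp.id,
                "compartment": "cell",
                "initialConcentration": "0",
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )
    if params is not None:
        pars = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
        for name, value in sorted(params.named.items()):
            ET.SubElement(pars, f"{{{SBML_NS}}}parameter",
                          {"id": name, "value": f"{value:.12g}",
                           "constant": "true"})
    rxns_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for r in network.reactions:
        rid = _sanitize(r.id)
        rx = ET.SubElement(
            rxns_el, f"{{{SBML_NS}}}reaction",
            {"id": rid, "reversible": "true" if r.reversible else "false",
             "name": r.kinetic_class},
        )
        if r.reactants:
            lor = ET.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sid, n in r.reactants.items():
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                              {"species": sid, "stoichiometry": str(n),
                               "constant": "true"})
        if r.products:
            lop = ET.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sid, n in r.products.items():
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                              {"species": sid, "stoichiometry": str(n),
                               "constant": "true"})
        if params is not None:
            kf = params.kf[r.id]
            kr = params.kr.get(r.id, 0.0)
            kl = ET.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
            fwd_factors = [_ci(f"kf_{rid}")]
            for sid, n in r.reactants.items():
                fwd_factors.extend([_ci(sid)] * n)
            if r.kinetic_class == "hill-regulated":
                # vmax * DivL^n / (K^n + DivL^n) scaling
                nm = params.named
                hill = _apply(
                    "divide",
                    _apply("power", _ci("DivL"), _ci("hill_n")),
                    _apply(
                        "plus",
                        _apply("power", _ci("hill_K"), _ci("hill_n")),
                        _apply("power", _ci("DivL"), _ci("hill_n")),
                    ),
                )
                fwd_factors.extend([_ci("hill_vmax"), hill])
            fwd = _times(*fwd_factors)
            if r.reversible:
                rev_factors = [_ci(f"kr_{rid}")]
                for sid, n in r.products.items():
                    rev_factors.extend([_ci(sid)] * n)
                expr = _apply("minus", fwd, _times(*rev_factors))
            else:
                expr = fwd
            kl.append(_math(expr))
            lolp = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
            ET.SubElement(lolp, f"{{{SBML_NS}}}localParameter",
                          {"id": f"kf_{rid}", "value": f"{kf:.12g}"})
            if r.reversible:
                ET.SubElement(lolp, f"{{{SBML_NS}}}localParameter",
                              {"id": f"kr_{rid}", "value": f"{kr:.12g}"})
    ET.indent(sbml)
    text = ET.tostring(sbml, encoding="unicode", xml_declaration=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@dataclass
class SbmlStructure:
    """Structural content recovered from an SBML document."""

    species: list
    reactions: list  # (id, reactants dict, products dict, reversible)
    parameters: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)


def import_sbml_structure(source) -> SbmlStructure:
    """Read species/reaction structure back from SBML text or a file path."""
    text = source
    if "\n" not in str(source) and not str(source).lstrip().startswith("<"):
        with open(source) as fh:
            text = fh.read()
    root = ET.fromstring(text)
    ns = {"s": SBML_NS}
    species = [
        el.get("id") for el in root.findall(".//s:listOfSpecies/s:species", ns)
    ]
    reactions = []
    for rx in root.findall(".//s:listOfReactions/s:reaction", ns):
        def side(tag):
            out = {}
            for ref in rx.findall(f"s:{tag}/s:speciesReference", ns):
                out[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
            return out
        reactions.append(
            (
                rx.get("id"),
                side("listOfReactants"),
                side("listOfProducts"),
                rx.get("reversible") == "true",
            )
        )
    parameters = {
        el.get("id"): float(el.get("value"))
        for el in root.findall(".//s:listOfParameters/s:parameter", ns)
        if el.get("value") is not None
    }
    return SbmlStructure(species, reactions, parameters)
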