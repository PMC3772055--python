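"""Reading and writing a subset of the XPPAUT ``.ode`` dialect.

Supported constructs: ``par``/``p`` assignments, ``init`` lines (including
``x(0)=...``), derivative definitions (``dX/dt=...`` or ``X'=...``),
``aux`` output definitions, ``@`` numerics options (collected, warned,
otherwise ignored) and ``done``.  Everything else that XPPAUT knows
(tables, Markov chains, wieners, global flags, ...) raises an explicit
unsupported-feature error rather than being silently mangled.

Parameter names are normalized case-insensitively with underscores
collapsed, since the same rate constant appears in the literature both as
``k_syn_dk`` and ``k_syndk``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .dynamics import Model

logger = logging.getLogger(__name__)

__all__ = [
    "OdeModel",
    "OdeParseError",
    "UnsupportedFeatureError",
    "normalize_name",
    "parse_ode_file",
    "write_ode_file",
]


class OdeParseError(ValueError):
    def __init__(self, message, line_no=None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class UnsupportedFeatureError(OdeParseError):
    pass


_UNSUPPORTED = ("table", "markov", "wiener", "global", "volt", "special",
                "solv", "bdry", "0=")


def normalize_name(name: str) -> str:
    """Case-insensitive, underscore-collapsed parameter-name key."""
    return name.strip().lower().replace("_", "")


@dataclass
class OdeModel:
    """Parsed content of an ``.ode`` file.

    ``parameters`` and ``initial`` are keyed by normalized name but retain
    the original spellings in ``names``; ``equations`` holds the derivative
    expressions as text for cross-validation against a generated model.
    """

    parameters: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    equations: dict = field(default_factory=dict)
    aux: dict = field(default_factory=dict)
    options: list = field(default_factory=list)
    names: dict = field(default_factory=dict)

    def parameter(self, name: str) -> float:
        return self.parameters[normalize_name(name)]


_ASSIGN = re.compile(r"\s*([A-Za-z]\w*)\s*=\s*([^,]+)")
_DERIV_SLASH = re.compile(r"^d([A-Za-z]\w*)/dt\s*=\s*(.+)$", re.IGNORECASE)
_DERIV_PRIME = re.compile(r"^([A-Za-z]\w*)'\s*=\s*(.+)$")
_INIT_CALL = re.compile(r"^([A-Za-z]\w*)\(0\)\s*=\s*(.+)$")


def _parse_number(text: str, line_no: int) -> float:
    try:
        return float(text.strip())
    except ValueError:
        raise OdeParseError(f"expected a number, got {text.strip()!r}", line_no)


def parse_ode_file(path) -> OdeModel:
    """Parse an XPPAUT ``.ode`` file (the supported dialect subset)."""
    model = OdeModel()
    with open(path) as fh:
        lines = fh.readlines()
    for line_no, raw in enumerate(lines, start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        lowered = line.lower()
        if lowered == "done":
            break
        if lowered.startswith("@"):
            model.options.append(line[1:].strip())
            logger.warning("ignoring numerics option on line %d: %s",
                           line_no, line)
            continue
        first = lowered.split()[0] if lowered.split() else ""
        for bad in _UNSUPPORTED:
            if lowered.startswith(bad):
                raise UnsupportedFeatureError(
                    f"construct {bad!r} is not supported", line_no
                )
        if first in ("par", "param", "p"):
            body = line[len(first):]
            matches = list(_ASSIGN.finditer(body))
            if not matches:
                raise OdeParseError("malformed parameter line", line_no)
            for m in matches:
                name, value = m.group(1), _parse_number(m.group(2), line_no)
                key = normalize_name(name)
                model.parameters[key] = value
                model.names[key] = name
            continue
        if first == "init":
            body = line[len(first):]
            matches = list(_ASSIGN.finditer(body))
            if not matches:
                raise OdeParseError("malformed init line", line_no)
            for m in matches:
                model.initial[normalize_name(m.group(1))] = _parse_number(
                    m.group(2), line_no
                )
            continue
        if first == "aux":
            body = line[len(first):].strip()
            if "=" not in body:
                raise OdeParseError("malformed aux line", line_no)
            name, expr = body.split("=", 1)
            model.aux[normalize_name(name)] = expr.strip()
            continue
        m = _DERIV_SLASH.match(line) or _DERIV_PRIME.match(line)
        if m:
            model.equations[normalize_name(m.group(1))] = m.group(2).strip()
            continue
        m = _INIT_CALL.match(line)
        if m:
            model.initial[normalize_name(m.group(1))] = _parse_number(
                m.group(2), line_no
            )
            continue
        raise OdeParseError(f"unrecognized line: {line!r}", line_no)
    return model


# ---------------------------------------------------------------------------
# writer


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def _rate_expr(reaction, params) -> str:
    def product(side):
        terms = []
        for sid, n in side.items():
            terms.extend([_sanitize(sid)] * n)
        return "*".join(terms) if terms else "1"

    rid = _sanitize(reaction.id)
    if reaction.kinetic_class == "hill-regulated":
        return (
            f"kf_{rid}*hill_vmax*DivL^hill_n/"
            f"(hill_K^hill_n+DivL^hill_n)*{product(reaction.reactants)}"
        )
    expr = f"kf_{rid}*{product(reaction.reactants)}"
    if reaction.reversible:
        expr += f"-kr_{rid}*{product(reaction.products)}"
    return f"({expr})" if reaction.reversible else expr


def write_ode_file(model: Model, path, initial_policy: str = "swarmer"):
    """Emit the model as an XPPAUT-dialect ``.ode`` file.

    Every rate constant becomes a ``par`` line; each species gets a
    derivative line assembled from its reactions.  Observables are linear
    combinations the reader can reconstruct from the state, so no ``aux``
    lines are emitted.
    """
    net, pm = model.network, model.params
    lines = [f"# {net.variant} PleC-switch model, generated"]
    for name in sorted(pm.named):
        lines.append(f"par {name}={pm.named[name]:.12g}")
    for name, value in sorted(model.config.scale_dict().items()):
        lines.append(f"par {name}={value:.12g}")
    for r in net.reactions:
        rid = _sanitize(r.id)
        lines.append(f"par kf_{rid}={pm.kf[r.id]:.12g}")
        if r.reversible:
            lines.append(f"par kr_{rid}={pm.kr[r.id]:.12g}")
    x0 = model.initial_state(initial_policy)
    for i, sid in enumerate(net.species_ids):
        lines.append(f"init {_sanitize(sid)}={x0[i]:.12g}")
    contributions = {sid: [] for sid in net.species_ids}
    for r in net.reactions:
        expr = _rate_expr(r, pm)
        for sid, n in r.reactants.items():
            coeff = f"-{n}*" if n > 1 else "-"
            contributions[sid].append(f"{coeff}{expr}")
        for sid, n in r.products.items():
            coeff = f"+{n}*" if n > 1 else "+"
            contributions[sid].append(f"{coeff}{expr}")
    for sid in net.species_ids:
        terms = contributions[sid]
        rhs = "".join(terms) if terms else "0"
        if rhs.startswith("+"):
            rhs = rhs[1:]
        lines.append(f"d{_sanitize(sid)}/dt={rhs}")
    lines.append("done")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def apply_ode_parameters(config, ode_model: OdeModel):
    """Overlay parameters parsed from an ``.ode`` file onto a configuration.

    Matching is by normalized name against the configuration's named
    constants and kinetic scales; unmatched parameters are returned for the
    caller to inspect (imported values replace package defaults).
    """
    from .thermo import DEFAULT_NAMED, DEFAULT_SCALES

    known = {}
    for name in list(DEFAULT_NAMED) + list(DEFAULT_SCALES):
        known[normalize_name(name)] = name
    unmatched = {}
    cfg = config
    for key, value in ode_model.parameters.items():
        if key in known:
            cfg = cfg.updated(known[key], value)
        else:
            unmatched[ode_model.names.get(key, key)] = value
    return cfg, unmatched
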