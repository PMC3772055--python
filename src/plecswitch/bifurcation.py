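"""One- and two-parameter bifurcation analysis by natural continuation.

Steady-state branches are tracked by sweeping a parameter in a given
direction, seeding each solve with the previous solution; forward and
backward sweeps started from the two canonical cell states discover the
lower and upper stable branches, and the parameter interval on which they
disagree is the bistable (hysteresis) interval.  Interval endpoints are the
saddle-node (fold) locations, refined by bisection.  Unstable branches are
not continued; the analysis targets the stable branches and fold positions.

The machinery is generic over a small "family" protocol so that it can be
exercised on analytic normal forms (the fold ``mu + x - x**3`` and the cusp
``a + b*x - x**3``) where fold and cusp loci are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Model, ModelConfig, SteadyStateError, find_steady_state

__all__ = [
    "Branch",
    "BistableRegion",
    "ModelFamily",
    "ScalarODEFamily",
    "cubic_fold_family",
    "cusp_family",
    "sweep_branch",
    "bistable_interval",
    "trace_region_boundary",
]

#: observable gap above which two steady states count as distinct
GAP_TOL = 1e-4
#: relative bisection tolerance for interval endpoints
REFINE_REL = 1e-4


@dataclass
class Branch:
    """A steady-state branch from a directional parameter sweep."""

    parameter: str
    values: np.ndarray
    states: list
    stable: list
    observables: pd.DataFrame
    direction: str
    truncated: bool = False

    def trace(self, name: str) -> np.ndarray:
        return self.observables[name].to_numpy()


@dataclass
class BistableRegion:
    """Two-parameter bistable region: fold loci and classification grid."""

    p1: str
    p2: str
    boundary: pd.DataFrame  # columns: p2, lo, hi (fold positions in p1)
    grid: pd.DataFrame  # columns: p2, bistable (bool), lo, hi
    projection_bounds: tuple  # (min p2, max p2) admitting bistability

    @property
    def empty(self) -> bool:
        return not bool(self.grid["bistable"].any())


# ---------------------------------------------------------------------------
# system families


class ModelFamily:
    """Continuation adapter for the reaction-network model."""

    def __init__(self, config: ModelConfig, gap_observable: str = "pleC_kinase_fraction"):
        self.config = config
        self.gap_observable = gap_observable

    def solve(self, params: dict, seed=None, policy: str = "swarmer"):
        cfg = self.config
        for k, v in params.items():
            cfg = cfg.updated(k, v)
        model = Model(cfg)
        if seed is None:
            seed = model.initial_state(policy)
            return model, *find_steady_state(model, seed)
        try:
            x, st = find_steady_state(model, seed, polish_only=True)
            if st:
                return model, x, st
        except SteadyStateError:
            pass
        return model, *find_steady_state(model, seed)

    def observable(self, model, x) -> float:
        return model.observable(self.gap_observable, x)

    def observables(self, model, x) -> dict:
        return model.observables(x)


class ScalarODEFamily:
    """One-dimensional test system ``dx/dt = f(x; params)``.

    Used with the fold and cusp normal forms, whose saddle-node loci are
    known in closed form.
    """

    gap_observable = "x"

    def __init__(self, f, dfdx, base_params: dict):
        self.f = f
        self.dfdx = dfdx
        self.base = dict(base_params)

    def solve(self, params: dict, seed=None, policy: str = "swarmer"):
        p = {**self.base, **params}
        if seed is None:
            x = -2.0 if policy == "swarmer" else 2.0
        else:
            x = float(np.asarray(seed).ravel()[0])
        # march in the flow direction with a fixed step; a sign change of f
        # brackets the stable root of the seed's basin, which bisection then
        # resolves (time flow never converges onto an unstable root)
        fx = self.f(x, p)
        found = abs(fx) < 1e-14
        for _ in range(20000):
            if found:
                break
            x_new = x + 0.01 * np.sign(fx)
            f_new = self.f(x_new, p)
            if f_new == 0.0:
                x, fx, found = x_new, f_new, True
            elif np.sign(f_new) != np.sign(fx):
                a, fa, b = x, fx, x_new
                for _ in range(120):
                    m = 0.5 * (a + b)
                    fm = self.f(m, p)
                    if np.sign(fm) == np.sign(fa):
                        a, fa = m, fm
                    else:
                        b = m
                x = 0.5 * (a + b)
                fx = self.f(x, p)
                found = True
            else:
                x, fx = x_new, f_new
        if not found or abs(self.f(x, p)) > 1e-10:
            raise SteadyStateError("scalar solve did not converge")
        stable = self.dfdx(x, p) < 0
        return p, np.array([x]), stable

    def observable(self, model, x) -> float:
        return float(np.asarray(x).ravel()[0])

    def observables(self, model, x) -> dict:
        return {"x": self.observable(model, x)}


def cubic_fold_family() -> ScalarODEFamily:
    """``dx/dt = mu + x - x**3``: folds at mu = -/+ 2/(3*sqrt(3))."""
    return ScalarODEFamily(
        f=lambda x, p: p["mu"] + x - x**3,
        dfdx=lambda x, p: 1.0 - 3.0 * x**2,
        base_params={"mu": 0.0},
    )


def cusp_family() -> ScalarODEFamily:
    """``dx/dt = a + b*x - x**3``: fold boundary at 4 b^3 = 27 a^2."""
    return ScalarODEFamily(
        f=lambda x, p: p["a"] + p["b"] * x - x**3,
        dfdx=lambda x, p: p["b"] - 3.0 * x**2,
        base_params={"a": 0.0, "b": 1.0},
    )


def _family_for(config_or_family, gap_observable=None):
    if isinstance(config_or_family, ModelConfig):
        return ModelFamily(config_or_family, gap_observable or "pleC_kinase_fraction")
    if gap_observable is not None and hasattr(config_or_family, "gap_observable"):
        config_or_family.gap_observable = gap_observable
    return config_or_family


# ---------------------------------------------------------------------------
# one-parameter sweeps


def sweep_branch(
    config_or_family,
    parameter: str,
    values,
    direction: str = "forward",
    policy: str | None = None,
    gap_observable: str | None = None,
) -> Branch:
    """Track a steady-state branch across ``values`` by natural continuation.

    ``direction`` 'forward' sweeps the values in ascending order starting
    from the swarmer-like state; 'backward' descends from the stalked-like
    state.  Loss of convergence truncates the branch (a fold signature).
    """
    fam = _family_for(config_or_family, gap_observable)
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) < 2:
        raise ValueError("need at least 2 parameter values")
    if direction == "backward":
        values = values[::-1]
    elif direction != "forward":
        raise ValueError("direction must be 'forward' or 'backward'")
    if policy is None:
        policy = "swarmer" if direction == "forward" else "stalked"

    states, stabs, rows, kept = [], [], [], []
    x = None
    truncated = False
    for p in values:
        try:
            model, x, st = fam.solve({parameter: float(p)}, seed=x, policy=policy)
        except SteadyStateError:
            truncated = True
            break
        states.append(x)
        stabs.append(bool(st))
        rows.append(fam.observables(model, x))
        kept.append(p)
    kept = np.array(kept)
    order = np.argsort(kept)
    obs = pd.DataFrame([rows[i] for i in order])
    obs.insert(0, parameter, kept[order])
    return Branch(
        parameter=parameter,
        values=kept[order],
        states=[states[i] for i in order],
        stable=[stabs[i] for i in order],
        observables=obs,
        direction=direction,
        truncated=truncated,
    )


def _bistable_at(fam, parameter, p, lo_seed, hi_seed, gap_tol):
    """Do the two seeds relax to distinct states at parameter value p?"""
    try:
        m1, x1, _ = fam.solve({parameter: float(p)}, seed=lo_seed)
        m2, x2, _ = fam.solve({parameter: float(p)}, seed=hi_seed)
    except SteadyStateError:
        return False, None, None
    gap = abs(fam.observable(m2, x2) - fam.observable(m1, x1))
    return gap > gap_tol, x1, x2


def bistable_interval(
    config_or_family,
    parameter: str,
    prange,
    n: int = 60,
    gap_tol: float = GAP_TOL,
    refine_rel: float = REFINE_REL,
    gap_observable: str | None = None,
):
    """Parameter interval with two distinct direction-dependent stable states.

    Forward and backward sweeps locate the hysteresis region; both endpoints
    (the saddle-node locations) are then refined by bisection to relative
    tolerance ``refine_rel``.  Returns ``(lo, hi)`` or ``None``.
    """
    fam = _family_for(config_or_family, gap_observable)
    lo_p, hi_p = float(prange[0]), float(prange[1])
    values = np.linspace(lo_p, hi_p, n)
    fwd = sweep_branch(fam, parameter, values, "forward")
    bwd = sweep_branch(fam, parameter, values, "backward")
    if len(fwd.values) < len(values) or len(bwd.values) < len(values):
        raise SteadyStateError("sweep truncated; cannot bracket the interval")
    gap = np.array(
        [
            abs(
                bwd.observables[fam.gap_observable].iloc[i]
                - fwd.observables[fam.gap_observable].iloc[i]
            )
            for i in range(len(values))
        ]
    )
    mask = gap > gap_tol
    if not mask.any():
        return None
    idx = np.where(mask)[0]
    i0, i1 = idx[0], idx[-1]

    scale = max(abs(lo_p), abs(hi_p), 1e-6)

    def refine(i_out, i_in):
        """Bisect between a monostable and a bistable grid point."""
        if i_out < 0 or i_out >= len(values):
            return values[i_in]
        a, b = values[i_out], values[i_in]  # a monostable, b bistable
        xa_lo = fwd.states[min(i_out, i_in)]
        xa_hi = bwd.states[max(i_out, i_in)]
        while abs(b - a) > refine_rel * scale:
            mid = 0.5 * (a + b)
            bi, x1, x2 = _bistable_at(fam, parameter, mid, xa_lo, xa_hi, gap_tol)
            if bi:
                b = mid
                xa_lo, xa_hi = x1, x2
            else:
                a = mid
        return 0.5 * (a + b)

    lo = refine(i0 - 1, i0)
    hi = refine(i1 + 1, i1)
    return float(min(lo, hi)), float(max(lo, hi))


# ---------------------------------------------------------------------------
# two-parameter region


def trace_region_boundary(
    config_or_family,
    p1: str,
    p2: str,
    p1_range,
    p2_values,
    n1: int = 41,
    gap_tol: float = GAP_TOL,
    refine_rel: float = REFINE_REL,
    refine_projection: bool = True,
    gap_observable: str | None = None,
) -> BistableRegion:
    """Map the bistable region in the (p1, p2) plane.

    For each value of ``p2`` the bistable interval in ``p1`` is computed;
    the region boundary is the locus of its endpoints (the saddle-node
    curves), and the projection onto ``p2`` gives the global bounds between
    which bistability exists, refined by bisection on ``p2``.
    """
    fam = _family_for(config_or_family, gap_observable)
    p2_values = np.asarray(p2_values, dtype=float)
    if len(p2_values) < 3:
        raise ValueError("need at least 3 values of the second parameter")

    def interval_at(v2):
        if isinstance(fam, ModelFamily):
            sub = ModelFamily(fam.config.updated(p2, float(v2)), fam.gap_observable)
        else:
            sub = type(fam)(fam.f, fam.dfdx, {**fam.base, p2: float(v2)})
            sub.gap_observable = fam.gap_observable
        try:
            return bistable_interval(
                sub, p1, p1_range, n=n1, gap_tol=gap_tol, refine_rel=refine_rel
            )
        except SteadyStateError:
            return None

    rows = []
    for v2 in p2_values:
        iv = interval_at(v2)
        rows.append(
            {
                "p2": v2,
                "bistable": iv is not None,
                "lo": iv[0] if iv else np.nan,
                "hi": iv[1] if iv else np.nan,
            }
        )
    grid = pd.DataFrame(rows)
    boundary = grid[grid["bistable"]][["p2", "lo", "hi"]].reset_index(drop=True)

    if not grid["bistable"].any():
        return BistableRegion(p1, p2, boundary, grid, (np.nan, np.nan))

    bist_vals = grid[grid["bistable"]]["p2"].to_numpy()
    lo2, hi2 = bist_vals.min(), bist_vals.max()
    if refine_projection:
        scale2 = max(abs(p2_values).max(), 1e-9)

        def bisect_edge(inside, outside):
            a, b = outside, inside  # a no-bistability, b bistable
            while abs(b - a) > max(refine_rel, 1e-3) * scale2:
                mid = 0.5 * (a + b)
                if interval_at(mid) is not None:
                    b = mid
                else:
                    a = mid
            return b

        below = p2_values[p2_values < lo2]
        above = p2_values[p2_values > hi2]
        if below.size:
            lo2 = bisect_edge(lo2, below.max())
        if above.size:
            hi2 = bisect_edge(hi2, above.min())
    return BistableRegion(p1, p2, boundary, grid, (float(lo2), float(hi2)))
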