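"""Continuation, fold detection and the two-parameter region machinery."""

import numpy as np
import pytest

from plecswitch.bifurcation import (
    ScalarODEFamily,
    bistable_interval,
    cubic_fold_family,
    cusp_family,
    sweep_branch,
    trace_region_boundary,
)
from plecswitch.dynamics import ModelConfig

FOLD = 2.0 / (3.0 * np.sqrt(3.0))


class TestNormalForms:
    def test_cubic_fold_locations(self):
        iv = bistable_interval(cubic_fold_family(), "mu", (-1.0, 1.0), n=80)
        assert iv is not None
        lo, hi = iv
        assert lo == pytest.approx(-FOLD, abs=1e-4)
        assert hi == pytest.approx(FOLD, abs=1e-4)

    def test_cubic_hysteresis_direction_dependence(self):
        fam = cubic_fold_family()
        values = np.linspace(-1.0, 1.0, 41)
        fwd = sweep_branch(fam, "mu", values, "forward")
        bwd = sweep_branch(fam, "mu", values, "backward")
        inside = np.abs(values) < FOLD - 0.05
        outside = np.abs(values) > FOLD + 0.05
        gap = np.abs(bwd.trace("x") - fwd.trace("x"))
        assert np.all(gap[inside] > 1.0)
        assert np.all(gap[outside] < 1e-6)

    def test_cusp_boundary_relation(self):
        region = trace_region_boundary(
            cusp_family(),
            "a",
            "b",
            (-1.5, 1.5),
            np.linspace(0.2, 2.0, 10),
            n1=61,
            refine_projection=False,
        )
        assert not region.empty
        for _, row in region.boundary.iterrows():
            b = row["p2"]
            for a in (row["lo"], row["hi"]):
                assert 4 * b**3 == pytest.approx(27 * a**2, rel=1e-3, abs=1e-3)

    def test_linear_decay_has_no_bistability(self):
        fam = ScalarODEFamily(
            f=lambda x, p: p["mu"] - x,
            dfdx=lambda x, p: -1.0,
            base_params={"mu": 0.0},
        )
        assert bistable_interval(fam, "mu", (0.0, 2.0), n=20) is None

    def test_cusp_region_vanishes_below_the_cusp_point(self):
        fam = cusp_family()
        assert bistable_interval(
            type(fam)(fam.f, fam.dfdx, {"a": 0.0, "b": -0.5}), "a", (-1.0, 1.0),
            n=40,
        ) is None


class TestModelSweeps:
    def test_kinase_branch_monotone_in_divj(self, fast_config):
        values = np.linspace(0.0, 1.0, 26)
        br = sweep_branch(fast_config, "DivJ_tot", values, "forward")
        kin = br.trace("pleC_kinase_fraction")
        assert np.all(np.diff(kin) > -1e-6)

    def test_branch_states_satisfy_steady_state_tolerance(self, fast_config):
        from plecswitch.dynamics import Model

        values = np.linspace(0.0, 0.6, 13)
        br = sweep_branch(fast_config, "DivJ_tot", values, "forward")
        for p, x in zip(br.values, br.states):
            model = Model(fast_config.updated("DivJ_tot", p))
            assert np.abs(model.f(x)).max() < fast_config.ss_tol * 10

    def test_baseline_interval_nonempty_and_refined(self, fast_config):
        iv = bistable_interval(fast_config, "DivJ_tot", (0.0, 0.6), n=41)
        assert iv is not None
        lo, hi = iv
        assert 0.0 < lo < hi < 0.6

    def test_sweeps_agree_outside_the_interval(self, fast_config):
        values = np.array([0.0, 0.05, 0.5, 0.6])
        fwd = sweep_branch(fast_config, "DivJ_tot", values, "forward")
        bwd = sweep_branch(fast_config, "DivJ_tot", values, "backward")
        gap = np.abs(
            bwd.trace("pleC_kinase_fraction") - fwd.trace("pleC_kinase_fraction")
        )
        assert np.all(gap < 1e-6)
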