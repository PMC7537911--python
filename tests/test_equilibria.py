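"""Fixed points, stability classes, loci and the period estimator."""

import numpy as np
import pytest

from caosc import (CONTROL, classify_sustained, equilibrium_residual,
                   estimate_period, find_fixed_points, find_fold, find_hopf,
                   generate_fixture, integrate, sweep_diagram)


class TestFixedPoints:
    def test_trivial_root_at_any_load(self):
        for cT in (5.0, 32.0, 54.0, 120.0):
            assert equilibrium_residual(0.0, cT) == 0.0

    @pytest.mark.parametrize("cT,n", [(32.0, 1), (54.0, 3), (75.0, 3)])
    def test_root_counts(self, cT, n):
        assert len(find_fixed_points(cT)) == n

    def test_lower_branch_always_stable(self):
        for cT in (20.0, 32.0, 45.0, 54.0, 66.0, 75.0, 100.0):
            low = find_fixed_points(cT)[0]
            assert low.branch == "lower" and low.is_stable

    def test_mid_load_extra_points_unstable(self):
        fps = find_fixed_points(54.0)
        assert [f.branch for f in fps] == ["lower", "intermediate", "upper"]
        assert not fps[1].is_stable and not fps[2].is_stable

    def test_high_load_upper_stable(self):
        fps = find_fixed_points(75.0)
        assert fps[2].branch == "upper" and fps[2].is_stable

    def test_residuals_tight(self):
        for fp in find_fixed_points(54.0)[1:]:
            assert abs(equilibrium_residual(fp.c_i, 54.0)) < 1e-9

    def test_class_consistent_with_eigenvalues(self):
        for cT in (54.0, 75.0):
            for fp in find_fixed_points(cT):
                if fp.is_stable:
                    assert fp.eigenvalues.real.max() < 0
                else:
                    assert fp.eigenvalues.real.max() > 0

    def test_stability_predicts_local_dynamics(self):
        """A small perturbation decays iff the point is classified stable."""
        for cT in (75.0, 54.0):
            up = find_fixed_points(cT)[-1]
            y0 = (up.c_d * 1.01, up.c_sr_tot)
            tr = integrate("fast_ryr", cT, t_end_ms=300.0, y0=y0,
                           sample_ms=0.5)
            final_dev = abs(tr.c_d[-1] - up.c_d) / max(up.c_d, 1e-9)
            if up.is_stable:
                assert final_dev < 0.01
            else:
                assert final_dev > 0.02

    def test_five_point_window_with_csq(self):
        p = CONTROL.replace(B_SQ=5000.0)
        counts = [len(find_fixed_points(cT, p)) for cT in np.arange(87, 95, 0.5)]
        assert max(counts) == 5

    def test_zero_load_single_trivial_point(self):
        fps = find_fixed_points(0.0)
        assert len(fps) == 1 and fps[0].c_i == 0.0


class TestLoci:
    def test_fold_bisection_refines(self):
        fold = find_fold(CONTROL, tol=0.02)
        assert len(find_fixed_points(fold + 0.1)) == 3
        assert len(find_fixed_points(fold - 0.1)) == 1

    def test_hopf_absent_at_high_csq(self):
        """With heavy calsequestrin the upper branch is born stable: the
        stabilisation happens at a saddle-node, not a Hopf."""
        assert find_hopf(CONTROL.replace(B_SQ=5000.0)) is None

    def test_hopf_sign_change_on_upper_branch(self):
        hopf = find_hopf(CONTROL)
        up = find_fixed_points(hopf + 0.5)[-1]
        dn = find_fixed_points(hopf - 0.5)[-1]
        assert up.is_stable and not dn.is_stable


class TestPeriodEstimation:
    @pytest.mark.parametrize("kind,period,tol", [
        ("sinusoid", 1000.0, 1.0),
        ("relaxation", 700.0, 2.0),
    ])
    def test_known_period_recovered(self, kind, period, tol):
        tr = generate_fixture(kind, {"period_ms": period})
        assert estimate_period(tr, transient_ms=2000.0) == pytest.approx(period, abs=tol)

    def test_constant_trace_is_not_oscillatory(self):
        tr = generate_fixture("constant")
        assert estimate_period(tr, transient_ms=2000.0) is None
        assert not classify_sustained(tr, transient_ms=2000.0)

    def test_noisy_oscillation_within_5_percent(self):
        tr = generate_fixture("noisy_oscillation",
                              {"period_ms": 800.0, "cv": 0.1}, seed=12)
        est = estimate_period(tr, transient_ms=2000.0)
        assert est == pytest.approx(800.0, rel=0.05)

    def test_too_short_trace_reported(self, oscillating_trace):
        with pytest.raises(ValueError):
            estimate_period(oscillating_trace.window(0.0, 100.0),
                            transient_ms=2000.0)

    def test_sinusoid_classified_sustained(self):
        tr = generate_fixture("sinusoid", {"period_ms": 1000.0})
        assert classify_sustained(tr, transient_ms=2000.0)


class TestSweep:
    def test_diagram_structure(self):
        grid = np.array([36.0, 44.0, 54.0, 64.0, 72.0])
        diag = sweep_diagram(grid, refine_loci=False)
        per_load = diag.fixed_points.groupby("load").size()
        assert per_load[36.0] == 1 and per_load[54.0] == 3
        cyc = diag.cycles.set_index("load")
        assert bool(cyc.loc[54.0, "oscillating"])
        assert bool(cyc.loc[64.0, "oscillating"])
        assert not bool(cyc.loc[44.0, "oscillating"])
        assert not bool(cyc.loc[72.0, "oscillating"])
        # cycle extent brackets the unstable upper point at 54
        up = find_fixed_points(54.0)[-1]
        assert cyc.loc[54.0, "cycle_min"] < up.c_i < cyc.loc[54.0, "cycle_max"]

    def test_monotone_grid_required(self):
        with pytest.raises(ValueError):
            sweep_diagram(np.array([50.0, 40.0]))
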