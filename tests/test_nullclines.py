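"""Nullcline geometry, pinch-off detection and the closed-form onset."""

import numpy as np
import pytest

from caosc import (CONTROL, cd_nullcline_branch_count, compute_nullclines,
                   find_fixed_points, jacobian_sign_report, onset_analytic,
                   onset_vs_buffers, pinch_off_load,
                   po_nullcline_branch_count)
from caosc.nullclines_analytics import alpha_residual, beta_residual


class TestBranchCounting:
    def test_connected_below_split_above(self):
        assert cd_nullcline_branch_count(45.0, CONTROL, 200, 600) == 1
        assert cd_nullcline_branch_count(55.0, CONTROL, 200, 600) == 2

    def test_fast_dyadic_plane_splits_too(self):
        assert po_nullcline_branch_count(49.0, CONTROL, 100, 400) == 1
        assert po_nullcline_branch_count(52.0, CONTROL, 100, 400) == 2

    def test_pinch_off_invariant_to_serca_strength(self):
        """The ċ_d = 0 curve contains no uptake term, so the pinch-off
        load must not move when g_up changes by ±50%."""
        base = pinch_off_load(CONTROL, n_csr=150, tol=0.1)
        for fac in (0.5, 1.5):
            p = CONTROL.replace(g_up=CONTROL.g_up * fac)
            assert abs(pinch_off_load(p, n_csr=150, tol=0.1) - base) <= 0.2


@pytest.fixture(scope="module")
def ns54():
    return compute_nullclines(54.0, CONTROL, n_csr=150, n_cd=400)


class TestNullclineSets:
    def test_points_satisfy_defining_equations(self, ns54):
        for cd, csr in ns54.alpha_points[::25]:
            assert abs(alpha_residual(cd, csr, 54.0)) < 1e-8 * max(1.0, cd)
        for cd, csr in ns54.beta_points[::25]:
            assert abs(beta_residual(cd, csr, 54.0)) < 1e-8 * max(1.0, cd)

    def test_branch_count_reported(self, ns54):
        assert ns54.alpha_branch_count == 2   # 54 uM is above the pinch-off

    def test_intersections_are_the_fixed_points(self, ns54):
        fps = find_fixed_points(54.0)
        nontrivial = [(fp.c_d, fp.c_sr) for fp in fps[1:]]
        assert len(ns54.intersections) >= len(nontrivial)
        for cd0, csr0 in nontrivial:
            d = min(abs(cd - cd0) + abs(csr - csr0) / 1e3
                    for cd, csr in ns54.intersections)
            assert d < 1e-6 * max(1.0, cd0)


class TestAnalyticOnset:
    def test_onset_satisfies_its_defining_conditions(self):
        """Independent check: at c̄_T* the quadratic for the critical SR
        level has zero discriminant, and c_sr* is its double root."""
        p = CONTROL
        res = onset_analytic(p)
        gt, v = p.g_tilde, p.v
        ct, csr = res.ct_star, res.csr_star
        b = (p.v_sr - 4.0 * gt * p.K_b * v * ct) / (4.0 * gt * p.K_b * p.v_sr)
        c = (p.v_i * p.B_b - v * ct) / (4.0 * gt * p.K_b * p.v_sr)
        assert b * b - 4.0 * c == pytest.approx(0.0, abs=1e-6 * max(1.0, b * b))
        assert csr == pytest.approx(-b / 2.0, rel=1e-9)

    def test_onset_monotone_increasing_in_Bb(self):
        cts = [onset_analytic(CONTROL.replace(B_b=b)).ct_star
               for b in (40.0, 80.0, 160.0, 320.0)]
        assert np.all(np.diff(cts) > 0)

    def test_onset_direction_in_Kb_at_control(self):
        # near control the closed form *decreases* with K_b: stronger
        # binding (lower K_b) raises the onset load
        lo = onset_analytic(CONTROL.replace(K_b=0.25)).ct_star
        hi = onset_analytic(CONTROL.replace(K_b=1.0)).ct_star
        ct = onset_analytic(CONTROL).ct_star
        assert lo > ct > hi

    def test_no_onset_when_buffer_vanishes(self):
        res = onset_analytic(CONTROL.replace(B_b=0.05))
        assert not res.has_onset and res.ct_star is None

    def test_buffer_scan_passes_through_control(self):
        df = onset_vs_buffers(CONTROL, bb_values=[40.0, 80.0, 160.0])
        ctrl = df[(df.parameter == "B_b") & (df.value == 80.0)].ct_star.iloc[0]
        assert ctrl == pytest.approx(onset_analytic(CONTROL).ct_star, rel=1e-12)
        doubled = df[(df.parameter == "B_b") & (df.value == 160.0)].ct_star.iloc[0]
        assert doubled > ctrl


class TestSignReport:
    def test_high_load_signs_force_stability(self):
        up = find_fixed_points(75.0)[-1]
        rep = jacobian_sign_report(up)
        assert rep.f1 < 0 and rep.g2 < 0 and rep.verdict == "stable"

    def test_mid_load_signs_indeterminate(self):
        up = find_fixed_points(54.0)[-1]
        rep = jacobian_sign_report(up)
        assert rep.f1 > 0 and rep.g2 < 0 and rep.verdict == "indeterminate"

    def test_determinable_verdicts_agree_with_eigenvalues(self):
        for cT in (45.0, 54.0, 62.0, 75.0, 90.0):
            for fp in find_fixed_points(cT):
                rep = jacobian_sign_report(fp)
                if rep.verdict == "stable":
                    assert fp.is_stable
                elif rep.verdict in ("unstable", "saddle"):
                    assert not fp.is_stable

    def test_three_var_rejected(self):
        fp = find_fixed_points(54.0, variant="three_var")[0]
        with pytest.raises(ValueError):
            jacobian_sign_report(fp)
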