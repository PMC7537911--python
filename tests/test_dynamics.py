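"""Right-hand sides, integration, and the stochastic gating model."""

import numpy as np
import pytest

from caosc import (CONTROL, initial_state, integrate, rhs_fast_dyadic,
                   rhs_fast_ryr, rhs_three_var, ryr_open_probability,
                   slaved_dyadic_calcium, solve_cytosolic, stochastic_po,
                   reconstruct_load)
from caosc.dynamics import VARIANTS


def random_feasible_states(n, cT, p, rng):
    out = []
    for _ in range(n):
        c_sr_tot = rng.uniform(0.2, 0.98) * p.v * cT / p.v_sr
        budget = p.v * cT - p.v_sr * c_sr_tot
        c_d = rng.uniform(0.0, 0.3) * budget / p.v_d
        out.append((c_d, c_sr_tot))
    return out


class TestRightHandSides:
    def test_rest_state_is_equilibrium(self):
        p = CONTROL
        rest3 = (0.0, p.v * 54.0 / p.v_sr, 0.0)
        assert rhs_three_var(rest3, 54.0, p) == pytest.approx((0, 0, 0), abs=1e-14)
        assert rhs_fast_ryr(rest3[:2], 54.0, p) == pytest.approx((0, 0), abs=1e-14)

    def test_no_fluxes_leaves_pure_dyadic_relaxation(self):
        p = CONTROL.replace(g=0.0, g_up=0.0)
        c_d, c_sr_tot = 3.0, 1500.0
        ci = solve_cytosolic(54.0, c_d, c_sr_tot, p)
        dcd, dcsr = rhs_fast_ryr((c_d, c_sr_tot), 54.0, p)
        assert dcsr == 0.0
        assert dcd == pytest.approx(-(c_d - ci) / p.tau_i, rel=1e-12)

    def test_fast_ryr_is_three_var_with_slaved_gating(self, rng):
        """Projecting the full model onto P_o = c_d²/(K_o²+c_d²) must
        reproduce the reduced right-hand side exactly."""
        p = CONTROL
        for c_d, c_sr_tot in random_feasible_states(5, 54.0, p, rng):
            po = float(ryr_open_probability(c_d, p))
            full = rhs_three_var((c_d, c_sr_tot, po), 54.0, p)
            red = rhs_fast_ryr((c_d, c_sr_tot), 54.0, p)
            assert full[:2] == pytest.approx(red, rel=1e-12)

    def test_half_activation_at_K_o(self):
        p = CONTROL
        c_d, c_sr_tot = p.K_o, 1500.0
        ci = solve_cytosolic(54.0, c_d, c_sr_tot, p)
        dcd, _ = rhs_fast_ryr((c_d, c_sr_tot), 54.0, p)
        release = dcd + (c_d - ci) / p.tau_i
        assert release == pytest.approx(0.5 * p.g * (c_sr_tot - c_d), rel=1e-12)

    def test_fast_dyadic_closed_ryr_limit(self):
        """With P_o = 0 the dyad equilibrates with the cytosol and the
        opening rate is the pure activation term."""
        p = CONTROL
        c_d, c_i = slaved_dyadic_calcium(0.0, 1500.0, 54.0, p)
        assert c_d == pytest.approx(c_i, rel=1e-10)
        _, dpo = rhs_fast_dyadic((1500.0, 0.0), 54.0, p)
        assert dpo == pytest.approx(p.k_p * c_d * c_d, rel=1e-10)

    def test_fast_dyadic_equal_concentrations_fixed(self):
        # when c_i = c_sr the slaving gives c_d = c_i for any P_o
        p = CONTROL
        level = 0.3
        cT = reconstruct_load(level, level, level, p)
        for po in (0.0, 0.3, 1.0):
            c_d, c_i = slaved_dyadic_calcium(po, level, cT, p)
            assert c_d == pytest.approx(c_i, rel=1e-9)

    def test_fast_dyadic_requires_no_csq(self):
        p = CONTROL.replace(B_SQ=1000.0)
        with pytest.raises(Exception):
            rhs_fast_dyadic((1500.0, 0.1), 54.0, p)


class TestStochasticGating:
    def test_sigma_zero_is_deterministic(self, rng):
        assert stochastic_po(3.0, 0.0, rng) == ryr_open_probability(3.0)

    def test_uniform_noise_moments(self):
        rng = np.random.default_rng(7)
        sigma = 0.1
        draws = np.array([stochastic_po(15.0, sigma, rng) for _ in range(20000)])
        det = float(ryr_open_probability(15.0))
        assert draws.mean() == pytest.approx(det, abs=3e-3)
        assert draws.std() == pytest.approx(sigma / np.sqrt(12.0), rel=0.05)
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_clamped_to_unit_interval(self):
        rng = np.random.default_rng(1)
        draws = [stochastic_po(0.0, 2.0, rng) for _ in range(500)]
        assert min(draws) >= 0.0 and max(draws) <= 1.0


class TestIntegration:
    @pytest.mark.parametrize("cT,regime", [
        (32.0, "rest"), (54.0, "oscillation"), (75.0, "upper")])
    def test_load_selects_regime(self, cT, regime):
        """Low load decays to the excitable rest state, intermediate load
        sustains an oscillation, high load settles on the open-RyR
        depleted-SR state."""
        from caosc import classify_sustained, find_fixed_points
        tr = integrate("fast_ryr", cT, t_end_ms=4000.0, kick=5.0,
                       sample_ms=0.25)
        tail = tr.window(3500.0)
        if regime == "rest":
            assert not classify_sustained(tr)
            assert tail.c_i.max() < 0.05
        elif regime == "oscillation":
            assert classify_sustained(tr)
        else:
            assert not classify_sustained(tr)
            upper = find_fixed_points(cT)[-1]
            assert tail.c_i.mean() == pytest.approx(upper.c_i, rel=1e-3)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_mass_conserved_along_trajectories(self, variant):
        tr = integrate(variant, 52.0, t_end_ms=2000.0, kick=5.0)
        if variant == "fast_dyadic":
            # the slaving transiently overfills the dyad at spike take-off;
            # the violation is bounded by ~v_d/v_sr of the load
            assert tr.mass_drift() < 1e-2
        else:
            assert tr.mass_drift() < 1e-8

    def test_stochastic_mass_conserved(self):
        tr = integrate("fast_ryr", 35.0, t_end_ms=30000.0, sigma=2e-3, seed=5)
        assert tr.mass_drift() < 1e-8

    def test_sigma_zero_euler_equals_deterministic_euler(self):
        a = integrate("fast_ryr", 54.0, t_end_ms=500.0, sigma=0.0,
                      method="euler", kick=5.0, seed=11)
        b = integrate("fast_ryr", 54.0, t_end_ms=500.0, sigma=0.0,
                      method="euler", kick=5.0, seed=999)
        assert np.array_equal(a.c_i, b.c_i)
        assert np.array_equal(a.c_sr_tot, b.c_sr_tot)

    def test_stochastic_run_reproducible_from_seed(self):
        a = integrate("fast_ryr", 40.0, t_end_ms=2000.0, sigma=2e-3, seed=3)
        b = integrate("fast_ryr", 40.0, t_end_ms=2000.0, sigma=2e-3, seed=3)
        assert np.array_equal(a.c_i, b.c_i)

    def test_tolerance_refinement_converged(self):
        """Halving the adaptive tolerances leaves the final state
        unchanged to well below the requested accuracy."""
        kw = dict(t_end_ms=2000.0, kick=5.0, sample_ms=1.0)
        a = integrate("fast_ryr", 75.0, rtol=1e-8, atol=1e-10, **kw)
        b = integrate("fast_ryr", 75.0, rtol=5e-9, atol=5e-11, **kw)
        assert abs(a.c_i[-1] - b.c_i[-1]) / a.c_i[-1] < 1e-6
        assert abs(a.c_sr_tot[-1] - b.c_sr_tot[-1]) / a.c_sr_tot[-1] < 1e-6

    def test_initial_state_mass_consistent(self):
        for variant in VARIANTS:
            y0 = initial_state(variant, 54.0, kick=2.0)
            assert len(y0) == (3 if variant == "three_var" else 2)
        cd, csrtot = initial_state("fast_ryr", 54.0, kick=2.0)
        ci = solve_cytosolic(54.0, cd, csrtot)
        assert reconstruct_load(ci, cd, csrtot) == pytest.approx(54.0, rel=1e-12)

    def test_times_strictly_increasing(self, oscillating_trace):
        assert np.all(np.diff(oscillating_trace.t_ms) > 0)

    def test_three_var_oscillates_in_its_window(self):
        from caosc import classify_sustained
        tr = integrate("three_var", 52.0, t_end_ms=4000.0, kick=5.0)
        assert classify_sustained(tr)
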