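"""Steady states, response surfaces, and CTO of the 2-compartment circuit."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import root

from dendsum.two_compartment import (
    TwoCompParams,
    compute_cto,
    fit_output_scale,
    response_surface,
    solve_steady_state,
)

P = TwoCompParams()


def kcl_residuals(p, v_p, v_d, n_p, n_d):
    r_d = (p.g_leak_dist * (v_d - p.e_rest) + p.g_axial * (v_d - v_p)
           - n_d * p.g_nmda_unit * p.b(v_d) * (p.e_syn - v_d))
    r_p = (p.g_leak_prox * (v_p - p.e_rest) + p.g_axial * (v_p - v_d)
           - n_p * p.g_nmda_unit * p.b(v_p) * (p.e_syn - v_p))
    return r_p, r_d


class TestSolve:
    def test_no_drive_rests_at_leak(self):
        ss = solve_steady_state(P, 0, 0)
        assert ss.v_prox == pytest.approx(-70.0, abs=1e-9)
        assert ss.v_dist == pytest.approx(-70.0, abs=1e-9)

    @pytest.mark.parametrize("n_p,n_d", [(0, 5), (5, 0), (10, 10), (40, 40),
                                         (3, 27), (17, 8)])
    def test_kcl_residuals_below_tolerance(self, n_p, n_d):
        ss = solve_steady_state(P, n_p, n_d)
        for (vp, vd) in ss.all_roots:
            r_p, r_d = kcl_residuals(P, vp, vd, n_p, n_d)
            assert abs(r_p) < 1e-9 and abs(r_d) < 1e-9

    def test_matches_damped_newton_oracle_from_random_starts(self):
        """The 1-D reduction equals an independent 2-D solve."""
        rng = np.random.default_rng(5)
        for n_p, n_d in [(4, 12), (25, 3), (40, 40), (12, 30)]:
            ss = solve_steady_state(P, n_p, n_d)
            best = None
            for _ in range(100):
                x0 = rng.uniform(-71.0, 1.0, 2)
                sol = root(lambda x: kcl_residuals(P, x[0], x[1], n_p, n_d),
                           x0, tol=1e-13)
                if sol.success and max(abs(np.array(
                        kcl_residuals(P, *sol.x, n_p, n_d)))) < 1e-9:
                    if best is None or sol.x[1] < best[1]:
                        best = sol.x
            assert best is not None
            assert best[0] == pytest.approx(ss.v_prox, abs=1e-6)
            assert best[1] == pytest.approx(ss.v_dist, abs=1e-6)

    def test_large_axial_conductance_collapses_compartments(self):
        p = TwoCompParams(g_axial=1e6)
        ss = solve_steady_state(p, 10, 10)
        assert abs(ss.v_prox - ss.v_dist) < 1e-3

    def test_dynamic_relaxation_reaches_steady_state(self):
        """A capacitive ODE version of the circuit settles onto the solver's
        rest-connected root from rest."""
        n_p, n_d = 20, 15

        def rhs(_, x):
            r_p, r_d = kcl_residuals(P, x[0], x[1], n_p, n_d)
            return [-r_p, -r_d]

        sol = solve_ivp(rhs, (0.0, 2000.0), [P.e_rest, P.e_rest],
                        rtol=1e-10, atol=1e-10)
        ss = solve_steady_state(P, n_p, n_d)
        assert sol.y[0, -1] == pytest.approx(ss.v_prox, abs=1e-5)
        assert sol.y[1, -1] == pytest.approx(ss.v_dist, abs=1e-5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            solve_steady_state(P, -1, 0)


class TestSurface:
    def test_origin_is_zero(self, twocomp_surface):
        assert twocomp_surface[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_both_counts(self, twocomp_surface):
        assert np.all(np.diff(twocomp_surface, axis=0) >= -1e-9)
        assert np.all(np.diff(twocomp_surface, axis=1) >= -1e-9)

    def test_distal_marginal_saturates_lower(self, twocomp_surface):
        assert twocomp_surface[0, :].max() < twocomp_surface[:, 0].max()

    def test_rest_connected_branch_continuous_along_rows(self, twocomp_surface):
        # no pathological jumps except the single local-spike upturn per row
        jumps = np.abs(np.diff(twocomp_surface, axis=1))
        assert np.all((jumps < 1e-9) | (jumps < 60.0))


class TestOutputScale:
    def test_scales_peak_to_target(self, twocomp_surface):
        s = fit_output_scale(twocomp_surface, 15.2)
        assert (twocomp_surface * s).max() == pytest.approx(15.2, rel=1e-12)

    def test_identity_when_target_is_current_max(self, twocomp_surface):
        assert fit_output_scale(
            twocomp_surface, twocomp_surface.max()) == pytest.approx(1.0)

    def test_linearity_in_target(self, twocomp_surface):
        assert fit_output_scale(twocomp_surface, 30.4) == pytest.approx(
            2 * fit_output_scale(twocomp_surface, 15.2))

    def test_zero_surface_rejected(self):
        with pytest.raises(ValueError):
            fit_output_scale(np.zeros((3, 3)), 15.2)


class TestCTO:
    def test_zero_at_steady_state(self):
        for n_p, n_d in [(10, 20), (40, 5)]:
            ss = solve_steady_state(P, n_p, n_d)
            cto = compute_cto(P, ss.v_dist, n_d, "dist", n_other=n_p)
            assert cto == pytest.approx(0.0, abs=1e-7)

    def test_positive_at_rest_with_drive(self):
        assert compute_cto(P, P.e_rest, 5, "dist") > 0

    def test_negative_without_drive_when_depolarized(self):
        assert compute_cto(P, -50.0, 0, "dist") < 0

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError):
            compute_cto(P, -50.0, 0, "middle")


class TestAsymmetry:
    def test_distal_driver_gain_dominates(self, twocomp_surface):
        """Proximal modulation boosts the distal-driver curve maximum far
        more than distal modulation boosts the proximal-driver maximum."""
        s = twocomp_surface
        gain_dist_driver = s[-1, :].max() / s[0, :].max() - 1
        gain_prox_driver = s[:, -1].max() / s[:, 0].max() - 1
        assert gain_dist_driver >= 2 * gain_prox_driver
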