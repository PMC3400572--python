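"""Two-input maps, curve families, and within/between-branch interaction."""

import numpy as np
import pytest

from dendsum.curve_stats import IOCurve
from dendsum.summation import (
    TwoInputMap,
    _cluster_sites,
    additivity_deviation,
    categorize_and_average,
    family_max_gain,
    map_two_input,
    ramp_single_site,
    slice_family,
    threshold_indices,
)


class TestMapStructure:
    def test_origin_is_zero(self, two_input_map):
        assert two_input_map.peaks[0, 0] == 0.0

    def test_edges_equal_single_site_ramps(self, cell, two_input_map):
        m = two_input_map
        ramp_p = ramp_single_site(cell, 90.0, m.n_prox[1:],
                                  protocol="double_pulse")
        ramp_d = ramp_single_site(cell, 150.0, m.n_dist[1:],
                                  protocol="double_pulse")
        assert m.peaks[1:, 0] == pytest.approx(ramp_p.y)
        assert m.peaks[0, 1:] == pytest.approx(ramp_d.y)

    def test_overall_peak_at_full_corner(self, two_input_map):
        peaks = two_input_map.peaks
        assert peaks.max() == peaks[-1, -1]

    def test_grid_monotone_within_tolerance(self, two_input_map):
        tol = 0.15  # mV; integration noise near the local-spike jump
        assert np.all(np.diff(two_input_map.peaks, axis=0) > -tol)
        assert np.all(np.diff(two_input_map.peaks, axis=1) > -tol)

    def test_colocalized_map_depends_on_total_count(self, cell):
        """Placing both 'sites' at one location makes (i, j) a function of
        i + j, mirroring the diagonal symmetry of co-localized panels."""
        m = map_two_input(cell, 120.0, 120.0, n_max=8, step=4)
        assert m.peaks[1, 0] == pytest.approx(m.peaks[0, 1], rel=0.02)
        assert m.peaks[2, 0] == pytest.approx(m.peaks[1, 1], rel=0.02)
        assert m.peaks[2, 1] == pytest.approx(m.peaks[1, 2], rel=0.02)


class TestFamilies:
    def test_slice_then_restack_reproduces_matrix(self, two_input_map):
        for driver in ("prox", "dist"):
            fam = slice_family(two_input_map, driver)
            stacked = fam.restack()
            target = (two_input_map.peaks if driver == "dist"
                      else two_input_map.peaks.T)
            assert np.array_equal(stacked, target)

    def test_family_count_and_intercepts(self, two_input_map):
        fam = slice_family(two_input_map, "dist")
        assert len(fam.curves) == len(two_input_map.n_prox)
        assert fam.mod_alone_peaks == pytest.approx(two_input_map.peaks[:, 0])

    def test_zero_modulation_curve_is_single_site_ramp(self, two_input_map):
        fam = slice_family(two_input_map, "dist")
        assert np.array_equal(fam.curves[0].y, two_input_map.peaks[0])


class TestCategorize:
    def _family(self, n_curves, scale=1.0):
        x = np.arange(5.0)
        curves = [IOCurve(x, (k + 1) * scale + x) for k in range(n_curves)]
        return slice_family(TwoInputMap(
            90.0, 150.0, np.arange(n_curves), x,
            np.vstack([c.y for c in curves])), "dist")

    def test_one_curve_per_bin_means_itself(self):
        fam = self._family(4)
        binned = categorize_and_average(fam, n_bins=4)
        assert len(binned.mean_curves) == 4
        for mean_curve in binned.mean_curves:
            member = np.flatnonzero(binned.bin_of_curve == mean_curve.meta["bin"])
            assert len(member) == 1
            assert np.array_equal(mean_curve.y, fam.curves[member[0]].y)

    def test_identical_curves_identical_means(self, two_input_map):
        fam = slice_family(two_input_map, "dist")
        clones = type(fam)(fam.driver, fam.mod_levels,
                           [fam.curves[3]] * 8,
                           np.repeat(fam.mod_alone_peaks[3], 8))
        binned = categorize_and_average(clones, n_bins=4)
        for mc in binned.mean_curves[1:]:
            assert mc.y == pytest.approx(binned.mean_curves[0].y)

    def test_bin_means_ordered_by_modulation_strength(self, two_input_map):
        fam = slice_family(two_input_map, "dist")
        binned = categorize_and_average(fam, n_bins=4)
        mid = len(binned.driver_counts) // 2
        vals = [mc.y[mid] for mc in binned.mean_curves]
        assert np.all(np.diff(vals) >= 0)

    def test_exclusion_ceiling_drops_strongest(self, two_input_map):
        fam = slice_family(two_input_map, "dist")
        ceiling = np.median(fam.mod_alone_peaks)
        binned = categorize_and_average(fam, n_bins=2,
                                        exclusion_ceiling=ceiling)
        excluded = np.flatnonzero(binned.bin_of_curve == -1)
        assert np.all(fam.mod_alone_peaks[excluded] > ceiling)


class TestRegional:
    def test_synapse_count_conserved_across_branches(self, cell):
        for n in (1, 7, 40):
            sites = _cluster_sites(cell, cell.basal_ids[:2], 150.0, n)
            assert len(sites) == n

    def test_single_branch_list_reduces_to_plain_map(self, cell):
        from dendsum.summation import regional_variant

        a = regional_variant(cell, [cell.basal_ids[0]], n_max=6, step=3)
        b = map_two_input(cell, n_max=6, step=3)
        assert a.peaks == pytest.approx(b.peaks)

    def test_regional_distribution_preserves_asymmetry_sign(self, cell):
        from dendsum.summation import regional_variant

        m = regional_variant(cell, cell.basal_ids[:2], n_max=40, step=10)
        fam_d = slice_family(m, "dist")
        fam_p = slice_family(m, "prox")
        assert family_max_gain(fam_d) > family_max_gain(fam_p) > -0.05


class TestAsymmetryAndAdditivity:
    def test_distal_driver_max_gain_dominates(self, two_input_map):
        fam_d = slice_family(two_input_map, "dist")
        fam_p = slice_family(two_input_map, "prox")
        assert family_max_gain(fam_d) >= 2 * family_max_gain(fam_p)

    def test_thresholds_shift_left_with_modulation(self, two_input_map):
        for driver in ("prox", "dist"):
            idx = threshold_indices(slice_family(two_input_map, driver))
            detected = [i for i in idx if i is not None]
            # once the modulation is strong enough no jump remains
            assert idx[:len(detected)] == detected
            assert np.all(np.diff(detected) <= 0)

    def test_between_branch_far_more_additive(self, branch_comparison):
        assert branch_comparison["dev_between"] < branch_comparison["dev_within"]

    def test_additivity_score_invariances(self):
        rng = np.random.default_rng(3)
        r = np.add.outer(rng.uniform(0, 10, 5), rng.uniform(0, 10, 4))
        m = TwoInputMap(90.0, 150.0, np.arange(5), np.arange(4), r)
        assert additivity_deviation(m) == pytest.approx(0.0, abs=1e-12)
        m2 = TwoInputMap(90.0, 150.0, np.arange(5), np.arange(4), r + 7.0)
        assert additivity_deviation(m2) == pytest.approx(0.0, abs=1e-12)
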