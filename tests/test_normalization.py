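"""Fiducial extraction, template scale factors, and cohort recovery."""

import numpy as np
import pandas as pd
import pytest

from dendsum.normalization import (
    TEMPLATE,
    FiducialError,
    FiducialSet,
    X_DIST,
    X_PROX,
    Y,
    apply_scale,
    extract_fiducials,
    fit_scale_factors,
    normalize_cell,
    rigid_scale_orthogonal,
)
from dendsum.synth import SyntheticCohortSpec, generate_cohort


def map_as_table(m) -> pd.DataFrame:
    rows = [{X_DIST: d, X_PROX: q, Y: m.peaks[i, j]}
            for i, q in enumerate(m.n_prox) for j, d in enumerate(m.n_dist)]
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def canonical_table(canonical_map_2c):
    return map_as_table(canonical_map_2c)


@pytest.fixture(scope="module")
def canonical_factors(canonical_table):
    fs = extract_fiducials(canonical_table)
    return fit_scale_factors(fs)


class TestFitScaleFactors:
    def test_template_maps_to_identity(self):
        assert fit_scale_factors(TEMPLATE) == pytest.approx((1.0, 1.0))

    def test_closed_form_inversion(self):
        """x doubled and y halved must be undone by factors (0.5, 2.0)."""
        a = TEMPLATE.as_array()
        warped = FiducialSet(*[(2 * x, 0.5 * y) for x, y in a])
        a_x, a_y = fit_scale_factors(warped)
        assert (a_x, a_y) == pytest.approx((0.5, 2.0), rel=1e-12)

    def test_bruteforce_grid_agrees(self):
        rng = np.random.default_rng(0)
        pts = TEMPLATE.as_array() * rng.uniform(0.5, 2.0, (4, 2))
        pts[1, 0] = pts[2, 0] = 0.0  # square/pentagon stay on the y axis
        f = FiducialSet(*[tuple(p) for p in pts])
        a_x, a_y = fit_scale_factors(f)
        grid = np.linspace(0.1, 5.0, 2001)

        def mse(ax, ay):
            scaled = f.as_array() * [ax, ay]
            return np.mean((scaled - TEMPLATE.as_array()) ** 2)

        gx = grid[np.argmin([mse(g, a_y) for g in grid])]
        gy = grid[np.argmin([mse(a_x, g) for g in grid])]
        assert a_x == pytest.approx(gx, abs=grid[1] - grid[0])
        assert a_y == pytest.approx(gy, abs=grid[1] - grid[0])

    def test_local_optimality(self):
        f = FiducialSet((2.0, 1.5), (0.0, 1.0), (0.0, 4.0), (1.1, 3.5))
        a_x, a_y = fit_scale_factors(f)

        def mse(ax, ay):
            scaled = f.as_array() * [ax, ay]
            return np.mean((scaled - TEMPLATE.as_array()) ** 2)

        best = mse(a_x, a_y)
        for eps in (0.99, 1.01):
            assert mse(a_x * eps, a_y) > best
            assert mse(a_x, a_y * eps) > best

    def test_all_zero_x_rejected(self):
        f = FiducialSet((0.0, 1.0), (0.0, 0.6), (0.0, 2.4), (0.0, 2.2))
        with pytest.raises(FiducialError):
            fit_scale_factors(f)


class TestExtraction:
    def test_circle_threshold_below_triangle(self, canonical_table):
        """A just-subthreshold proximal bias lowers the distal threshold."""
        fs = extract_fiducials(canonical_table)
        assert fs.circle[0] < fs.triangle[0]
        assert fs.pentagon[1] > fs.square[1]

    def test_family_without_spikes_raises(self):
        x = np.arange(0.0, 10.0)
        rows = []
        for q in (0.0, 2.0, 4.0):
            for d in x:
                rows.append({X_DIST: d, X_PROX: q, Y: 0.5 * d + 0.2 * q + 0.1})
        with pytest.raises(FiducialError):
            extract_fiducials(pd.DataFrame(rows))

    def test_template_self_consistency(self, canonical_table,
                                       canonical_factors):
        """Normalizing the canonical table and re-extracting gives fiducials
        that already fit the template with unit factors."""
        a_x, a_y = canonical_factors
        scaled = apply_scale(canonical_table, a_x, a_y)
        fs2 = extract_fiducials(scaled)
        assert fit_scale_factors(fs2) == pytest.approx((1.0, 1.0), abs=1e-9)


class TestRigidScale:
    def test_pentagon_maps_to_target(self, canonical_table):
        scaled, (a_x, a_y) = rigid_scale_orthogonal(canonical_table)
        fs = extract_fiducials(scaled)
        px = getattr(fs, "_pentagon_x")
        assert px == pytest.approx(1.0, abs=1e-12)
        assert fs.pentagon[1] == pytest.approx(2.4, abs=1e-12)

    def test_arithmetic(self):
        # the scale factors are target / pentagon coordinates
        x = np.arange(0.0, 11.0)
        rows = []
        for q in np.arange(0.0, 2.6, 0.5):
            for d in x:
                dist_jump = 2.0 if d >= (3 if q >= 1.5 else 5) else 0.0
                y = 2.0 * q + 0.2 * d + (4.3 if q >= 2.0 else 0.0) + dist_jump
                rows.append({X_DIST: d, X_PROX: q, Y: y + 0.05})
        table = pd.DataFrame(rows)
        fs = extract_fiducials(table)
        px, py = getattr(fs, "_pentagon_x"), fs.pentagon[1]
        assert px > 0 and py > 0
        _, (a_x, a_y) = rigid_scale_orthogonal(table)
        assert a_x == pytest.approx(1.0 / px)
        assert a_y == pytest.approx(2.4 / py)


class TestRecovery:
    def test_zero_noise_recovery_within_point1_percent(self, canonical_map_2c,
                                                       canonical_factors):
        spec = SyntheticCohortSpec(noise_sd_mv=0.0, x_sigma=0.4, y_sigma=0.4,
                                   seed=21)
        cohort = generate_cohort(spec, canonical_map_2c)
        a_x0, a_y0 = canonical_factors
        for c in cohort.cells:
            _, (a_x, a_y), _ = normalize_cell(c.table)
            assert a_x * c.x_scale / a_x0 == pytest.approx(1.0, rel=1e-3)
            assert a_y * c.y_scale / a_y0 == pytest.approx(1.0, rel=1e-3)

    def test_default_noise_recovery_within_5_percent(self, canonical_map_2c,
                                                     canonical_factors):
        spec = SyntheticCohortSpec(seed=22)  # default 0.3 mV noise
        cohort = generate_cohort(spec, canonical_map_2c)
        a_x0, a_y0 = canonical_factors
        for c in cohort.cells:
            _, (a_x, a_y), _ = normalize_cell(c.table)
            assert a_x * c.x_scale / a_x0 == pytest.approx(1.0, rel=0.05)
            assert a_y * c.y_scale / a_y0 == pytest.approx(1.0, rel=0.05)

    def test_idempotence_on_normalized_data(self, canonical_table):
        scaled, (a_x, a_y), _ = normalize_cell(canonical_table)
        _, (b_x, b_y), _ = normalize_cell(scaled)
        assert (b_x, b_y) == pytest.approx((1.0, 1.0), abs=1e-9)
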