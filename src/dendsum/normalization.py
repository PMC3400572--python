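"""Fiducial-point extraction and template normalization of two-input data.

Heterogeneous cells (different electrode placements, stimulation efficacy,
branch input resistances) are brought onto a common scale using four
landmark ("fiducial") points of each cell's two-input response family,
viewed with the distal input as driver and the proximal input as modulator:

* triangle -- just-suprathreshold distal-alone response (x = driver
  intensity at the spike, y = peak mV);
* square   -- just-subthreshold proximal-alone peak (x = 0);
* pentagon -- just-suprathreshold proximal-alone peak (x = 0);
* circle   -- just-suprathreshold distal response under a simultaneous
  just-subthreshold proximal bias.

A fixed template -- triangle (1, 1), square (0, 0.6), pentagon (0, 2.4),
circle (0.6, 2.2) -- encodes the average ratios observed across cells. For
each cell, one horizontal and one vertical scale factor are chosen to
minimize the mean squared error between the scaled fiducials and the
template (a separable least-squares problem with a closed form); those two
factors alone then rescale the cell's entire data set, so the landmark fit
cannot overfit the full curves.

The orthogonal view (proximal driver, distal modulator) is more uniform
across cells and is rigidly scaled by a single landmark: the pentagon
(carrying its driver intensity) is placed at (1, 2.4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_stats import IOCurve, detect_threshold

__all__ = [
    "FiducialSet",
    "TEMPLATE",
    "FiducialError",
    "extract_fiducials",
    "fit_scale_factors",
    "apply_scale",
    "rigid_scale_orthogonal",
    "normalize_cell",
]

X_DIST, X_PROX, Y = "x_dist", "x_prox", "y_mv"  # canonical CSV columns


class FiducialError(RuntimeError):
    """A required fiducial point could not be extracted."""


@dataclass(frozen=True)
class FiducialSet:
    triangle: tuple[float, float]
    square: tuple[float, float]
    pentagon: tuple[float, float]
    circle: tuple[float, float]

    def __post_init__(self):
        if not self.pentagon[1] > self.square[1]:
            raise FiducialError(
                "just-suprathreshold proximal peak must exceed the "
                "just-subthreshold one")

    def as_array(self) -> np.ndarray:
        return np.array([self.triangle, self.square, self.pentagon, self.circle])


TEMPLATE = FiducialSet(triangle=(1.0, 1.0), square=(0.0, 0.6),
                       pentagon=(0.0, 2.4), circle=(0.6, 2.2))


def _level_curve(table: pd.DataFrame, fixed_col: str, level: float,
                 var_col: str, drop_zero: bool = False) -> IOCurve:
    rows = table[np.isclose(table[fixed_col], level)].sort_values(var_col)
    if drop_zero:
        # the measured zero-stimulus sample is noise around zero; the
        # origin-anchored NRLE fit supplies the exact (0, 0) point instead
        rows = rows[rows[var_col] > 0]
    if len(rows) < 3:
        raise FiducialError(
            f"no usable curve at {fixed_col} = {level} (only {len(rows)} points)")
    return IOCurve(rows[var_col].to_numpy(), rows[Y].to_numpy())


def extract_fiducials(table: pd.DataFrame,
                      criterion: float = 1.3) -> FiducialSet:
    """Landmark points of one cell's two-input table.

    ``table`` columns: ``x_dist`` (distal driver intensity), ``x_prox``
    (proximal modulation intensity), ``y_mv`` (peak somatic response). The
    proximal-alone curve provides the square and pentagon; the distal-alone
    curve the triangle; the distal curve at the just-subthreshold proximal
    bias provides the circle.
    """
    prox = _level_curve(table, X_DIST, 0.0, X_PROX, drop_zero=True)
    th = detect_threshold(prox, criterion=criterion)
    if th is None:
        raise FiducialError("square/pentagon: no proximal-alone local spike")
    sub, supra = th
    square = (0.0, float(prox.y[sub]))
    pentagon = (0.0, float(prox.y[supra]))
    prox_sub_level = float(prox.x[sub])
    pentagon_x = float(prox.x[supra])  # used by the rigid orthogonal scaling

    dist = _level_curve(table, X_PROX, 0.0, X_DIST, drop_zero=True)
    th = detect_threshold(dist, criterion=criterion)
    if th is None:
        raise FiducialError("triangle: no distal-alone local spike")
    triangle = (float(dist.x[th[1]]), float(dist.y[th[1]]))

    biased = _level_curve(table, X_PROX, prox_sub_level, X_DIST)
    th = detect_threshold(biased, criterion=criterion)
    if th is None:
        raise FiducialError("circle: no local spike on the proximally "
                            "biased distal curve")
    circle = (float(biased.x[th[1]]), float(biased.y[th[1]]))

    fs = FiducialSet(triangle, square, pentagon, circle)
    object.__setattr__(fs, "_pentagon_x", pentagon_x)
    return fs


def fit_scale_factors(f: FiducialSet,
                      t: FiducialSet = TEMPLATE) -> tuple[float, float]:
    """Separable least-squares scale factors onto the template.

    Minimizing ``sum_i (a_x x_i - tx_i)^2 + (a_y y_i - ty_i)^2`` over the
    four fiducials gives ``a_x = sum(x_i tx_i) / sum(x_i^2)`` over the
    points with nonzero x (triangle and circle) and the analogous ``a_y``
    over all four points.
    """
    a = f.as_array()
    ta = t.as_array()
    x, tx = a[:, 0], ta[:, 0]
    y, ty = a[:, 1], ta[:, 1]
    nz = x != 0
    if not nz.any():
        raise FiducialError("all fiducial x-coordinates are zero; horizontal "
                            "scale undefined")
    a_x = float(np.sum(x[nz] * tx[nz]) / np.sum(x[nz] ** 2))
    a_y = float(np.sum(y * ty) / np.sum(y ** 2))
    return a_x, a_y


def apply_scale(table: pd.DataFrame, a_x: float, a_y: float) -> pd.DataFrame:
    """Scale both intensity axes by ``a_x`` and the response by ``a_y``."""
    out = table.copy()
    out[X_DIST] = out[X_DIST] * a_x
    out[X_PROX] = out[X_PROX] * a_x
    out[Y] = out[Y] * a_y
    return out


def rigid_scale_orthogonal(table: pd.DataFrame,
                           target: tuple[float, float] = (1.0, 2.4),
                           criterion: float = 1.3
                           ) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Scale a cell so its pentagon (with driver x) lands on ``target``.

    In the proximal-driver view the pentagon carries the proximal driver
    intensity of the just-suprathreshold point; a single pair of factors
    maps it exactly onto the target and rescales the whole table.
    """
    fs = extract_fiducials(table, criterion=criterion)
    px = getattr(fs, "_pentagon_x")
    py = fs.pentagon[1]
    if px <= 0 or py <= 0:
        raise FiducialError("pentagon has non-positive coordinates")
    a_x, a_y = target[0] / px, target[1] / py
    return apply_scale(table, a_x, a_y), (a_x, a_y)


def normalize_cell(table: pd.DataFrame, criterion: float = 1.3
                   ) -> tuple[pd.DataFrame, tuple[float, float], FiducialSet]:
    """Four-fiducial normalization of one cell's two-input table."""
    fs = extract_fiducials(table, criterion=criterion)
    a_x, a_y = fit_scale_factors(fs)
    return apply_scale(table, a_x, a_y), (a_x, a_y), fs
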