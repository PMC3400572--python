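"""Input-output curve statistics: the NRLE measure and threshold detection.

NRLE ("nonlinearity relative to linear extrapolation") quantifies the
sharpest supralinear upturn of an input-output curve: for each point from
the second onward, a least-squares line through all preceding points is
extrapolated to that point's abscissa, and the maximum ratio of the actual
to the extrapolated response along the curve is the NRLE. Values above 1
indicate supralinear (local-spike-like) behavior; purely linear curves give
exactly 1 and saturating curves fall below 1.

Because zero stimulus produces zero depolarization, the physically forced
point (0, 0) is prepended by default (``anchor_origin``) so the fit
preceding the second data point is well posed; curves that already contain
an x = 0 sample (e.g. modulator-biased curves with a nonzero intercept)
are used as measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["IOCurve", "NRLEResult", "compute_nrle", "nrle_profile",
           "detect_threshold"]

logger = logging.getLogger(__name__)

PROXIMAL_DISTAL_CUTOFF_UM = 100.0  # classification boundary for sites
DEFAULT_JUMP_CRITERION = 1.3       # minimum NRLE that counts as a local spike


@dataclass
class IOCurve:
    """Stimulus intensities vs peak somatic depolarization (mV)."""

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) < 3:
            raise ValueError("an input-output curve needs at least 3 points")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be finite")

    def __len__(self):
        return len(self.x)


@dataclass(frozen=True)
class NRLEResult:
    nrle: float
    index: int              # index into the curve's own arrays
    ratios: np.ndarray      # per-index ratio (NaN where skipped)


def nrle_profile(c: IOCurve, anchor_origin: bool = True) -> NRLEResult:
    """Actual / linearly-extrapolated response ratio at every curve point."""
    x, y = c.x, c.y
    if anchor_origin and x[0] > 0:
        xf = np.concatenate(([0.0], x))
        yf = np.concatenate(([0.0], y))
        shift = 1
    else:
        xf, yf = x, y
        shift = 0
    n = len(x)
    ratios = np.full(n, np.nan)
    for i in range(n):
        k = i + shift  # index into the fitted arrays
        if k < 1:
            continue
        xs, ys = xf[:k], yf[:k]
        if k == 1:
            # one preceding point: the line fit is degenerate; use the
            # horizontal line through it (only reachable on curves whose
            # first sample already sits at x = 0, e.g. modulator-biased
            # curves with a nonzero intercept -- origin-anchored curves
            # always have two preceding points here)
            if ys[0] <= 0:
                continue
            y_ext = ys[0]
        else:
            if np.ptp(xs) == 0:
                continue
            slope, intercept = np.polyfit(xs, ys, 1)
            y_ext = slope * x[i] + intercept
        if y_ext <= 0:
            logger.warning(
                "NRLE: non-positive extrapolation (%.3g) at x=%.3g; skipped",
                y_ext, x[i])
            continue
        ratios[i] = y[i] / y_ext
    if np.all(np.isnan(ratios)):
        raise ValueError("no NRLE ratio could be evaluated on this curve")
    idx = int(np.nanargmax(ratios))
    return NRLEResult(float(ratios[idx]), idx, ratios)


def compute_nrle(c: IOCurve, anchor_origin: bool = True) -> tuple[float, int]:
    """Maximum actual/extrapolated ratio along the curve and its index.

    Ties break toward the smaller index.
    """
    r = nrle_profile(c, anchor_origin=anchor_origin)
    return r.nrle, r.index


def detect_threshold(c: IOCurve, criterion: float = DEFAULT_JUMP_CRITERION,
                     anchor_origin: bool = True) -> tuple[int, int] | None:
    """Just-sub and just-supra threshold indices of a local-spike jump.

    The suprathreshold index is where the NRLE ratio is maximal (the
    sharpest upturn); the subthreshold index is the point before it.
    Returns ``None`` when the curve's NRLE is below ``criterion`` (no local
    spike on this curve).
    """
    nrle, idx = compute_nrle(c, anchor_origin=anchor_origin)
    if nrle < criterion or idx == 0:
        return None
    return idx - 1, idx
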