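"""Single-site ramps and two-input (proximal x distal) grid experiments.

These protocols drive the cable model: a *ramp* varies the synapse count of
one cluster and records the peak somatic depolarization per count; a
*two-input map* activates a proximal and a distal cluster simultaneously
over a grid of synapse-count pairs. Curve families are one-dimensional
slices of a map viewed with either site as the driver (x-axis) and the
other as the modulator (one curve per modulation level); the modulator-
alone peaks are the curves' y-intercepts.

Peak responses are cached per (cell, protocol, locations, counts) so grid
mapping is re-entrant: a 21x21 map reuses the ramps already computed for
its first row and column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophysics import (
    Site,
    double_pulse,
    peak_depolarization,
    place_cluster,
    simulate,
    synapse_events,
)
from .cell import CellModel
from .curve_stats import IOCurve, detect_threshold

__all__ = [
    "TwoInputMap",
    "CurveFamily",
    "BinnedFamily",
    "ramp_single_site",
    "map_two_input",
    "slice_family",
    "categorize_and_average",
    "regional_variant",
    "family_max_gain",
    "threshold_indices",
    "additivity_deviation",
]

logger = logging.getLogger(__name__)

SINGLE_PULSE_NMDA = 3.56  # nS, uncaging-like single pulses
DOUBLE_PULSE_NMDA = (2.23, 4.46)  # nS, first/second pulse at 50 Hz
AMPA_GMAX = 1.5  # nS, fixed on every pulse

_PEAK_CACHE: dict = {}


@dataclass
class TwoInputMap:
    """Peak somatic depolarization over a (proximal, distal) count grid."""

    loc_prox: float
    loc_dist: float
    n_prox: np.ndarray
    n_dist: np.ndarray
    peaks: np.ndarray  # [i_prox, j_dist], mV
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_prox = np.asarray(self.n_prox)
        self.n_dist = np.asarray(self.n_dist)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.peaks.shape != (len(self.n_prox), len(self.n_dist)):
            raise ValueError("peaks shape must match the count axes")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.peaks, index=self.n_prox, columns=self.n_dist)
        df.index.name = "n_prox"
        df.columns.name = "n_dist"
        return df


@dataclass
class CurveFamily:
    """One IOCurve per modulation level, sharing a driver axis."""

    driver: str  # "prox" | "dist"
    mod_levels: np.ndarray
    curves: list[IOCurve]
    mod_alone_peaks: np.ndarray  # y-intercepts

    def restack(self) -> np.ndarray:
        """Rows = modulation levels, columns = driver counts."""
        return np.vstack([c.y for c in self.curves])


@dataclass
class BinnedFamily:
    bin_edges: np.ndarray
    bin_of_curve: np.ndarray  # -1 for excluded curves
    mean_curves: list[IOCurve]
    driver_counts: np.ndarray


def _cluster_sites(cell: CellModel, branches, center: float, n: int,
                   spacing: float = 0.5) -> list[Site]:
    """A cluster of n synapses, split evenly across the given branches."""
    if np.isscalar(branches):
        branches = [branches]
    k = len(branches)
    per = [n // k + (1 if i < n % k else 0) for i in range(k)]
    sites: list[Site] = []
    for b, cnt in zip(branches, per):
        if cnt:
            sites.extend(place_cluster(cell.morphology, b, center, cnt, spacing))
    return sites


def _pair_peak(cell: CellModel, branches_prox, branches_dist,
               loc_prox: float, loc_dist: float, n_p: int, n_d: int,
               protocol: str, nmda_scale: float, dt: float) -> float:
    key = (cell.morphology.fingerprint(), cell.membrane, cell.channels,
           tuple(np.atleast_1d(branches_prox)), tuple(np.atleast_1d(branches_dist)),
           loc_prox, loc_dist, n_p, n_d, protocol, nmda_scale, dt)
    if key in _PEAK_CACHE:
        return _PEAK_CACHE[key]
    if n_p == 0 and n_d == 0:
        peak = 0.0
    else:
        sites = (_cluster_sites(cell, branches_prox, loc_prox, n_p) if n_p else []) \
            + (_cluster_sites(cell, branches_dist, loc_dist, n_d) if n_d else [])
        m, mem, ch = cell.morphology, cell.membrane, cell.channels
        if protocol == "double_pulse":
            r = double_pulse(m, mem, ch, sites, nmda_scale=nmda_scale, dt=dt)
        elif protocol == "single_pulse":
            ev = synapse_events(sites, 5.0, SINGLE_PULSE_NMDA * nmda_scale,
                                AMPA_GMAX)
            r = simulate(m, mem, ch, ev, duration=70.0, dt=dt)
        else:
            raise ValueError(f"unknown protocol {protocol!r}")
        peak = peak_depolarization(r)
    _PEAK_CACHE[key] = peak
    return peak


def ramp_single_site(cell: CellModel, loc: float, counts=None,
                     branch=None, protocol: str = "single_pulse",
                     nmda_scale: float = 1.0, dt: float = 0.1) -> IOCurve:
    """Peak somatic depolarization vs synapse count at one site.

    ``nmda_scale=0`` simulates NMDA receptor block (the AMPA component is
    untouched).
    """
    counts = np.arange(2, 42, 2) if counts is None else np.asarray(counts)
    branch = cell.basal_ids[0] if branch is None else branch
    peaks = [_pair_peak(cell, branch, branch, loc, loc, int(n), 0,
                        protocol, nmda_scale, dt) for n in counts]
    return IOCurve(counts.astype(float), np.array(peaks),
                   meta={"loc_um": loc, "protocol": protocol,
                         "nmda_scale": nmda_scale})


def map_two_input(cell: CellModel, loc_prox: float = 90.0,
                  loc_dist: float = 150.0, n_max: int = 40, step: int = 2,
                  protocol: str = "double_pulse",
                  branch_prox=None, branch_dist=None,
                  nmda_scale: float = 1.0, dt: float = 0.1) -> TwoInputMap:
    """Simultaneous two-cluster activation over a synapse-count grid.

    Both clusters sit on the same branch by default (the canonical
    within-branch configuration); pass a different ``branch_dist`` for the
    between-branch control.
    """
    branch_prox = cell.basal_ids[0] if branch_prox is None else branch_prox
    branch_dist = branch_prox if branch_dist is None else branch_dist
    counts = np.arange(0, n_max + 1, step)
    peaks = np.empty((len(counts), len(counts)))
    for i, n_p in enumerate(counts):
        for j, n_d in enumerate(counts):
            peaks[i, j] = _pair_peak(cell, branch_prox, branch_dist,
                                     loc_prox, loc_dist, int(n_p), int(n_d),
                                     protocol, nmda_scale, dt)
    return TwoInputMap(loc_prox, loc_dist, counts, counts, peaks,
                       meta={"protocol": protocol,
                             "branch_prox": branch_prox,
                             "branch_dist": branch_dist,
                             "nmda_scale": nmda_scale})


def regional_variant(cell: CellModel, distribute_over,
                     **map_kwargs) -> TwoInputMap:
    """Two-input map with each cluster split across sibling branches.

    Each cluster's synapses are divided evenly over ``distribute_over`` at
    matched path distances; with a single branch this reduces exactly to
    :func:`map_two_input`.
    """
    return map_two_input(cell, branch_prox=list(distribute_over),
                         branch_dist=list(distribute_over), **map_kwargs)


def slice_family(m: TwoInputMap, driver: str) -> CurveFamily:
    """View the map as driver input-output curves, one per modulation level."""
    if driver == "dist":
        mod_levels, x = m.n_prox, m.n_dist
        rows = m.peaks  # row i: fixed prox level
    elif driver == "prox":
        mod_levels, x = m.n_dist, m.n_prox
        rows = m.peaks.T
    else:
        raise ValueError("driver must be 'prox' or 'dist'")
    curves = [IOCurve(x.astype(float), rows[i],
                      meta={"driver": driver, "mod_level": int(mod_levels[i])})
              for i in range(len(mod_levels))]
    mod_alone = np.array([c.y[0] for c in curves])
    return CurveFamily(driver, np.asarray(mod_levels), curves, mod_alone)


def categorize_and_average(f: CurveFamily, n_bins: int = 4,
                           exclusion_ceiling: float | None = None) -> BinnedFamily:
    """Group curves into modulation-strength categories and average per bin.

    Bins are contiguous quantile ranges of the modulator-alone peak; curves
    whose modulator-alone peak exceeds ``exclusion_ceiling`` are dropped
    before binning (mirroring the exclusion of modulation levels with no
    experimental counterpart).
    """
    keep = np.ones(len(f.curves), dtype=bool)
    if exclusion_ceiling is not None:
        keep &= f.mod_alone_peaks <= exclusion_ceiling
    kept = np.flatnonzero(keep)
    if len(kept) == 0:
        raise ValueError("all curves excluded")
    if len(kept) < n_bins:
        logger.warning("only %d curves for %d bins; merging", len(kept), n_bins)
        n_bins = len(kept)
    strengths = f.mod_alone_peaks[kept]
    edges = np.quantile(strengths, np.linspace(0, 1, n_bins + 1))
    bin_of = np.full(len(f.curves), -1)
    for k, ci in enumerate(kept):
        b = int(np.searchsorted(edges[1:-1], strengths[k], side="right"))
        bin_of[ci] = b
    x = f.curves[0].x
    means = []
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        if len(members) == 0:  # quantile ties can empty a bin
            continue
        y = np.mean([f.curves[i].y for i in members], axis=0)
        means.append(IOCurve(x, y, meta={"bin": b, "n_curves": len(members)}))
    return BinnedFamily(edges, bin_of, means, x)


# -- derived metrics -------------------------------------------------------

def family_max_gain(f: CurveFamily) -> float:
    """Relative increase of the curve maximum under strongest modulation."""
    base = float(np.max(f.curves[0].y))
    top = float(np.max(f.curves[-1].y))
    if base <= 0:
        raise ValueError("unmodulated curve has no positive response")
    return top / base - 1.0


def threshold_indices(f: CurveFamily, criterion: float = 1.3) -> list[int | None]:
    """Suprathreshold index per modulation level (None once no jump remains)."""
    out = []
    for c in f.curves:
        th = detect_threshold(c, criterion=criterion)
        out.append(None if th is None else th[1])
    return out


def between_branch_comparison(cell: CellModel, loc_prox: float = 90.0,
                              loc_dist: float = 150.0,
                              prox_counts=None, dist_counts=None,
                              protocol: str = "double_pulse",
                              dt: float = 0.1) -> dict:
    """Within- vs between-branch additivity of peak somatic responses.

    The distal input acts as a modulator at counts below its own local-spike
    threshold (where the within-branch interaction is strongest) while the
    proximal driver spans its full range; the same grid is mapped with both
    clusters on one branch and with the distal cluster moved to a sibling
    branch at the same path distance. Returns both additivity deviation
    scores and their ratio.
    """
    prox_counts = np.arange(0, 45, 5) if prox_counts is None else np.asarray(prox_counts)
    dist_counts = np.array([0, 3, 6, 9]) if dist_counts is None else np.asarray(dist_counts)
    b0 = cell.basal_ids[0]
    maps = {}
    for label, bd in (("within", b0), ("between", cell.basal_ids[1])):
        peaks = np.zeros((len(prox_counts), len(dist_counts)))
        for i, n_p in enumerate(prox_counts):
            for j, n_d in enumerate(dist_counts):
                peaks[i, j] = _pair_peak(cell, b0, bd, loc_prox, loc_dist,
                                         int(n_p), int(n_d), protocol, 1.0, dt)
        maps[label] = TwoInputMap(loc_prox, loc_dist, prox_counts,
                                  dist_counts, peaks,
                                  meta={"layout": label})
    dev_w = additivity_deviation(maps["within"])
    dev_b = additivity_deviation(maps["between"])
    return {"within": maps["within"], "between": maps["between"],
            "dev_within": dev_w, "dev_between": dev_b,
            "ratio": dev_w / dev_b if dev_b > 0 else np.inf}


def additivity_deviation(m: TwoInputMap) -> float:
    """Maximum deviation from additive combination, relative to the range.

    ``max |r(i,j) - r(i,0) - r(0,j) + r(0,0)| / (max - min)``; near zero
    when the two inputs sum linearly at the soma (between-branch control).
    """
    r = m.peaks
    pred = r[:, :1] + r[:1, :] - r[0, 0]
    dev = np.abs(r - pred).max()
    rng = r.max() - r.min()
    return float(dev / rng) if rng > 0 else 0.0
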