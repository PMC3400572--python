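"""Synthetic two-input "slice experiment" cohorts.

The normalization stage assumes heterogeneous cells: different stimulation
efficacies and branch geometries stretch each cell's intensity axis and
response axis, and measurements carry additive noise. This module emulates
that structure with no recordings: each synthetic cell is the canonical
model-generated two-input map with its axes warped by hidden per-cell
scale factors (log-normal with unit median, so factors are positive and
symmetric on a log scale), subsampled to a realistic number of stimulus
pairs, plus Gaussian measurement noise on the responses.

The subsample always contains the curves that define the fiducial points
(the proximal-alone ramp, the distal-alone ramp, and the distal ramps at
the proximal levels bracketing the subthreshold bias), so extraction can
only fail through noise, in which case generation retries with a fresh
subsample before giving up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_stats import IOCurve, detect_threshold
from .normalization import X_DIST, X_PROX, Y, extract_fiducials, FiducialError
from .summation import TwoInputMap

__all__ = ["SyntheticCohortSpec", "SyntheticCell", "SyntheticCohort",
           "generate_cohort", "CohortGenerationError"]

logger = logging.getLogger(__name__)


class CohortGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the experimental structure being emulated: 6 cells
    contributing 29-56 stimulus pairs each, per-cell horizontal and
    vertical log-normal scale variability (sigma 0.3, unit median) and
    0.3 mV additive measurement noise on peak responses.
    """

    n_cells: int = 6
    pairs_min: int = 29
    pairs_max: int = 56
    x_sigma: float = 0.3
    y_sigma: float = 0.3
    noise_sd_mv: float = 0.3
    seed: int = 0
    pair_counts: tuple[int, ...] | None = None  # fixed per-cell preset

    def __post_init__(self):
        if self.x_sigma < 0 or self.y_sigma < 0 or self.noise_sd_mv < 0:
            raise ValueError("spreads must be >= 0")
        if not (3 <= self.pairs_min <= self.pairs_max):
            raise ValueError("invalid pairs range")
        if self.pair_counts is not None:
            if len(self.pair_counts) != self.n_cells:
                raise ValueError("pair_counts must have one entry per cell")
            if any(not (self.pairs_min <= c <= self.pairs_max)
                   for c in self.pair_counts):
                raise ValueError("pair_counts outside the allowed range")


@dataclass
class SyntheticCell:
    cell_id: int
    table: pd.DataFrame            # observed: x_dist, x_prox, y_mv
    x_scale: float                 # hidden ground truth
    y_scale: float
    n_pairs: int


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    cells: list[SyntheticCell]

    @property
    def total_pairs(self) -> int:
        return sum(c.n_pairs for c in self.cells)

    def observed_frame(self) -> pd.DataFrame:
        frames = []
        for c in self.cells:
            t = c.table.copy()
            t.insert(0, "cell_id", c.cell_id)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cell_id": c.cell_id, "x_scale": c.x_scale,
              "y_scale": c.y_scale, "n_pairs": c.n_pairs}
             for c in self.cells])


def _canonical_prox_sub_index(canonical: TwoInputMap,
                              criterion: float) -> int:
    prox_alone = IOCurve(canonical.n_prox[1:].astype(float),
                         canonical.peaks[1:, 0])
    th = detect_threshold(prox_alone, criterion=criterion)
    if th is None:
        raise CohortGenerationError(
            "canonical map has no proximal-alone local spike")
    return th[0] + 1  # back to full-axis indexing


def _cell_table(canonical: TwoInputMap, rng: np.random.Generator,
                n_pairs: int, x_scale: float, y_scale: float,
                noise_sd: float, prox_sub_idx: int) -> pd.DataFrame:
    n_p = canonical.n_prox
    n_d = canonical.n_dist
    # mandatory curves: proximal-alone, distal-alone, and distal ramps at
    # the levels bracketing the canonical subthreshold proximal bias
    mandatory_rows: list[tuple[int, int]] = []
    for i in range(len(n_p)):
        mandatory_rows.append((i, 0))
    bias_rows = sorted({prox_sub_idx, min(prox_sub_idx + 1, len(n_p) - 1)})
    for i in [0] + bias_rows:
        for j in range(1, len(n_d)):
            mandatory_rows.append((i, j))
    mandatory = list(dict.fromkeys(mandatory_rows))
    pool = [(i, j) for i in range(len(n_p)) for j in range(len(n_d))
            if (i, j) not in set(mandatory)]
    n_extra = max(0, n_pairs - len(mandatory))
    extra_idx = rng.choice(len(pool), size=min(n_extra, len(pool)),
                           replace=False) if pool and n_extra else []
    chosen = mandatory + [pool[k] for k in np.sort(np.asarray(extra_idx, int))]
    rows = []
    for i, j in chosen:
        y = canonical.peaks[i, j] * y_scale + rng.normal(0.0, noise_sd)
        rows.append({X_DIST: n_d[j] * x_scale, X_PROX: n_p[i] * x_scale,
                     Y: y})
    return pd.DataFrame(rows)


def generate_cohort(spec: SyntheticCohortSpec, canonical: TwoInputMap,
                    criterion: float = 1.3,
                    max_retries: int = 20) -> SyntheticCohort:
    """Sample a cohort of warped, noisy copies of the canonical map.

    Each cell's table passes fiducial extraction (retried with fresh draws
    when noise defeats it); ground-truth scale factors are stored separately
    from the observed tables.
    """
    rng = np.random.default_rng(spec.seed)
    prox_sub_idx = _canonical_prox_sub_index(canonical, criterion)
    # noise-free reference: where the true local-spike transitions sit
    ref = extract_fiducials(
        _cell_table(canonical, np.random.default_rng(0), 10 ** 9,
                    1.0, 1.0, 0.0, prox_sub_idx),
        criterion=criterion)
    cells: list[SyntheticCell] = []
    for cid in range(spec.n_cells):
        x_scale = float(np.exp(rng.normal(0.0, spec.x_sigma)))
        y_scale = float(np.exp(rng.normal(0.0, spec.y_sigma)))
        n_pairs = (spec.pair_counts[cid] if spec.pair_counts is not None
                   else int(rng.integers(spec.pairs_min, spec.pairs_max + 1)))
        ok = None
        for attempt in range(max_retries):
            table = _cell_table(canonical, rng, n_pairs, x_scale, y_scale,
                                spec.noise_sd_mv, prox_sub_idx)
            try:
                fs = extract_fiducials(table, criterion=criterion)
            except FiducialError:
                logger.warning("cell %d: fiducial extraction failed on "
                               "attempt %d; retrying", cid, attempt + 1)
                continue
            # a fiducial detected at the wrong stimulus level is as
            # undetectable as a missing one: the jump must be found at the
            # cell's true (warped) transition
            expect = np.array([ref.triangle[0], ref.circle[0],
                               getattr(ref, "_pentagon_x")]) * x_scale
            got = np.array([fs.triangle[0], fs.circle[0],
                            getattr(fs, "_pentagon_x")])
            if not np.allclose(got, expect, rtol=1e-9):
                logger.warning("cell %d: fiducial misdetected on attempt "
                               "%d; retrying", cid, attempt + 1)
                continue
            ok = table
            break
        if ok is None:
            raise CohortGenerationError(
                f"cell {cid}: fiducials undetectable after {max_retries} "
                f"attempts at noise sd {spec.noise_sd_mv} mV")
        cells.append(SyntheticCell(cid, ok, x_scale, y_scale, len(ok)))
    return SyntheticCohort(spec, cells)


def paper_like_pair_counts(n_cells: int = 6, total: int = 294,
                           lo: int = 29, hi: int = 56) -> list[int]:
    """A fixed per-cell pair-count preset summing to the stated total."""
    base = [lo + round((hi - lo) * k / (n_cells - 1)) for k in range(n_cells)]
    # adjust the middle cells to hit the total exactly while staying in range
    diff = total - sum(base)
    k = 0
    while diff != 0:
        step = 1 if diff > 0 else -1
        cand = base[k % n_cells] + step
        if lo <= cand <= hi:
            base[k % n_cells] = cand
            diff -= step
        k += 1
    return base
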