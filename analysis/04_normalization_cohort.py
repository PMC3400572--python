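#!/usr/bin/env python
"""Synthetic heterogeneous cohort + fiducial-template normalization.

Generates a 6-cell cohort of warped, noisy copies of the canonical
two-input map (per-cell log-normal horizontal/vertical scale factors,
29-56 stimulus pairs per cell, the paper-like preset totalling 294 pairs,
0.3 mV measurement noise), extracts each cell's four fiducial points
(triangle/square/pentagon/circle), fits the two per-cell scale factors
onto the fixed template, and compares the recovered factors with the
hidden ground truth. Also applies the single-landmark rigid scaling of
the orthogonal (proximal-driver) view.

Writes results/cohort_observed.csv, cohort_ground_truth.csv,
cohort_recovery.csv. Runtime: seconds.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dendsum.normalization import (
    extract_fiducials,
    fit_scale_factors,
    normalize_cell,
    rigid_scale_orthogonal,
)
from dendsum.summation import TwoInputMap
from dendsum.synth import (
    SyntheticCohortSpec,
    generate_cohort,
    paper_like_pair_counts,
)
from dendsum.two_compartment import (
    TwoCompParams,
    fit_output_scale,
    response_surface,
)


def canonical_map(step: int = 4) -> TwoInputMap:
    counts = np.arange(0, 41, step)
    surf = response_surface(TwoCompParams(), counts, counts)
    surf = surf * fit_output_scale(surf, 15.2)
    return TwoInputMap(90.0, 150.0, counts, counts, surf)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    canon = canonical_map()
    spec = SyntheticCohortSpec(seed=args.seed,
                               pair_counts=tuple(paper_like_pair_counts()))
    cohort = generate_cohort(spec, canon)
    cohort.observed_frame().to_csv(args.outdir / "cohort_observed.csv",
                                   index=False)
    cohort.ground_truth().to_csv(args.outdir / "cohort_ground_truth.csv",
                                 index=False)
    print(f"cohort: {spec.n_cells} cells, {cohort.total_pairs} stimulus "
          f"pairs (preset minimum 294)")

    # reference factors of the canonical map itself: recovery is judged
    # relative to these, since every cell is a warped copy of the canonical
    rows = [{"x_dist": d, "x_prox": q, "y_mv": canon.peaks[i, j]}
            for i, q in enumerate(canon.n_prox)
            for j, d in enumerate(canon.n_dist)]
    a_x0, a_y0 = fit_scale_factors(extract_fiducials(pd.DataFrame(rows)))

    recov = []
    for c in cohort.cells:
        _, (a_x, a_y), fs = normalize_cell(c.table)
        _, (r_x, r_y) = rigid_scale_orthogonal(c.table)
        err_x = abs(a_x * c.x_scale / a_x0 - 1)
        err_y = abs(a_y * c.y_scale / a_y0 - 1)
        recov.append({"cell_id": c.cell_id, "n_pairs": c.n_pairs,
                      "true_x_scale": c.x_scale, "true_y_scale": c.y_scale,
                      "fit_a_x": a_x, "fit_a_y": a_y,
                      "rigid_a_x": r_x, "rigid_a_y": r_y,
                      "rel_err_x": err_x, "rel_err_y": err_y,
                      "circle_x_over_triangle_x": fs.circle[0] / fs.triangle[0]})
        print(f"cell {c.cell_id}: true scales ({c.x_scale:.3f}, "
              f"{c.y_scale:.3f}), recovery error ({err_x:.2%}, {err_y:.2%}); "
              f"circle/triangle threshold ratio "
              f"{fs.circle[0] / fs.triangle[0]:.2f}")
    df = pd.DataFrame(recov)
    df.to_csv(args.outdir / "cohort_recovery.csv", index=False)
    print(f"\nmedian recovery error: x {df.rel_err_x.median():.2%}, "
          f"y {df.rel_err_y.median():.2%} at "
          f"{spec.noise_sd_mv} mV measurement noise")
    print("proximal bias cuts the distal spike threshold to "
          f"{df.circle_x_over_triangle_x.mean():.2f}x its unbiased value "
          "on average")
    print(f"wrote results under {args.outdir}")


if __name__ == "__main__":
    main()
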