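#!/usr/bin/env python
"""Two-input (90 x 150 um) summation map and its asymmetric curve families.

Maps peak somatic depolarization over a 21 x 21 grid of simultaneous
proximal/distal synapse counts with the double-pulse protocol, slices the
map into driver/modulator curve families in both orientations, bins the
families into four modulation-strength categories, and quantifies the
headline asymmetry: proximal modulation raises the maximum of the
distally-driven curve (gain boost) while distal modulation mostly
left-shifts the proximally-driven curve (threshold lowering).

Also runs the between-branch control with sub-spike distal modulators.

Writes results/two_input_map.csv, *_family_{dist,prox}.csv,
results/asymmetry_summary.csv. Runtime: ~2 min on one core.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dendsum.cell import default_cell
from dendsum.summation import (
    between_branch_comparison,
    categorize_and_average,
    family_max_gain,
    map_two_input,
    slice_family,
    threshold_indices,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cell = default_cell()
    m = map_two_input(cell, 90.0, 150.0, n_max=40, step=2)
    m.to_frame().to_csv(args.outdir / "two_input_map.csv")
    print(f"grid peak {m.peaks.max():.2f} mV at "
          f"(n_prox, n_dist) = ({m.n_prox[-1]}, {m.n_dist[-1]})")

    summary = []
    for driver in ("dist", "prox"):
        fam = slice_family(m, driver)
        gain = family_max_gain(fam)
        th = threshold_indices(fam)
        detected = [i for i in th if i is not None]
        binned = categorize_and_average(fam, n_bins=4)
        rows = []
        for c, lvl in zip(fam.curves, fam.mod_levels):
            for x, y in zip(c.x, c.y):
                rows.append({"mod_level": int(lvl), "driver_count": x,
                             "peak_mv": y})
        pd.DataFrame(rows).to_csv(
            args.outdir / f"two_input_family_{driver}.csv", index=False)
        print(f"{driver}-driver view: max gain under strongest modulation "
              f"{gain:+.2%}; threshold index shifts "
              f"{detected[0]} -> {detected[-1]} over the detectable range; "
              f"{len(binned.mean_curves)} category averages")
        summary.append({"driver": driver, "max_gain": gain,
                        "first_threshold_idx": detected[0],
                        "last_threshold_idx": detected[-1]})

    cmp = between_branch_comparison(cell)
    print(f"additivity deviation: within-branch {cmp['dev_within']:.3f}, "
          f"between-branch {cmp['dev_between']:.3f} "
          f"(ratio {cmp['ratio']:.1f}x)")
    summary.append({"driver": "additivity",
                    "max_gain": np.nan,
                    "first_threshold_idx": cmp["dev_within"],
                    "last_threshold_idx": cmp["dev_between"]})
    pd.DataFrame(summary).to_csv(args.outdir / "asymmetry_summary.csv",
                                 index=False)
    print(f"wrote results under {args.outdir}")


if __name__ == "__main__":
    main()
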