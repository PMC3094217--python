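#!/usr/bin/env python
"""Parameter sensitivity sweep for the liver level-set stage.

Varies each of the five parameters one at a time around the tuned defaults,
segments the default phantom, scores the result against the ground truth
and writes a CSV (parameter, value, voe, total_score).  This is an
exploratory tool, not part of the acceptance surface.

Usage:  python scripts/sensitivity.py --seed 0 --out sensitivity.csv
"""

from __future__ import annotations

import argparse
import csv
from dataclasses import replace

import numpy as np
from scipy import ndimage

from hepatoseg.eval_metrics import HumanErrorRefs, compute_metrics, total_score
from hepatoseg.liver_levelset import LevelSetParams, segment_liver
from hepatoseg.phantom import default_spec, make_phantom, scaled_spec

SWEEPS = {
    "min_rms": np.geomspace(0.005, 0.05, 7),
    "G_L": np.linspace(0.15, 0.65, 7),
    "G_H": np.linspace(0.15, 0.65, 7),
    "beta": -np.geomspace(0.5, 50.0, 7),
    "gamma": np.linspace(0.0, 1000.0, 7),
}

# placeholder human-error references for the sweep (the score is only used
# to compare parameter settings against each other)
REFS = HumanErrorRefs(e_voe=6.4, e_rvd=4.7, e_asd=1.0, e_rmssd=1.8, e_msd=19.0)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=str, default="sensitivity.csv")
    ap.add_argument("--shape", type=int, nargs=3, default=(64, 96, 96))
    args = ap.parse_args()

    truth = make_phantom(scaled_spec(default_spec(args.seed),
                                     tuple(args.shape)))
    liver = truth.liver.as_bool()
    k = truth.volume.shape[0] // 2
    seed2d = ndimage.binary_erosion(liver[k], iterations=3)

    rows = []
    base = LevelSetParams()
    for name, values in SWEEPS.items():
        for v in values:
            params = replace(base, **{name: float(v)})
            try:
                seg = segment_liver(truth.volume, k, seed2d, params)
                m = compute_metrics(seg, truth.liver)
                rep = total_score(m, REFS)
                rows.append((name, float(v), m[0], rep.total_score))
            except (ValueError, RuntimeError):
                rows.append((name, float(v), float("nan"), 0.0))
            print(f"{name}={v:.4g}: voe={rows[-1][2]:.2f} "
                  f"score={rows[-1][3]:.1f}")

    with open(args.out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parameter", "value", "voe_percent", "total_score"])
        w.writerows(rows)


if __name__ == "__main__":
    main()
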