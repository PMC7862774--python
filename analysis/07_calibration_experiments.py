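"""Recovery and false-positive calibration of the whole scan.

Runs 20 seeded studies with the planted QTL (does region calling find it,
and how well is it localised?) and 20 without any QTL (how often do windows
exceed the 99.9% threshold, and are regions ever called?).  Takes a few
minutes; writes results/calibration.json.
"""

import json
import warnings
from pathlib import Path

import numpy as np

from bulkscan.experiments import null_experiment, recovery_experiment

OUT = Path("results/calibration.json")
SEED0 = 1


def main() -> None:
    warnings.filterwarnings("ignore", category=UserWarning)
    rec = recovery_experiment(n_seeds=20, seed0=SEED0)
    nul = null_experiment(n_seeds=20, seed0=SEED0)
    summary = {
        "recovery": {
            "n_seeds": rec.n_seeds,
            "regions_overlapping_truth": rec.n_with_overlapping_region,
            "best_midpoint_within_500kb": rec.n_best_midpoint_within_window,
            "median_midpoint_error_kb": float(np.median(rec.midpoint_errors_bp)) / 1e3,
            "median_peak_error_kb": float(np.median(rec.peak_errors_bp)) / 1e3,
        },
        "null": {
            "n_seeds": nul.n_seeds,
            "mean_window_exceedance": nul.mean_exceedance,
            "seeds_with_false_regions": nul.n_seeds_with_regions,
        },
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(summary, indent=1))
    print(json.dumps(summary, indent=1))
    print("note: regions overlap the QTL in every seed, but with a single "
          "strong QTL the 0.7/0.3 pool-index plateau spans most of the "
          "chromosome, so region midpoints localise to ~1 Mb while the peak "
          "window localises to ~0.1 Mb")


if __name__ == "__main__":
    main()
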