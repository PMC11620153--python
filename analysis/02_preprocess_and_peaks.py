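#!/usr/bin/env python
"""Condition every recording and extract activation-peak features.

Applies the DC-removal -> 10-100 Hz band-pass -> 2-s edge trim -> rectify ->
linear-envelope chain, selects prominence-thresholded peaks, and writes the
per-recording peak features (count, median amplitude, mean interval) plus a
ground-truth comparison showing how well the detected counts recover the
simulated tap counts.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from emgtap.evaluation import recovery_errors
from emgtap.pipeline import load_cohort, peak_feature_frame
from emgtap.simulate import SimConfig, simulate_cohort

COHORT = Path("scratch/cohort/manifest.json")
OUT = Path("results")


def main() -> None:
    recordings, _ = load_cohort(COHORT)
    peaks = peak_feature_frame(recordings)
    OUT.mkdir(exist_ok=True)
    peaks.to_csv(OUT / "peak_features.csv", index=False)

    summary = (
        peaks[peaks.feature == "n_peaks"]
        .groupby(["task", "group", "condition"])["value"]
        .agg(["mean", "std"])
        .round(1)
    )
    print("mean detected peaks per recording:")
    print(summary.to_string())

    # recovery against ground truth (regenerated from the same seed)
    cohort = simulate_cohort(SimConfig(seed=2026))
    errors = recovery_errors(cohort)
    print(
        f"\nmedian |detected - true| tap-count error: "
        f"{100 * errors['median_count_rel_error']:.1f}% "
        f"(interval: {100 * errors['median_interval_rel_error']:.1f}%)"
    )
    pd.DataFrame([errors]).to_csv(OUT / "recovery_errors.csv", index=False)


if __name__ == "__main__":
    main()
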