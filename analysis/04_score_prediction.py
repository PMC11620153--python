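#!/usr/bin/env python
"""Leave-one-subject-out score prediction: standard vs extended features.

Builds per-(subject, condition, task) feature tables for the six PD
subjects, fits random-forest regressors of the total MDS-UPDRS III score
under leave-one-subject-out cross-validation, and compares the pooled
out-of-fold Pearson correlations of the standard (Hudgins + Du) and
extended (plus MAV1/MAV2/ApEn/SampEn and activation-peak) feature banks.
"""

import json
from pathlib import Path

from emgtap.features import build_table, standard_subset
from emgtap.model import compare_models
from emgtap.pipeline import load_cohort

COHORT = Path("scratch/cohort/manifest.json")
OUT = Path("results")


def main() -> None:
    recordings, scores = load_cohort(COHORT)
    pd_recs = [r for r in recordings if r.group == "pd"]
    table_ext = build_table(pd_recs, feature_set="extended")
    table_std = standard_subset(table_ext)
    table_ext.data.to_csv(OUT / "features_extended.tsv", sep="\t")
    table_std.data.to_csv(OUT / "features_standard.tsv", sep="\t")

    report = compare_models(table_std, table_ext, scores)
    for task, preds in report.pop("predictions").items():
        for name, frame in preds.items():
            frame.assign(feature_set=name).to_csv(
                OUT / f"predictions_{task}_{name}.csv", index=False
            )
    (OUT / "model_comparison.json").write_text(json.dumps(report, indent=2))

    print("pooled LOSO Pearson correlation with the total score:")
    for task, vals in report["tasks"].items():
        print(f"  {task:>15}: standard {vals['r_standard']:+.3f}  "
              f"extended {vals['r_extended']:+.3f}  "
              f"(delta {vals['delta_r']:+.3f})")


if __name__ == "__main__":
    main()
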