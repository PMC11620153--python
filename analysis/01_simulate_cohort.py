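#!/usr/bin/env python
"""Generate the default synthetic tapping-EMG cohort and persist it.

Writes 38 recordings (6 PD subjects x OFF/ON x two tasks, 7 healthy
controls x two tasks), the linked MDS-UPDRS-like scores, the cohort
manifest and the generator ground truth.  Recordings are large, so they go
under scratch/; run this before 02-05, which read the manifest.
"""

from pathlib import Path

from emgtap.simulate import SimConfig, generate_cohort

OUT = Path("scratch/cohort")


def main() -> None:
    cfg = SimConfig(seed=2026)
    cohort, manifest = generate_cohort(cfg, OUT)
    n_pd = sum(1 for r in cohort.recordings if r.group == "pd")
    n_hc = len(cohort.recordings) - n_pd
    print(f"wrote {len(cohort.recordings)} recordings to {OUT}/ "
          f"({n_pd} PD, {n_hc} healthy), {len(cohort.scores)} score rows")
    print(f"manifest: {OUT}/manifest.json; ground truth: {OUT}/sim_truth.json")


if __name__ == "__main__":
    main()
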