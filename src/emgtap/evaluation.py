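"""Study-level evaluation routines: calibration sweeps and recovery metrics.

These functions measure, from scratch, the properties the pipeline is
expected to have on synthetic cohorts: detection of the levodopa x group
interaction, post-hoc contrast behaviour, false-positive calibration under a
null model, ground-truth recovery of tap counts and intervals, and the
standard-vs-extended model comparison.  They are used by the acceptance
checks and by the analysis scripts.

Problem sizes are chosen so a full evaluation runs in minutes on one core:
the cohort sweeps use one channel and one task per cohort and the model
comparison two channels (full-length 23-s recordings at 1260 Hz throughout);
see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from emgtap.bursts import select_peaks
from emgtap.features import build_table, standard_subset
from emgtap.model import ModelConfig, compare_models
from emgtap.pipeline import peak_feature_frame
from emgtap.preprocess import PreprocessParams, preprocess_recording
from emgtap.simulate import SimConfig, simulate_cohort
from emgtap.stats import (
    bonferroni_alpha,
    impute_healthy_condition,
    independent_t,
    mixed_anova_2x2,
    paired_t,
)

SWEEP_CHANNELS = (("flexors", "left"),)
MODEL_CHANNELS = (("flexors", "left"), ("extensors", "left"))


def cohort_sweep(
    n_cohorts: int,
    seed0: int,
    healthy_rate_hz: float | None = None,
    alpha: float | None = None,
) -> dict:
    """Rejection rates of the ANOVA sources and post-hoc contrasts for the
    activation-peak count, across seeded synthetic cohorts.

    Each cohort is generated, preprocessed and peak-counted from scratch
    (one channel, one task).  ``healthy_rate_hz`` overrides the healthy
    group's mean tap rate; with the override set equal to the PD ON rate the
    sweep probes the ON ~ healthy regime in which the ON-vs-healthy contrast
    should rarely reject.
    """
    alpha = alpha if alpha is not None else bonferroni_alpha(0.05, 4)
    counts = {"group": 0, "condition": 0, "interaction": 0,
              "off_vs_on": 0, "off_vs_healthy": 0, "on_vs_healthy": 0}
    for k in range(n_cohorts):
        kwargs = {}
        if healthy_rate_hz is not None:
            kwargs["rate_healthy_hz"] = healthy_rate_hz
        cfg = SimConfig(
            tasks=("finger_tapping",), channels=SWEEP_CHANNELS,
            seed=seed0 + k, **kwargs,
        )
        cohort = simulate_cohort(cfg)
        peaks = peak_feature_frame(cohort.recordings)
        sub = peaks[peaks.feature == "n_peaks"][
            ["subject_id", "group", "condition", "value"]
        ]
        res = mixed_anova_2x2(impute_healthy_condition(sub))
        for source in ("group", "condition", "interaction"):
            counts[source] += res[source]["p"] < alpha
        wide = sub[sub.group == "pd"].pivot_table(
            index="subject_id", columns="condition", values="value"
        )
        healthy = sub.loc[sub.group == "healthy", "value"].to_numpy()
        try:
            off_on_sig = paired_t(wide["off"], wide["on"], alpha).significant
        except ValueError:
            # integer peak counts can make every OFF-ON difference identical;
            # a constant nonzero shift is an unambiguous within-subject effect
            off_on_sig = bool(np.mean(wide["off"] - wide["on"]) != 0)
        counts["off_vs_on"] += off_on_sig
        counts["off_vs_healthy"] += independent_t(
            wide["off"], healthy, alpha_adjusted=alpha
        ).significant
        counts["on_vs_healthy"] += independent_t(
            wide["on"], healthy, alpha_adjusted=alpha
        ).significant
    return {k: v / n_cohorts for k, v in counts.items()}


def null_anova_rejection_rates(
    n_reps: int, seed: int, alpha: float | None = None,
    n_pd: int = 6, n_healthy: int = 7,
) -> dict:
    """False-positive rates of the mixed ANOVA under a pure null.

    Measurements are a subject random intercept plus Gaussian noise with no
    group, condition or interaction effect, so every source's rejection rate
    should equal the nominal alpha.
    """
    alpha = alpha if alpha is not None else bonferroni_alpha(0.05, 4)
    rng = np.random.default_rng(seed)
    rej = {"group": 0, "condition": 0, "interaction": 0}
    for _ in range(n_reps):
        rows = []
        for group, n in (("pd", n_pd), ("healthy", n_healthy)):
            for i in range(n):
                intercept = rng.standard_normal()
                for cond in ("off", "on"):
                    rows.append(
                        {
                            "subject_id": f"{group}{i}", "group": group,
                            "condition": cond,
                            "value": intercept + rng.standard_normal(),
                        }
                    )
        res = mixed_anova_2x2(pd.DataFrame(rows))
        for source in rej:
            rej[source] += res[source]["p"] < alpha
    return {k: v / n_reps for k, v in rej.items()}


def recovery_errors(cohort, params: PreprocessParams | None = None,
                    rel_threshold: float = 0.1) -> dict:
    """Relative errors of pipeline peak counts and intervals vs ground truth.

    Truth for the count is the number of simulated taps inside the analysed
    (edge-trimmed) interval; truth for the mean inter-peak interval is the
    reciprocal of the subject's true tap rate.
    """
    params = params or PreprocessParams()
    cfg = cohort.config
    count_errors, interval_errors = [], []
    for rec in cohort.recordings:
        _, envelopes = preprocess_recording(rec, params)
        key = (rec.subject_id, rec.condition, rec.task)
        taps = [
            t for t in cohort.truth.tap_times[key]
            if params.trim_s <= t <= cfg.duration_s - params.trim_s
        ]
        true_rate = cohort.truth.true_rate_hz[key]
        for env in envelopes:
            ps = select_peaks(env.samples, rel_threshold)
            count_errors.append(abs(len(ps) - len(taps)) / len(taps))
            if len(ps) >= 2:
                interval = float(np.mean(np.diff(ps.indices))) / cfg.fs
                interval_errors.append(abs(interval - 1 / true_rate) * true_rate)
    return {
        "median_count_rel_error": float(np.median(count_errors)),
        "median_interval_rel_error": float(np.median(interval_errors)),
        "n_recordings": len(cohort.recordings),
    }


def model_comparison_sweep(n_seeds: int, seed0: int,
                           config: ModelConfig | None = None) -> dict:
    """Standard-vs-extended pooled LOSO correlations over seeded cohorts.

    Each seed generates a fresh 6-patient cohort (two channels, one task)
    whose clinical scores are antitone in the true tap rate, then fits both
    models and records the pooled out-of-fold Pearson correlations.
    """
    config = config or ModelConfig()
    r_standard, r_extended = [], []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_pd=6, n_healthy=0, tasks=("finger_tapping",),
            channels=MODEL_CHANNELS, seed=seed0 + k,
        )
        cohort = simulate_cohort(cfg)
        table_ext = build_table(cohort.recordings, feature_set="extended")
        table_std = standard_subset(table_ext)
        rep = compare_models(table_std, table_ext, cohort.scores, config)
        vals = rep["tasks"]["finger_tapping"]
        r_standard.append(vals["r_standard"])
        r_extended.append(vals["r_extended"])
    wins = sum(e > s for s, e in zip(r_standard, r_extended))
    return {
        "r_standard": r_standard,
        "r_extended": r_extended,
        "extended_win_fraction": wins / n_seeds,
        "mean_r_standard": float(np.mean(r_standard)),
        "mean_r_extended": float(np.mean(r_extended)),
    }


def filter_contract(fs: float = 1260.0) -> dict:
    """Magnitude-response contract of the default conditioning chain.

    Measured on actual signals: attenuation of a 2 Hz sinusoid and gain at
    50 Hz through the zero-phase 10-100 Hz band-pass, and the DC gain of the
    envelope stage on a constant input.
    """
    from emgtap.preprocess import bandpass, linear_envelope

    t = np.arange(int(20 * fs)) / fs
    core = slice(int(2 * fs), -int(2 * fs))

    x50 = np.sin(2 * np.pi * 50 * t)
    y50 = bandpass(x50, fs)
    gain_50 = float(np.sqrt(np.mean(y50[core] ** 2) / np.mean(x50[core] ** 2)))

    x2 = np.sin(2 * np.pi * 2 * t)
    y2 = bandpass(x2, fs)
    atten_2_db = float(
        20 * np.log10(np.sqrt(np.mean(x2**2)) / max(np.sqrt(np.mean(y2**2)), 1e-300))
    )

    env = linear_envelope(np.ones(int(5 * fs)), fs)
    dc_gain = float(env.mean())
    return {"gain_50hz": gain_50, "attenuation_2hz_db": atten_2_db,
            "envelope_dc_gain": dc_gain}
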