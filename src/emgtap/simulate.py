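"""Forward generator of tapping-EMG cohorts with known ground truth.

Each recording is burst-modulated band-limited noise: a quasi-periodic
renewal train of tap times (Gamma inter-tap intervals with configurable
coefficient of variation), each tap contributing a Hann-shaped amplitude
pulse that modulates a 20-450 Hz unit-variance noise carrier, on top of
baseline instrumentation noise.  The tap rate encodes bradykinesia severity:
PD subjects tap slowly OFF medication, faster ON, and healthy controls
fastest.  MDS-UPDRS-like item scores are an antitone (noisy affine-clip)
function of the subject's true tap rate, so score-feature correlations and
score regression have a known direction.

The generator returns every recording together with :class:`SimTruth`
(tap times, true rates, per-channel burst amplitudes, generated scores), so
recovery of the truth by the analysis pipeline is testable end-to-end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from emgtap.io import (
    ChannelLabel,
    ClinicalScores,
    CohortManifest,
    EmgRecording,
    UPPER_LIMB_ITEMS,
    save_recording,
    save_scores,
)

DEFAULT_CHANNELS = (
    ("flexors", "left"),
    ("extensors", "left"),
    ("flexors", "right"),
    ("extensors", "right"),
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generation parameters (defaults emulate the study setup:
    6 PD patients recorded OFF and ON, 7 healthy controls recorded once,
    23-s recordings at 1260 Hz)."""

    n_pd: int = 6
    n_healthy: int = 7
    duration_s: float = 23.0
    fs: float = 1260.0
    rate_pd_off_hz: float = 1.5
    rate_pd_on_hz: float = 3.0
    rate_healthy_hz: float = 4.0
    rate_between_subject_sd: float = 0.3
    jitter_cv: float = 0.1
    burst_width_s: float = 0.120
    burst_amplitude_mv: float = 0.5
    amplitude_between_subject_sigma: float = 0.4  # lognormal sigma
    sequence_decrement: float = 0.0  # fractional amplitude loss by the last tap
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    baseline_noise_sd_mv: float = 0.02
    tremor_amplitude_mv: float = 0.0
    tremor_freq_hz: float = 5.0
    score_noise_sd: float = 0.3
    tasks: tuple[str, ...] = ("finger_tapping", "hand_movements")
    channels: tuple[tuple[str, str], ...] = DEFAULT_CHANNELS
    seed: int = 0

    def validate(self) -> None:
        if min(self.rate_pd_off_hz, self.rate_pd_on_hz, self.rate_healthy_hz) <= 0:
            raise ValueError("tap rates must be positive")
        if not self.rate_pd_off_hz < self.rate_pd_on_hz <= self.rate_healthy_hz:
            raise ValueError("need rate_pd_off < rate_pd_on <= rate_healthy")
        if self.fs <= 2 * self.carrier_band_hz[1]:
            raise ValueError("fs must exceed twice the carrier band upper edge")


@dataclass
class SimTruth:
    """Ground truth per recording and per subject x condition."""

    tap_times: dict = field(default_factory=dict)      # rec key -> list of times (s)
    true_rate_hz: dict = field(default_factory=dict)   # rec key -> subject rate
    burst_amplitudes: dict = field(default_factory=dict)  # rec key -> {channel: a0}
    scores: dict = field(default_factory=dict)         # (subject, cond) -> totals

    def to_json(self) -> str:
        def keyed(d):
            return {"|".join(k) if isinstance(k, tuple) else k: v for k, v in d.items()}

        return json.dumps(
            {
                "tap_times": keyed(self.tap_times),
                "true_rate_hz": keyed(self.true_rate_hz),
                "burst_amplitudes": keyed(self.burst_amplitudes),
                "scores": keyed(self.scores),
            },
            indent=2,
        )


@dataclass
class Cohort:
    """In-memory generated cohort."""

    recordings: list[EmgRecording]
    scores: list[ClinicalScores]
    truth: SimTruth
    config: SimConfig


def simulate_tap_times(
    rate_hz: float, duration_s: float, jitter_cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Renewal tap process: Gamma intervals with mean 1/rate and CV jitter_cv.

    ``jitter_cv = 0`` degenerates to exact periodic tapping.  The first tap
    falls one interval after t = 0; times are truncated to (0, duration).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    mean_iti = 1.0 / rate_hz
    n_max = int(np.ceil(duration_s * rate_hz * 2 + 20))
    if jitter_cv == 0:
        intervals = np.full(n_max, mean_iti)
    else:
        shape = 1.0 / jitter_cv**2
        scale = mean_iti / shape
        intervals = rng.gamma(shape, scale, size=n_max)
    times = np.cumsum(intervals)
    return times[times < duration_s]


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (4th-order Butterworth)."""
    high = min(band[1], 0.999 * fs / 2)
    sos = sps.butter(4, [band[0], high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def render_emg(
    tap_times: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    amplitude_mv: float | None = None,
) -> np.ndarray:
    """Render one channel: Hann burst pulses x band-limited carrier + noise.

    The k-th burst amplitude is ``a0 * (1 - delta * k / (K - 1))`` so that a
    sequence-effect decrement ``delta`` scales the last burst to
    ``(1 - delta) * a0``.
    """
    n = int(round(config.duration_s * config.fs))
    a0 = config.burst_amplitude_mv if amplitude_mv is None else amplitude_mv
    t = np.arange(n) / config.fs
    modulation = np.zeros(n)
    width = int(round(config.burst_width_s * config.fs))
    pulse = np.hanning(width)
    k_total = len(tap_times)
    for k, tk in enumerate(tap_times):
        decr = config.sequence_decrement * (k / (k_total - 1) if k_total > 1 else 0.0)
        a_k = a0 * (1.0 - decr)
        start = int(round(tk * config.fs)) - width // 2
        lo, hi = max(start, 0), min(start + width, n)
        if hi > lo:
            modulation[lo:hi] += a_k * pulse[lo - start : hi - start]
    signal = modulation * _bandlimited_noise(n, config.fs, config.carrier_band_hz, rng)
    signal = signal + config.baseline_noise_sd_mv * rng.standard_normal(n)
    if config.tremor_amplitude_mv > 0:
        tremor_mod = config.tremor_amplitude_mv * 0.5 * (
            1 + np.sin(2 * np.pi * config.tremor_freq_hz * t)
        )
        signal = signal + tremor_mod * _bandlimited_noise(
            n, config.fs, config.carrier_band_hz, rng
        )
    return signal


def simulate_scores(
    true_rate_hz: float,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str,
    condition: str,
) -> ClinicalScores:
    """Item scores as a noisy antitone map of the tap rate.

    Each upper-limb motor item is ``clip(round(4.5 - rate + N(0, sigma)), 0, 4)``
    (round half up, so the map is deterministic and monotone at sigma = 0);
    the Part-III total is the sum of the nine items.
    """
    if true_rate_hz <= 0:
        raise ValueError("rate must be positive")
    items = {}
    for key in UPPER_LIMB_ITEMS:
        raw = 4.5 - true_rate_hz + config.score_noise_sd * rng.standard_normal()
        items[key] = int(np.clip(np.floor(raw + 0.5), 0, 4))
    total = int(sum(items.values()))
    return ClinicalScores(
        subject_id=subject_id, condition=condition, items=items, total_part3=total
    )


def _subject_rates(config: SimConfig, rng: np.random.Generator, group: str) -> dict:
    """Per-condition mean tap rates for one subject.

    Rates are drawn independently per condition around the group-condition
    means, so PD subjects differ in how strongly levodopa speeds their
    tapping (variable medication response) — the between-subject variance
    that the OFF-ON difference analyses measure.
    """
    sd = config.rate_between_subject_sd

    def draw(mean: float) -> float:
        return max(0.2, mean + sd * rng.standard_normal())

    if group == "pd":
        return {"off": draw(config.rate_pd_off_hz), "on": draw(config.rate_pd_on_hz)}
    return {"na": draw(config.rate_healthy_hz)}


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate the full in-memory cohort.

    PD subjects get OFF and ON recordings for every task; healthy subjects
    one recording per task (condition ``na``).  All randomness flows from
    ``config.seed``; identical configs give identical cohorts.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    channels = [ChannelLabel(m, s) for m, s in config.channels]
    recordings: list[EmgRecording] = []
    scores: list[ClinicalScores] = []
    truth = SimTruth()

    subjects = [("pd", f"pd{i + 1:02d}") for i in range(config.n_pd)] + [
        ("healthy", f"hc{i + 1:02d}") for i in range(config.n_healthy)
    ]
    for group, subject_id in subjects:
        rates = _subject_rates(config, rng, group)
        amps = {
            c.column: config.burst_amplitude_mv
            * np.exp(config.amplitude_between_subject_sigma * rng.standard_normal())
            for c in channels
        }
        for condition, rate in rates.items():
            for task in config.tasks:
                taps = simulate_tap_times(
                    rate, config.duration_s, config.jitter_cv, rng
                )
                samples = np.stack(
                    [
                        render_emg(taps, config, rng, amplitude_mv=amps[c.column])
                        for c in channels
                    ]
                )
                rec = EmgRecording(
                    samples=samples,
                    sampling_rate_hz=config.fs,
                    channels=list(channels),
                    subject_id=subject_id,
                    group=group,
                    condition=condition,
                    task=task,
                )
                recordings.append(rec)
                key = (subject_id, condition, task)
                truth.tap_times[key] = taps.tolist()
                truth.true_rate_hz[key] = rate
                truth.burst_amplitudes[key] = amps
            if group == "pd":
                sc = simulate_scores(rate, config, rng, subject_id, condition)
                scores.append(sc)
                truth.scores[(subject_id, condition)] = {
                    "total_part3": sc.total_part3,
                    "upper_limb_subtotal": sc.upper_limb_subtotal,
                }
    return Cohort(recordings=recordings, scores=scores, truth=truth, config=config)


def write_cohort(cohort: Cohort, out_dir: Path) -> CohortManifest:
    """Persist a cohort in the package's CSV/JSON formats plus sim_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = CohortManifest(notes="synthetic tapping-EMG cohort")
    for rec in cohort.recordings:
        stem = f"{rec.subject_id}_{rec.condition}_{rec.task}"
        csv_path = out_dir / f"{stem}.csv"
        meta_path = out_dir / f"{stem}.json"
        save_recording(rec, csv_path, meta_path)
        manifest.entries.append(
            {
                "subject_id": rec.subject_id,
                "condition": rec.condition,
                "task": rec.task,
                "recording": csv_path.name,
                "metadata": meta_path.name,
            }
        )
    save_scores(cohort.scores, out_dir / "scores.csv")
    manifest.scores_path = "scores.csv"
    manifest.save(out_dir / "manifest.json")
    (out_dir / "sim_truth.json").write_text(cohort.truth.to_json())
    manifest.validate(root=out_dir)
    return manifest


def generate_cohort(config: SimConfig | None = None, out_dir: Path | None = None):
    """Simulate and (optionally) persist a cohort; returns (cohort, manifest)."""
    cohort = simulate_cohort(config)
    manifest = write_cohort(cohort, out_dir) if out_dir is not None else None
    return cohort, manifest


def file_hashes(directory: Path) -> dict[str, str]:
    """SHA-256 of every file in a cohort directory (determinism checks)."""
    out = {}
    for p in sorted(Path(directory).iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out
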