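"""Data model and CSV/JSON readers/writers for recordings, manifests and scores.

A recording is a plain CSV (``time_s`` column plus one column per channel, in
millivolts) with a sidecar JSON holding the metadata (subject, group,
condition, task, nominal sampling rate, channel labels).  Clinical scores are
one CSV row per (subject, condition) with the nine upper-limb MDS-UPDRS III
items and the Part-III total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: MDS-UPDRS III items whose sum forms the upper-limb subtotal: rigidity of
#: the right/left upper extremity (3.3b/3.3c), finger tapping (3.4), hand
#: movements (3.5), pronation-supination (3.6), postural tremor (3.15),
#: kinetic tremor (3.16) and rest-tremor amplitude right/left (3.17a/3.17b).
UPPER_LIMB_ITEMS: tuple[str, ...] = (
    "3.3b", "3.3c", "3.4", "3.5", "3.6", "3.15", "3.16", "3.17a", "3.17b",
)

MUSCLES = ("flexors", "extensors")
SIDES = ("left", "right")
GROUPS = ("pd", "healthy")
CONDITIONS = ("off", "on", "na")
TASKS = ("finger_tapping", "hand_movements")


class FormatError(ValueError):
    """A file does not conform to the recording/scores schema."""


@dataclass(frozen=True)
class ChannelLabel:
    muscle: str  # flexors | extensors
    side: str    # left | right

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle group {self.muscle!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def column(self) -> str:
        return f"{self.muscle}_{self.side}"

    @classmethod
    def from_column(cls, name: str) -> "ChannelLabel":
        muscle, _, side = name.partition("_")
        return cls(muscle, side)


@dataclass
class EmgRecording:
    """Multi-channel sEMG recording with subject/condition/task metadata.

    ``samples`` is a (n_channels, n_samples) float array in millivolts.
    ``condition`` is ``"na"`` exactly for healthy subjects, who are recorded
    once (no medication state).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channels: list[ChannelLabel]
    subject_id: str
    group: str
    condition: str
    task: str
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if (self.condition == "na") != (self.group == "healthy"):
            raise ValueError("condition is 'na' if and only if group is 'healthy'")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("channel count does not match sample matrix")
        pairs = [(c.muscle, c.side) for c in self.channels]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate channel (muscle, side) labels")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, muscle: str, side: str) -> np.ndarray:
        for i, c in enumerate(self.channels):
            if (c.muscle, c.side) == (muscle, side):
                return self.samples[i]
        raise KeyError(f"no channel ({muscle}, {side})")


@dataclass
class ClinicalScores:
    """Per (subject, condition) MDS-UPDRS III upper-limb items and totals."""

    subject_id: str
    condition: str  # off | on
    items: dict[str, int]
    total_part3: int
    upper_limb_subtotal: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("off", "on"):
            raise ValueError("scores condition must be 'off' or 'on'")
        missing = set(UPPER_LIMB_ITEMS) - set(self.items)
        if missing:
            raise ValueError(f"missing items: {sorted(missing)}")
        for k, v in self.items.items():
            if not 0 <= int(v) <= 4:
                raise ValueError(f"item {k} score {v} outside [0, 4]")
        subtotal = int(sum(self.items[k] for k in UPPER_LIMB_ITEMS))
        if self.upper_limb_subtotal is None:
            self.upper_limb_subtotal = subtotal
        elif self.upper_limb_subtotal != subtotal:
            raise ValueError("upper_limb_subtotal does not equal the item sum")
        if self.total_part3 < self.upper_limb_subtotal:
            raise ValueError("total_part3 smaller than the upper-limb subtotal")


@dataclass
class CohortManifest:
    """List of recording/metadata paths plus a scores-file reference."""

    entries: list[dict] = field(default_factory=list)
    scores_path: str | None = None
    notes: str = ""

    def validate(self, root: Path | None = None) -> None:
        root = Path(root) if root is not None else Path(".")
        keys = set()
        for e in self.entries:
            for p in (e["recording"], e["metadata"]):
                if not (root / p).exists():
                    raise FormatError(f"manifest path not resolvable: {p}")
            key = (e["subject_id"], e["condition"], e["task"])
            if key in keys:
                raise FormatError(f"duplicate manifest entry for {key}")
            keys.add(key)
        if self.scores_path is not None and not (root / self.scores_path).exists():
            raise FormatError(f"scores path not resolvable: {self.scores_path}")

    def save(self, path: Path) -> None:
        payload = {
            "entries": self.entries,
            "scores_path": self.scores_path,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: Path) -> "CohortManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def load_recording(path: Path, meta_path: Path) -> EmgRecording:
    """Read a recording CSV plus its sidecar JSON into an :class:`EmgRecording`.

    The declared metadata is authoritative for the sampling rate; the time
    column is only checked for strict monotonicity.
    """
    meta = json.loads(Path(meta_path).read_text())
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty recording CSV: {path}") from exc
    if "time_s" not in df.columns:
        raise FormatError("recording CSV lacks a 'time_s' column")
    if len(df) == 0:
        raise FormatError(f"recording CSV has no rows: {path}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise FormatError("time column is not strictly increasing")

    channels = [ChannelLabel(**c) for c in meta["channels"]]
    expected = [c.column for c in channels]
    present = [c for c in df.columns if c != "time_s"]
    if sorted(expected) != sorted(present):
        raise FormatError(
            f"channel columns {present} do not match metadata {expected}"
        )
    samples = np.stack([df[c].to_numpy(dtype=float) for c in expected])
    return EmgRecording(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channels=channels,
        subject_id=str(meta["subject_id"]),
        group=meta["group"],
        condition=meta["condition"],
        task=meta["task"],
        t0_s=float(meta.get("t0_s", 0.0)),
    )


def save_recording(rec: EmgRecording, path: Path, meta_path: Path,
                   float_format: str = "%.6f") -> None:
    """Write the CSV + sidecar JSON pair read back by :func:`load_recording`."""
    t = rec.t0_s + np.arange(rec.n_samples) / rec.sampling_rate_hz
    df = pd.DataFrame({"time_s": t})
    for label, row in zip(rec.channels, rec.samples):
        df[label.column] = row
    df.to_csv(path, index=False, float_format=float_format)
    meta = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "condition": rec.condition,
        "task": rec.task,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "t0_s": rec.t0_s,
        "channels": [{"muscle": c.muscle, "side": c.side} for c in rec.channels],
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_scores(path: Path) -> list[ClinicalScores]:
    """Read the scores CSV (one row per subject x condition).

    ``upper_limb_subtotal`` is recomputed from the items; if the CSV carries
    the column it must agree with the sum.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    out = []
    for _, row in df.iterrows():
        items = {k: int(row[f"item_{k}"]) for k in UPPER_LIMB_ITEMS}
        subtotal = (
            int(row["upper_limb_subtotal"])
            if "upper_limb_subtotal" in df.columns
            else None
        )
        out.append(
            ClinicalScores(
                subject_id=str(row["subject_id"]),
                condition=str(row["condition"]),
                items=items,
                total_part3=int(row["total_part3"]),
                upper_limb_subtotal=subtotal,
            )
        )
    return out


def save_scores(scores: Iterable[ClinicalScores], path: Path) -> None:
    rows = []
    for s in scores:
        row = {"subject_id": s.subject_id, "condition": s.condition}
        row.update({f"item_{k}": s.items[k] for k in UPPER_LIMB_ITEMS})
        row["total_part3"] = s.total_part3
        row["upper_limb_subtotal"] = s.upper_limb_subtotal
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
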