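"""Prominence-thresholded muscle-activation peaks on the linear envelope.

Each tap or hand-open/close movement produces one activation burst, hence one
envelope peak.  A peak's prominence — its height above the higher of the two
base minima, where each base is the minimum between the peak and the nearest
strictly higher sample (or the signal edge) on that side — separates genuine
activation maxima from envelope ripple.  Peaks are kept when their prominence
reaches a per-signal threshold expressed as a fraction of the envelope's
dynamic range, which makes selection unit-free and scale-equivariant.

Three whole-recording features summarise the selected peaks: their count
(movement repetitions), the median peak amplitude (contraction power, mV) and
the mean inter-peak interval (movement period, s).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PeakSet:
    """Selected envelope peaks with their prominences and the threshold used."""

    indices: np.ndarray      # strictly increasing sample indices
    magnitudes: np.ndarray   # envelope value at each index (mV)
    prominences: np.ndarray  # >= threshold_mv
    threshold_mv: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if not (len(self.indices) == len(self.magnitudes) == len(self.prominences)):
            raise ValueError("indices/magnitudes/prominences length mismatch")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class BurstFeatures:
    """The three whole-recording activation-peak features.

    ``median_peak_amplitude_mv`` is NaN when no peak was found and
    ``mean_inter_peak_interval_s`` is NaN with fewer than two peaks.
    """

    n_peaks: int
    median_peak_amplitude_mv: float
    mean_inter_peak_interval_s: float


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima; plateaus collapse to their midpoint.

    A maximal run of equal values ``x[s..e]`` is a local maximum when the
    sample before it is strictly lower and the sample after it is strictly
    lower; the run is reported once, at ``s + (e - s) // 2`` (left-of-centre
    for even plateau widths).  Endpoints are never returned.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            # walk the plateau starting at i
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append(i + (j - i) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def prominence(x: np.ndarray, peak_index: int) -> float:
    """Prominence of a single local maximum via a contour scan on each side.

    On each side, scan away from the peak until a sample strictly higher than
    the peak (or the signal edge); the side's base is the minimum over the
    scanned range.  Prominence is peak height minus the higher base.
    """
    x = np.asarray(x, dtype=float)
    i = int(peak_index)
    if not 0 < i < x.size - 1:
        raise ValueError("peak index must be interior")
    _validate_maximum(x, i)
    h = x[i]
    left = x[:i]
    higher = np.nonzero(left > h)[0]
    lo = higher[-1] + 1 if higher.size else 0
    left_min = x[lo : i + 1].min()
    right = x[i + 1 :]
    higher = np.nonzero(right > h)[0]
    hi = i + 1 + higher[0] if higher.size else x.size
    right_min = x[i:hi].min()
    p = h - max(left_min, right_min)
    if p < 0:
        raise ValueError(f"index {i} is not a local maximum")
    return float(p)


def _validate_maximum(x: np.ndarray, i: int) -> None:
    """Raise unless ``i`` lies on a local-maximum plateau of ``x``."""
    h = x[i]
    j = i
    while j > 0 and x[j - 1] == h:
        j -= 1
    k = i
    while k < x.size - 1 and x[k + 1] == h:
        k += 1
    if j == 0 or k == x.size - 1 or x[j - 1] >= h or x[k + 1] >= h:
        raise ValueError(f"index {i} is not a local maximum")


def select_peaks(envelope: np.ndarray, rel_threshold: float = 0.1) -> PeakSet:
    """All local maxima whose prominence reaches the per-signal threshold.

    ``threshold_mv = rel_threshold * (max - min)`` of the envelope.  A flat
    envelope yields an empty :class:`PeakSet` (threshold 0) with a warning.
    """
    x = np.asarray(envelope, dtype=float)
    if rel_threshold < 0:
        raise ValueError("rel_threshold must be non-negative")
    dyn = float(x.max() - x.min()) if x.size else 0.0
    if dyn == 0.0:
        logger.warning("flat envelope: no peaks selectable")
        empty = np.empty(0)
        return PeakSet(empty, empty, empty, threshold_mv=0.0)
    threshold = rel_threshold * dyn
    idx = local_maxima(x)
    proms = np.array([prominence(x, i) for i in idx])
    keep = proms >= threshold
    return PeakSet(idx[keep], x[idx[keep]], proms[keep], threshold_mv=threshold)


def burst_features(peaks: PeakSet, fs: float) -> BurstFeatures:
    """Count, median amplitude and mean inter-peak interval of a PeakSet."""
    n = len(peaks)
    median = float(np.median(peaks.magnitudes)) if n else math.nan
    interval = (
        float(np.mean(np.diff(peaks.indices)) / fs) if n >= 2 else math.nan
    )
    return BurstFeatures(
        n_peaks=n,
        median_peak_amplitude_mv=median,
        mean_inter_peak_interval_s=interval,
    )


def envelope_burst_features(
    envelope: np.ndarray, fs: float, rel_threshold: float = 0.1
) -> BurstFeatures:
    """Convenience: select peaks then summarise them."""
    return burst_features(select_peaks(envelope, rel_threshold), fs)


def peaks_to_table(peaks: PeakSet, fs: float):
    """Peak table as a DataFrame: ``index,time_s,magnitude_mv,prominence_mv``."""
    import pandas as pd

    return pd.DataFrame(
        {
            "index": peaks.indices,
            "time_s": peaks.indices / fs,
            "magnitude_mv": peaks.magnitudes,
            "prominence_mv": peaks.prominences,
        }
    )
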