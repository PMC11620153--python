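"""Windowed time-domain sEMG feature banks and the per-cohort feature table.

Feature sets
------------
* Hudgins set: MAV, ZC, WL, SSC.
* Du set: IAV, VAR, WL, ZC, SSC, WAMP.
* Extended additions: MAV1 and MAV2 (centre-weighted mean absolute values),
  approximate entropy (ApEn) and sample entropy (SampEn), plus the
  whole-recording activation-peak count and mean inter-peak interval.

Signals are segmented into 1-s windows with 0.5-s overlap, a Hann taper is
applied, features are computed per window and averaged per channel.  Count
thresholds (ZC/SSC/WAMP) default to 0.05x the window standard deviation so
the counts are invariant to amplitude rescaling; entropies use the standard
m = 2, r = 0.2 x SD, Chebyshev distance.  Standardization (z-scoring) is
fitted on a designated row subset so that cross-validation can reuse training
statistics on held-out rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from emgtap.bursts import envelope_burst_features
from emgtap.preprocess import PreprocessParams, preprocess_recording

logger = logging.getLogger(__name__)

try:  # pairwise template counting is the hot loop; JIT it when available
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


STANDARD_FEATURES = ("MAV", "ZC", "WL", "SSC", "IAV", "VAR", "WAMP")
EXTENDED_FEATURES = STANDARD_FEATURES + ("MAV1", "MAV2", "ApEn", "SampEn")
BURST_FEATURES = ("n_peaks", "mean_interval_s")


@dataclass(frozen=True)
class WindowSpec:
    length_s: float = 1.0
    step_s: float = 0.5
    taper: str = "hann"  # hann | rect

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.length_s:
            raise ValueError("need 0 < step_s <= length_s")
        if self.taper not in ("hann", "rect"):
            raise ValueError("taper must be 'hann' or 'rect'")


@dataclass(frozen=True)
class FeatureParams:
    """Thresholds and entropy parameters.

    ``eps_*_rel`` are fractions of the window standard deviation; set
    ``eps_*_abs`` to use fixed absolute thresholds instead.
    """

    eps_zc_rel: float = 0.05
    eps_ssc_rel: float = 0.05
    eps_wamp_rel: float = 0.05
    eps_zc_abs: float | None = None
    eps_ssc_abs: float | None = None
    eps_wamp_abs: float | None = None
    entropy_m: int = 2
    entropy_r_factor: float = 0.2

    def thresholds(self, window: np.ndarray) -> tuple[float, float, float]:
        sd = float(np.std(window))
        return (
            self.eps_zc_abs if self.eps_zc_abs is not None else self.eps_zc_rel * sd,
            self.eps_ssc_abs if self.eps_ssc_abs is not None else self.eps_ssc_rel * sd,
            self.eps_wamp_abs if self.eps_wamp_abs is not None else self.eps_wamp_rel * sd,
        )


def segment(x: np.ndarray, fs: float, spec: WindowSpec | None = None) -> list[np.ndarray]:
    """Overlapping windows ``[k*step, k*step + len)`` with optional Hann taper."""
    spec = spec or WindowSpec()
    x = np.asarray(x, dtype=float)
    wlen = int(round(spec.length_s * fs))
    step = int(round(spec.step_s * fs))
    if x.size < wlen:
        raise ValueError("signal shorter than one window")
    n_win = (x.size - wlen) // step + 1
    taper = np.hanning(wlen) if spec.taper == "hann" else np.ones(wlen)
    return [x[k * step : k * step + wlen] * taper for k in range(n_win)]


# -- individual feature formulas ------------------------------------------------

def _zc(x: np.ndarray, eps: float) -> int:
    s = np.sign(x)
    return int(np.sum((s[:-1] * s[1:] < 0) & (np.abs(np.diff(x)) >= eps)))


def _ssc(x: np.ndarray, eps: float) -> int:
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.sum((d1 * d2 > 0) & (np.maximum(np.abs(d1), np.abs(d2)) >= eps)))


def hudgins(window: np.ndarray, params: FeatureParams | None = None) -> dict[str, float]:
    """MAV, ZC, WL, SSC of one window."""
    params = params or FeatureParams()
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("window too short")
    eps_zc, eps_ssc, _ = params.thresholds(x)
    return {
        "MAV": float(np.mean(np.abs(x))),
        "ZC": float(_zc(x, eps_zc)),
        "WL": float(np.sum(np.abs(np.diff(x)))),
        "SSC": float(_ssc(x, eps_ssc)),
    }


def du(window: np.ndarray, params: FeatureParams | None = None) -> dict[str, float]:
    """IAV, VAR, WL, ZC, SSC, WAMP of one window (VAR uses 1/(N-1) of x^2)."""
    params = params or FeatureParams()
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("window too short")
    eps_zc, eps_ssc, eps_wamp = params.thresholds(x)
    return {
        "IAV": float(np.sum(np.abs(x))),
        "VAR": float(np.sum(x**2) / (x.size - 1)),
        "WL": float(np.sum(np.abs(np.diff(x)))),
        "ZC": float(_zc(x, eps_zc)),
        "SSC": float(_ssc(x, eps_ssc)),
        # a zero difference is no jump, so WAMP stays 0 on constant windows
        # even when the threshold degenerates to 0
        "WAMP": float(np.sum((np.abs(np.diff(x)) >= eps_wamp)
                             & (np.abs(np.diff(x)) > 0))),
    }


def _mav1_weights(n: int) -> np.ndarray:
    i = np.arange(1, n + 1)
    w = np.full(n, 0.5)
    w[(i >= 0.25 * n) & (i <= 0.75 * n)] = 1.0
    return w


def _mav2_weights(n: int) -> np.ndarray:
    i = np.arange(1, n + 1, dtype=float)
    w = np.ones(n)
    low = i < 0.25 * n
    high = i > 0.75 * n
    w[low] = 4 * i[low] / n
    w[high] = 4 * (n - i[high]) / n
    return w


@njit(cache=True)
def _entropy_counts(y: np.ndarray, m: int, r: float):  # pragma: no cover - jitted
    """Chebyshev template-match counts for embedding dims m and m+1.

    Returns (c_m, c_m1, a, b): per-template match counts including
    self-matches for templates of length m (c_m, size N-m+1) and m+1 (c_m1,
    size N-m), plus the SampEn pair counts a (length m+1) and b (length m)
    over unordered pairs i < j restricted to the first N-m templates.
    """
    n = y.shape[0]
    n_m = n - m + 1
    n_m1 = n - m
    c_m = np.ones(n_m)   # self-matches included
    c_m1 = np.ones(n_m1)
    a = 0.0
    b = 0.0
    for i in range(n_m):
        for j in range(i + 1, n_m):
            d = 0.0
            for k in range(m):
                t = abs(y[i + k] - y[j + k])
                if t > d:
                    d = t
            if d <= r:
                c_m[i] += 1.0
                c_m[j] += 1.0
                if j < n_m1:  # implies i < n_m1
                    b += 1.0
                    # (m+1)-template distance = max(d, last-element distance)
                    if abs(y[i + m] - y[j + m]) <= r:
                        a += 1.0
                        c_m1[i] += 1.0
                        c_m1[j] += 1.0
    return c_m, c_m1, a, b


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = phi^m - phi^(m+1), self-matches included.

    ``r`` defaults to 0.2x the window SD (Chebyshev distance).
    """
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError("window too short for the embedding dimension")
    if r is None:
        r = 0.2 * float(np.std(x))
    c_m, c_m1, _, _ = _entropy_counts(x, m, float(r))
    phi_m = np.mean(np.log(c_m / c_m.size))
    phi_m1 = np.mean(np.log(c_m1 / c_m1.size))
    return float(phi_m - phi_m1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B), self-matches excluded; NaN when A or B is 0."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        raise ValueError("window too short for the embedding dimension")
    if r is None:
        r = 0.2 * float(np.std(x))
    _, _, a, b = _entropy_counts(x, m, float(r))
    if a == 0.0 or b == 0.0:
        return math.nan
    return float(-math.log(a / b))


def extended(window: np.ndarray, params: FeatureParams | None = None) -> dict[str, float]:
    """MAV1, MAV2, ApEn, SampEn of one window (SampEn may be NaN)."""
    params = params or FeatureParams()
    x = np.asarray(window, dtype=float)
    if x.size < params.entropy_m + 2:
        raise ValueError("window too short")
    sd = float(np.std(x))
    r = params.entropy_r_factor * sd
    if sd == 0.0:
        # constant window: perfectly regular
        apen, sampen = 0.0, 0.0
    else:
        # one pairwise pass serves both entropies
        c_m, c_m1, a, b = _entropy_counts(x, params.entropy_m, r)
        apen = float(
            np.mean(np.log(c_m / c_m.size)) - np.mean(np.log(c_m1 / c_m1.size))
        )
        sampen = float(-math.log(a / b)) if a > 0 and b > 0 else math.nan
    ax = np.abs(x)
    return {
        "MAV1": float(np.mean(_mav1_weights(x.size) * ax)),
        "MAV2": float(np.mean(_mav2_weights(x.size) * ax)),
        "ApEn": apen,
        "SampEn": sampen,
    }


def window_features(
    window: np.ndarray, params: FeatureParams, feature_set: str
) -> dict[str, float]:
    """Union of the per-window formulas for ``feature_set`` standard|extended."""
    out = hudgins(window, params)
    out.update(du(window, params))
    if feature_set == "extended":
        out.update(extended(window, params))
    return out


def channel_features(
    x: np.ndarray,
    fs: float,
    window_spec: WindowSpec | None = None,
    params: FeatureParams | None = None,
    feature_set: str = "extended",
) -> dict[str, float]:
    """Per-window features averaged over windows for one channel.

    Windows where SampEn is undefined (no template matches) are excluded from
    the SampEn mean; if every window is undefined the value falls back to 0
    (flagged via a log message).
    """
    window_spec = window_spec or WindowSpec()
    params = params or FeatureParams()
    rows = [window_features(w, params, feature_set) for w in segment(x, fs, window_spec)]
    names = rows[0].keys()
    out = {}
    for name in names:
        vals = np.array([r[name] for r in rows], dtype=float)
        ok = ~np.isnan(vals)
        if not ok.any():
            logger.warning("feature %s undefined in every window; falling back to 0", name)
            out[name] = 0.0
        else:
            out[name] = float(vals[ok].mean())
    return out


# -- cohort-level table ---------------------------------------------------------

@dataclass
class FeatureTable:
    """Rows keyed by (subject, condition, task); columns = feature x channel.

    ``scaler`` holds the fitted standardization state (means/SDs and the fit
    subset) after :func:`standardize`.
    """

    data: pd.DataFrame  # indexed by (subject_id, condition, task)
    feature_set: str
    scaler: dict | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)


def build_table(
    recordings,
    preproc: PreprocessParams | None = None,
    window_spec: WindowSpec | None = None,
    params: FeatureParams | None = None,
    feature_set: str = "extended",
    include_burst: bool | None = None,
    rel_threshold: float = 0.1,
) -> FeatureTable:
    """Preprocess every recording and assemble the per-row feature vectors.

    Windowed features are computed on the band-passed trimmed signal; the
    whole-recording activation-peak count and mean inter-peak interval are
    computed on the linear envelope and appended per channel when
    ``include_burst`` (default: exactly for the extended set).
    """
    preproc = preproc or PreprocessParams()
    if include_burst is None:
        include_burst = feature_set == "extended"
    rows = {}
    for rec in recordings:
        filtered, envelopes = preprocess_recording(rec, preproc)
        row = {}
        for label, y, env in zip(rec.channels, filtered, envelopes):
            feats = channel_features(
                y, rec.sampling_rate_hz, window_spec, params, feature_set
            )
            for name, value in feats.items():
                row[f"{name}__{label.column}"] = value
            if include_burst:
                bf = envelope_burst_features(
                    env.samples, rec.sampling_rate_hz, rel_threshold
                )
                row[f"n_peaks__{label.column}"] = float(bf.n_peaks)
                iv = bf.mean_inter_peak_interval_s
                row[f"mean_interval_s__{label.column}"] = (
                    iv if not math.isnan(iv) else 0.0
                )
        rows[(rec.subject_id, rec.condition, rec.task)] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(
        df.index, names=["subject_id", "condition", "task"]
    )
    if df.isna().any().any():
        raise ValueError("feature table contains missing values")
    return FeatureTable(data=df.sort_index(), feature_set=feature_set)


def standard_subset(table: FeatureTable) -> FeatureTable:
    """Slice an extended table down to the standard (Hudgins + Du) columns.

    Equivalent to rebuilding with ``feature_set="standard"`` since every
    per-window formula is independent of the others.
    """
    keep = [
        c for c in table.data.columns if c.split("__")[0] in STANDARD_FEATURES
    ]
    return FeatureTable(data=table.data[keep].copy(), feature_set="standard")


def standardize(table: FeatureTable, fit_rows=None) -> FeatureTable:
    """Z-score columns using statistics fitted on ``fit_rows`` only.

    ``fit_rows`` is an index subset (default: all rows).  Zero-SD columns on
    the fit subset map to 0 everywhere (flagged).  The fitted means/SDs are
    stored so held-out rows are transformed with training statistics.
    """
    df = table.data
    fit = df if fit_rows is None else df.loc[fit_rows]
    if len(fit) == 0:
        raise ValueError("empty fit subset")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "constant columns standardized to 0: %s",
            list(sd.index[degenerate]),
        )
    safe_sd = sd.replace(0.0, 1.0)
    z = (df - mean) / safe_sd
    z.loc[:, degenerate] = 0.0
    return FeatureTable(
        data=z,
        feature_set=table.feature_set,
        scaler={
            "mean": mean,
            "sd": sd,
            "fit_rows": list(fit.index) if fit_rows is not None else "all",
        },
    )


def apply_standardization(table: FeatureTable, scaler: dict) -> pd.DataFrame:
    """Transform rows with previously fitted statistics (no refitting)."""
    sd = scaler["sd"]
    z = (table.data - scaler["mean"]) / sd.replace(0.0, 1.0)
    z.loc[:, sd == 0] = 0.0
    return z
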