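"""Independent brute-force oracles used to validate the implementation.

Everything here is written as directly as possible from first principles
(linear scans, explicit template enumeration, naive sums of squares) and
never calls the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def oracle_local_maxima(x) -> list[int]:
    """Plateau-aware local maxima by explicit run scanning."""
    x = list(map(float, x))
    n = len(x)
    out = []
    s = 0
    while s < n:
        e = s
        while e + 1 < n and x[e + 1] == x[s]:
            e += 1
        if s > 0 and e < n - 1 and x[s - 1] < x[s] and x[e] > x[e + 1]:
            out.append(s + (e - s) // 2)
        s = e + 1
    return out


def oracle_prominence(x, i: int) -> float:
    """Linear contour scan on each side of peak ``i``."""
    x = list(map(float, x))
    h = x[i]
    left_min = h
    j = i - 1
    while j >= 0 and x[j] <= h:
        left_min = min(left_min, x[j])
        j -= 1
    right_min = h
    j = i + 1
    while j < len(x) and x[j] <= h:
        right_min = min(right_min, x[j])
        j += 1
    return h - max(left_min, right_min)


def oracle_select(x, rel_threshold: float):
    """Threshold = rel * (max - min); keep maxima with prominence >= it."""
    x = list(map(float, x))
    thr = rel_threshold * (max(x) - min(x))
    idx = [i for i in oracle_local_maxima(x) if oracle_prominence(x, i) >= thr]
    return idx, thr


def _cheb(u, v) -> float:
    return max(abs(a - b) for a, b in zip(u, v))


def oracle_apen(x, m: int, r: float) -> float:
    """Direct template-count ApEn (self-matches included)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm: int) -> float:
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for u in templates:
            c = sum(1 for v in templates if _cheb(u, v) <= r)
            total += np.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def oracle_sampen(x, m: int, r: float) -> float:
    """Direct pair-count SampEn (self-matches excluded); NaN when degenerate."""
    x = list(map(float, x))
    n = len(x)
    tm = [x[i : i + m] for i in range(n - m)]
    tm1 = [x[i : i + m + 1] for i in range(n - m)]
    b = sum(
        1 for i in range(len(tm)) for j in range(i + 1, len(tm))
        if _cheb(tm[i], tm[j]) <= r
    )
    a = sum(
        1 for i in range(len(tm1)) for j in range(i + 1, len(tm1))
        if _cheb(tm1[i], tm1[j]) <= r
    )
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def oracle_mixed_anova(subjects) -> dict:
    """Naive sums-of-squares mixed 2x2 partition.

    ``subjects`` is a list of (group, off_value, on_value) tuples.
    """
    ys = [(g, float(a), float(b)) for g, a, b in subjects]
    n = len(ys)
    allvals = [v for _, a, b in ys for v in (a, b)]
    grand = sum(allvals) / len(allvals)
    groups = sorted({g for g, _, _ in ys})
    subj_mean = [(a + b) / 2 for _, a, b in ys]

    ss_group = 0.0
    ss_subj_within = 0.0
    for g in groups:
        members = [i for i, (gg, _, _) in enumerate(ys) if gg == g]
        gm = sum(subj_mean[i] for i in members) / len(members)
        ss_group += 2 * len(members) * (gm - grand) ** 2
        ss_subj_within += 2 * sum((subj_mean[i] - gm) ** 2 for i in members)

    off_mean = sum(a for _, a, _ in ys) / n
    on_mean = sum(b for _, _, b in ys) / n
    ss_cond = n * ((off_mean - grand) ** 2 + (on_mean - grand) ** 2)

    ss_cells = 0.0
    for g in groups:
        members = [i for i, (gg, _, _) in enumerate(ys) if gg == g]
        for col in (1, 2):
            cell = sum(ys[i][col] for i in members) / len(members)
            ss_cells += len(members) * (cell - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_cond

    ss_within = sum(
        (ys[i][col] - subj_mean[i]) ** 2 for i in range(n) for col in (1, 2)
    )
    ss_err_within = ss_within - ss_cond - ss_inter

    df_err = n - 2
    from scipy import stats as spstats

    def src(ss, ss_err):
        f = ss / (ss_err / df_err)
        return {"F": f, "df1": 1, "df2": df_err, "p": float(spstats.f.sf(f, 1, df_err))}

    return {
        "group": src(ss_group, ss_subj_within),
        "condition": src(ss_cond, ss_err_within),
        "interaction": src(ss_inter, ss_err_within),
    }
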