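"""Group-level statistical battery for the ON/OFF x PD/healthy design.

* 2x2 mixed-design ANOVA (between factor: group; within factor: medication
  condition) via the classical univariate sums-of-squares partition with
  subjects nested in group.  Healthy subjects, measured once, have their
  value imputed into both condition cells first.
* Paired t (OFF vs ON within PD) and independent t (PD condition vs healthy;
  Welch by default) with a Bonferroni-adjusted alpha — 0.05 over the four
  muscle-group channels gives 0.0125.
* Spearman rank correlations between activation-peak features and MDS-UPDRS
  III scores, with exact permutation p-values for n <= 8 where the
  t-approximation is unreliable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats


@dataclass
class AnovaResult:
    """F, dfs and p per source of the 2x2 mixed design."""

    sources: dict  # name -> {"F", "df1", "df2", "p", "ss"}

    def __getitem__(self, name: str) -> dict:
        return self.sources[name]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    alpha_adjusted: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha_adjusted


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    x_label: str = "x"
    y_label: str = "y"


def impute_healthy_condition(values: pd.DataFrame) -> pd.DataFrame:
    """Duplicate each healthy subject's single measurement into OFF and ON.

    ``values`` is long-format with columns ``subject_id, group, condition,
    value``; healthy rows carry condition ``na`` and appear exactly once per
    subject, PD rows appear once per condition.
    """
    out = []
    for subject, sub in values.groupby("subject_id", sort=False):
        group = sub["group"].iloc[0]
        if group == "healthy":
            if len(sub) != 1:
                raise ValueError(
                    f"healthy subject {subject} has {len(sub)} measurements"
                )
            for cond in ("off", "on"):
                row = sub.iloc[0].copy()
                row["condition"] = cond
                out.append(row)
        else:
            if sorted(sub["condition"]) != ["off", "on"]:
                raise ValueError(f"pd subject {subject} lacks both conditions")
            out.extend(r for _, r in sub.iterrows())
    return pd.DataFrame(out).reset_index(drop=True)


def mixed_anova_2x2(table: pd.DataFrame) -> AnovaResult:
    """Classical univariate mixed-design partition of a complete 2x2 table.

    ``table`` is long-format with columns ``subject_id, group, condition,
    value``; every subject must have exactly one value per condition.  The
    between-subject error (subjects within groups, df = N - 2) tests the
    group effect; the condition-by-subject error (df = N - 2) tests the
    condition and interaction effects.  Group sums of squares use weighted
    (cell-size) means, the convention of standard repeated-measures ANOVA
    software.
    """
    wide = table.pivot_table(
        index=["subject_id", "group"], columns="condition", values="value"
    )
    if wide.isna().any().any():
        raise ValueError("incomplete subject x condition cells")
    conditions = list(wide.columns)
    if len(conditions) != 2:
        raise ValueError("need exactly two conditions")
    groups = wide.index.get_level_values("group")
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")

    y = wide.to_numpy()  # (N subjects, 2 conditions)
    n_subjects = y.shape[0]
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)

    ss_between_subj = 2.0 * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    ss_subj_within = 0.0
    for g in labels:
        sel = groups == g
        gm = subj_means[sel].mean()
        ss_group += 2.0 * sel.sum() * (gm - grand) ** 2
        ss_subj_within += 2.0 * np.sum((subj_means[sel] - gm) ** 2)

    ss_cond = n_subjects * np.sum((cond_means - grand) ** 2)
    # cell means weighted by group size
    ss_cells = 0.0
    for g in labels:
        sel = groups == g
        cell = y[sel].mean(axis=0)
        ss_cells += sel.sum() * np.sum((cell - grand) ** 2)
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within = np.sum((y - subj_means[:, None]) ** 2)
    ss_err_within = ss_within - ss_cond - ss_inter

    df_err = n_subjects - 2
    if df_err <= 0:
        raise ValueError("need more than two subjects")

    # scale-aware tolerance for exactly-degenerate designs (0/0 -> F = 0)
    ss_total = float(np.sum((y - grand) ** 2))
    tiny = 1e-12 * max(1.0, ss_total)

    def source(ss: float, ss_err: float) -> dict:
        mse = ss_err / df_err
        if mse <= tiny:
            f = 0.0 if ss <= tiny else math.inf
        else:
            f = ss / mse
        p = float(spstats.f.sf(f, 1, df_err)) if math.isfinite(f) else 0.0
        return {"F": float(f), "df1": 1, "df2": df_err, "p": p, "ss": float(ss)}

    return AnovaResult(
        sources={
            "group": source(ss_group, ss_subj_within),
            "condition": source(ss_cond, ss_err_within),
            "interaction": source(ss_inter, ss_err_within),
        }
    )


def paired_t(x_off: np.ndarray, x_on: np.ndarray, alpha_adjusted: float = 0.05) -> TestResult:
    """Two-sided paired t-test on the OFF-ON differences."""
    x_off = np.asarray(x_off, dtype=float)
    x_on = np.asarray(x_on, dtype=float)
    if x_off.shape != x_on.shape or x_off.size < 2:
        raise ValueError("need equal-length samples of size >= 2")
    d = x_off - x_on
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = spstats.ttest_rel(x_off, x_on)
    return TestResult(float(res.statistic), float(x_off.size - 1), float(res.pvalue),
                      alpha_adjusted)


def independent_t(
    x_a: np.ndarray, x_b: np.ndarray, variant: str = "welch",
    alpha_adjusted: float = 0.05,
) -> TestResult:
    """Two-sided independent-samples t-test (Welch default, Student optional)."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.size < 2 or x_b.size < 2:
        raise ValueError("each group needs at least 2 values")
    equal_var = variant == "student"
    res = spstats.ttest_ind(x_a, x_b, equal_var=equal_var)
    if equal_var:
        df = x_a.size + x_b.size - 2.0
    else:
        va, vb = np.var(x_a, ddof=1) / x_a.size, np.var(x_b, ddof=1) / x_b.size
        df = (va + vb) ** 2 / (
            va**2 / (x_a.size - 1) + vb**2 / (x_b.size - 1)
        )
    return TestResult(float(res.statistic), float(df), float(res.pvalue), alpha_adjusted)


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 4) -> float:
    """Per-comparison alpha: family alpha divided by the comparison count."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def _rankdata(x: np.ndarray) -> np.ndarray:
    return spstats.rankdata(x, method="average")


def spearman(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Spearman rho with an exact permutation p-value for n <= 8.

    rho is the Pearson correlation of average ranks; for n <= 8 the two-sided
    p is the exact proportion of permutations of y whose |rho| is at least
    the observed one, otherwise the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need matched samples with n >= 3")
    rx, ry = _rankdata(x), _rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant input: rho undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * spstats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=min(p, 1.0), n=n,
                             x_label=x_label, y_label=y_label)


def delta_correlation_report(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    score_scope: str = "total",
) -> pd.DataFrame:
    """Spearman correlations between peak features and clinical scores.

    ``features``: long-format with columns ``subject_id, condition, channel,
    feature, value`` (features ``n_peaks`` and ``mean_interval_s``), PD
    subjects only, both conditions.  ``scores``: columns ``subject_id,
    condition, total_part3, upper_limb_subtotal``.

    Returns one row per (channel, feature, contrast) where contrast is
    ``delta`` (OFF - ON differences) or ``off``/``on`` (per-condition
    levels), with rho, exact-permutation p and n.
    """
    score_col = "total_part3" if score_scope == "total" else "upper_limb_subtotal"
    s = scores.set_index(["subject_id", "condition"])[score_col]
    f = features.set_index(["subject_id", "condition", "channel", "feature"])["value"]
    rows = []
    for (channel, feature), sub in features.groupby(["channel", "feature"]):
        wide = sub.pivot_table(index="subject_id", columns="condition", values="value")
        subjects = list(wide.index)
        sc_off = np.array([s[(subj, "off")] for subj in subjects], dtype=float)
        sc_on = np.array([s[(subj, "on")] for subj in subjects], dtype=float)
        contrasts = {
            "delta": (wide["off"] - wide["on"], sc_off - sc_on),
            "off": (wide["off"], sc_off),
            "on": (wide["on"], sc_on),
        }
        for name, (fx, sy) in contrasts.items():
            res = spearman(np.asarray(fx, dtype=float), sy,
                           x_label=f"{feature}:{channel}:{name}",
                           y_label=f"{score_col}:{name}")
            rows.append(
                {
                    "channel": channel,
                    "feature": feature,
                    "contrast": name,
                    "scope": score_scope,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                }
            )
    del f
    return pd.DataFrame(rows)
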