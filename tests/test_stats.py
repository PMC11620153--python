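import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from emgtap.stats import (
    bonferroni_alpha,
    delta_correlation_report,
    impute_healthy_condition,
    independent_t,
    mixed_anova_2x2,
    paired_t,
    spearman,
)
from tests.oracles import oracle_mixed_anova


def long_table(subjects):
    """subjects: list of (group, off, on) -> long-format DataFrame."""
    rows = []
    for i, (g, off, on) in enumerate(subjects):
        for c, v in (("off", off), ("on", on)):
            rows.append({"subject_id": f"{g}{i}", "group": g, "condition": c,
                         "value": float(v)})
    return pd.DataFrame(rows)


class TestImputation:
    def test_healthy_duplicated_into_both_conditions(self):
        df = pd.DataFrame([
            {"subject_id": "h1", "group": "healthy", "condition": "na", "value": 5.0},
            {"subject_id": "p1", "group": "pd", "condition": "off", "value": 3.0},
            {"subject_id": "p1", "group": "pd", "condition": "on", "value": 7.0},
        ])
        out = impute_healthy_condition(df)
        h = out[out.subject_id == "h1"]
        assert sorted(h.condition) == ["off", "on"]
        assert (h.value == 5.0).all()
        p = out[out.subject_id == "p1"].set_index("condition").value
        assert p["off"] == 3.0 and p["on"] == 7.0

    def test_healthy_with_two_measurements_rejected(self):
        df = pd.DataFrame([
            {"subject_id": "h1", "group": "healthy", "condition": "na", "value": 5.0},
            {"subject_id": "h1", "group": "healthy", "condition": "na", "value": 6.0},
        ])
        with pytest.raises(ValueError, match="healthy subject h1"):
            impute_healthy_condition(df)


class TestMixedAnova:
    def test_df_structure_6_vs_7(self, rng):
        subjects = [("pd", *rng.standard_normal(2)) for _ in range(6)]
        subjects += [("healthy", *rng.standard_normal(2)) for _ in range(7)]
        res = mixed_anova_2x2(long_table(subjects))
        for source in ("group", "condition", "interaction"):
            assert res[source]["df1"] == 1
            assert res[source]["df2"] == 11

    def test_group_shift_with_no_within_change(self):
        # PD shifted up by 1, every subject identical OFF and ON
        subjects = [("pd", 1.0 + d, 1.0 + d) for d in (0.0, 0.1, -0.1, 0.2)]
        subjects += [("healthy", d, d) for d in (0.0, 0.1, -0.1, 0.2)]
        res = mixed_anova_2x2(long_table(subjects))
        assert res["condition"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["group"]["F"] > 10

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(20):
            subjects = [("pd", *rng.standard_normal(2)) for _ in range(4)]
            subjects += [("healthy", *rng.standard_normal(2)) for _ in range(4)]
            res = mixed_anova_2x2(long_table(subjects))
            expected = oracle_mixed_anova(subjects)
            for source in ("group", "condition", "interaction"):
                assert res[source]["F"] == pytest.approx(
                    expected[source]["F"], abs=1e-8
                )
                assert res[source]["p"] == pytest.approx(
                    expected[source]["p"], abs=1e-8
                )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        subjects = [("pd", *rng.standard_normal(2)) for _ in range(6)]
        subjects += [("healthy", *rng.standard_normal(2)) for _ in range(7)]
        df = long_table(subjects)
        res = mixed_anova_2x2(df)
        aov = pg.mixed_anova(data=df, dv="value", within="condition",
                             between="group", subject="subject_id")
        for source, pg_name in (
            ("group", "group"), ("condition", "condition"),
            ("interaction", "Interaction"),
        ):
            row = aov[aov.Source == pg_name].iloc[0]
            assert res[source]["F"] == pytest.approx(float(row.F), abs=1e-8)
            assert res[source]["df2"] == int(row.DF2)

    def test_incomplete_cells_rejected(self):
        df = long_table([("pd", 1, 2), ("healthy", 3, 4), ("healthy", 1, 2)])
        df = df.drop(index=0)
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova_2x2(df)

    def test_unit_rescaling_invariance(self, rng):
        subjects = [("pd", *rng.standard_normal(2)) for _ in range(5)]
        subjects += [("healthy", *rng.standard_normal(2)) for _ in range(5)]
        df = long_table(subjects)
        scaled = df.assign(value=df.value * 1000.0)
        a, b = mixed_anova_2x2(df), mixed_anova_2x2(scaled)
        for source in ("group", "condition", "interaction"):
            assert a[source]["F"] == pytest.approx(b[source]["F"])


class TestTTests:
    def test_paired_closed_form(self):
        # differences [1,2,3]: t = mean/ (sd/sqrt(3)) = 2 / (1/sqrt(3))
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * math.sqrt(3))
        assert res.df == 2

    def test_paired_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_paired_sign_flip(self):
        a = np.array([3.0, 5.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 2.0, 3.0])
        r1, r2 = paired_t(a, b), paired_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_independent_identical_groups(self):
        r = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_independent_antisymmetry(self, rng):
        a, b = rng.standard_normal(6), rng.standard_normal(7) + 1
        r1, r2 = independent_t(a, b), independent_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_welch_hand_formula(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([3.0, 5.0, 6.0, 9.0])
        res = independent_t(a, b, variant="welch")
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 4
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 3)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.p == pytest.approx(2 * spstats.t.sf(abs(t), df))

    def test_student_variant_df(self):
        res = independent_t([1.0, 2.0], [3.0, 4.0, 5.0], variant="student")
        assert res.df == 3.0

    def test_significance_flag(self):
        res = independent_t(np.zeros(5) + [0, .1, -.1, .05, -.05],
                            np.full(5, 10.0) + [0, .1, -.1, .05, -.05],
                            alpha_adjusted=0.0125)
        assert res.p < 0.0125 and res.significant


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.07, 1, 0.07), (0.05, 5, 0.01)]
    )
    def test_division(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestSpearman:
    def test_perfect_antitone(self):
        res = spearman(np.arange(1, 7), np.arange(6, 0, -1))
        assert res.rho == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(7)
        y = rng.standard_normal(7)
        r1 = spearman(x, y).rho
        r2 = spearman(np.exp(3 * x), y).rho
        assert r1 == pytest.approx(r2)

    def test_tied_data_matches_hand_ranking(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])  # average ranks by hand
        ry = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected)

    def test_exact_permutation_p_small_n(self):
        # n=4, monotone: only 2 of 24 permutations achieve |rho| = 1
        res = spearman([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(2 / 24)

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        res = spearman(x, y)
        rx = spstats.rankdata(x)
        ry = spstats.rankdata(y)
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= abs(res.rho) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert res.p == pytest.approx(count / math.factorial(5))

    def test_large_n_t_approximation(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.5 * rng.standard_normal(30)
        res = spearman(x, y)
        ref = spstats.spearmanr(x, y)
        assert res.rho == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue), rel=1e-6)


class TestDeltaCorrelationReport:
    def features_frame(self, values):
        """values: {(subject, condition): n_peaks}; one channel."""
        rows = []
        for (s, c), v in values.items():
            rows.append({"subject_id": s, "condition": c, "channel": "flexors_left",
                         "feature": "n_peaks", "value": float(v)})
        return pd.DataFrame(rows)

    def scores_frame(self, values):
        rows = []
        for (s, c), v in values.items():
            rows.append({"subject_id": s, "condition": c,
                         "total_part3": v, "upper_limb_subtotal": v})
        return pd.DataFrame(rows)

    def test_antitone_link_gives_rho_minus_one(self):
        subjects = [f"p{i}" for i in range(6)]
        feats, scores = {}, {}
        for i, s in enumerate(subjects):
            feats[(s, "off")] = 20 + i
            feats[(s, "on")] = 40 + 3 * i   # delta(off-on) = -20 - 2i, decreasing
            scores[(s, "off")] = 30 - i
            scores[(s, "on")] = 15 - 2 * i  # delta = 15 + i, increasing
        rep = delta_correlation_report(
            self.features_frame(feats), self.scores_frame(scores)
        )
        delta_row = rep[rep.contrast == "delta"].iloc[0]
        assert delta_row.rho == pytest.approx(-1.0)

    def test_swapping_conditions_flips_delta_rho(self):
        rng = np.random.default_rng(3)
        subjects = [f"p{i}" for i in range(6)]
        feats = {(s, c): rng.integers(10, 60) for s in subjects for c in ("off", "on")}
        scores = {(s, c): int(rng.integers(5, 35)) for s in subjects
                  for c in ("off", "on")}
        swapped = {(s, "on" if c == "off" else "off"): v for (s, c), v in feats.items()}
        rep = delta_correlation_report(self.features_frame(feats),
                                       self.scores_frame(scores))
        rep_swapped = delta_correlation_report(self.features_frame(swapped),
                                               self.scores_frame(scores))
        a = rep[rep.contrast == "delta"].iloc[0].rho
        b = rep_swapped[rep_swapped.contrast == "delta"].iloc[0].rho
        assert a == pytest.approx(-b)

    def test_independent_feature_gives_small_mean_rho(self):
        """Permutation null: with scores unlinked to the feature, |rho| at
        n = 6 averages well below 0.2 over 200 label permutations."""
        rng = np.random.default_rng(9)
        subjects = [f"p{i}" for i in range(6)]
        feats = {(s, c): float(rng.integers(10, 60)) for s in subjects
                 for c in ("off", "on")}
        base_scores = [(30 - 2 * i, 18 - i) for i in range(6)]
        rhos = []
        for _ in range(200):
            perm = rng.permutation(6)
            scores = {}
            for i, s in enumerate(subjects):
                off, on = base_scores[perm[i]]
                scores[(s, "off")] = off
                scores[(s, "on")] = on
            rep = delta_correlation_report(self.features_frame(feats),
                                           self.scores_frame(scores))
            rhos.append(rep[rep.contrast == "delta"].iloc[0].rho)
        assert abs(np.mean(rhos)) < 0.2
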