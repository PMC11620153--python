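import math

import numpy as np
import pandas as pd
import pytest

from emgtap.features import (
    FeatureParams,
    FeatureTable,
    WindowSpec,
    approximate_entropy,
    build_table,
    channel_features,
    du,
    extended,
    hudgins,
    sample_entropy,
    segment,
    standard_subset,
    standardize,
    apply_standardization,
)
from tests.oracles import oracle_apen, oracle_sampen

EPS0 = FeatureParams(eps_zc_abs=0.0, eps_ssc_abs=0.0, eps_wamp_abs=0.0)


class TestSegmentation:
    def test_19s_signal_gives_37_windows(self):
        windows = segment(np.zeros(23940), 1260.0)
        assert len(windows) == 37
        assert all(w.size == 1260 for w in windows)

    def test_signal_equal_to_window_gives_one(self):
        assert len(segment(np.zeros(1260), 1260.0)) == 1

    def test_rect_windows_are_slices(self, rng):
        x = rng.standard_normal(300)
        windows = segment(x, 100.0, WindowSpec(1.0, 0.5, taper="rect"))
        assert len(windows) == 5
        for k, w in enumerate(windows):
            assert np.array_equal(w, x[k * 50 : k * 50 + 100])

    def test_hann_taper_applied(self, rng):
        x = rng.standard_normal(100)
        w = segment(x, 100.0, WindowSpec(1.0, 1.0, taper="hann"))[0]
        assert np.allclose(w, x * np.hanning(100))

    @pytest.mark.parametrize(
        "n,wlen,step", [(100, 10, 5), (101, 10, 5), (109, 10, 5), (50, 50, 25)]
    )
    def test_window_count_formula(self, n, wlen, step):
        fs = 1.0
        windows = segment(np.zeros(n), fs, WindowSpec(wlen, step, taper="rect"))
        assert len(windows) == (n - wlen) // step + 1


class TestHudginsAndDu:
    def test_hand_evaluation(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        h = hudgins(x, EPS0)
        assert h["MAV"] == 1.5
        assert h["WL"] == 9.0  # |−2| + |3| + |−4|
        assert h["ZC"] == 3
        assert h["SSC"] == 2
        d = du(x, EPS0)
        assert d["IAV"] == 6.0
        assert d["VAR"] == pytest.approx(10.0 / 3.0)
        assert d["WL"] == h["WL"] and d["ZC"] == h["ZC"] and d["SSC"] == h["SSC"]

    def test_constant_window(self):
        h = hudgins(np.full(10, -3.0), EPS0)
        assert h == {"MAV": 3.0, "ZC": 0.0, "WL": 0.0, "SSC": 0.0}

    def test_linear_ramp(self):
        h = hudgins(np.linspace(-1, 1, 21), EPS0)
        assert h["SSC"] == 0
        assert h["ZC"] <= 1

    def test_wamp_threshold(self):
        d = du(np.array([0.0, 1.0, 0.0, 1.0]), FeatureParams(eps_wamp_abs=0.5))
        assert d["WAMP"] == 3

    def test_all_zero_window(self):
        d = du(np.zeros(8), EPS0)
        assert all(v == 0 for v in d.values())

    def test_scaling_behaviour(self, rng):
        """MAV/IAV/WL scale by |c|, VAR by c^2; counts invariant under the
        SD-relative threshold policy."""
        x = rng.standard_normal(64)
        c = -2.5
        params = FeatureParams()
        a = {**hudgins(x, params), **du(x, params)}
        b = {**hudgins(c * x, params), **du(c * x, params)}
        for name in ("MAV", "IAV", "WL"):
            assert b[name] == pytest.approx(abs(c) * a[name])
        assert b["VAR"] == pytest.approx(c**2 * a["VAR"])
        for name in ("ZC", "SSC", "WAMP"):
            assert b[name] == a[name]


class TestExtended:
    def test_mav1_hand_evaluation(self):
        e = extended(np.array([1.0, -1.0, 2.0, -2.0]))
        assert e["MAV1"] == pytest.approx((1 + 1 + 2 + 0.5 * 2) / 4)

    def test_mav2_taper_endpoints(self):
        # N=8: i=1 gets 4/8=0.5, i=8 gets 0, centre band weight 1
        x = np.ones(8)
        e = extended(x)
        w = np.array([0.5, 1, 1, 1, 1, 1, 0.5, 0.0])
        assert e["MAV2"] == pytest.approx(w.mean())

    def test_constant_window_zero_entropy(self):
        e = extended(np.full(50, 2.0))
        assert e["ApEn"] == 0.0 and e["SampEn"] == 0.0

    def test_random_more_entropic_than_periodic(self, rng):
        n = 120
        periodic = np.sin(2 * np.pi * np.arange(n) / 10)
        random = rng.standard_normal(n)
        random *= periodic.std() / random.std()
        assert approximate_entropy(random) > approximate_entropy(periodic)
        assert sample_entropy(random) > sample_entropy(periodic)

    def test_entropies_match_template_count_oracle(self, rng):
        for n in (20, 60, 150, 200):
            x = rng.standard_normal(n)
            r = 0.2 * x.std()
            assert approximate_entropy(x, 2, r) == pytest.approx(
                oracle_apen(x, 2, r), abs=1e-10
            )
            got = sample_entropy(x, 2, r)
            exp = oracle_sampen(x, 2, r)
            if math.isnan(exp):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(exp, abs=1e-10)

    def test_sampen_undefined_marker(self):
        # strictly monotone widely-spaced values: no template matches at all
        x = np.array([1.0, 10.0, 100.0, 1000.0, 1e4, 1e5])
        assert math.isnan(sample_entropy(x, 2, r=0.1))


class TestChannelFeatures:
    def test_identical_windows_equal_single_window(self):
        block = np.sin(np.linspace(0, 4 * np.pi, 100))
        x = np.tile(block, 5)
        spec = WindowSpec(1.0, 1.0, taper="rect")
        vec = channel_features(x, 100.0, spec, feature_set="extended")
        single = {
            **hudgins(block, FeatureParams()),
            **du(block, FeatureParams()),
            **extended(block, FeatureParams()),
        }
        for name, value in single.items():
            assert vec[name] == pytest.approx(value)

    def test_nan_windows_excluded_from_mean(self, monkeypatch):
        import emgtap.features as feat

        calls = iter([1.0, math.nan])

        def fake_extended(window, params=None):
            return {"MAV1": 0.0, "MAV2": 0.0, "ApEn": 0.0, "SampEn": next(calls)}

        monkeypatch.setattr(feat, "extended", fake_extended)
        vec = feat.channel_features(
            np.arange(200.0), 100.0, WindowSpec(1.0, 1.0), feature_set="extended"
        )
        assert vec["SampEn"] == 1.0  # mean over the single defined window

    def test_all_nan_falls_back_to_zero(self, monkeypatch):
        import emgtap.features as feat

        def fake_extended(window, params=None):
            return {"MAV1": 0.0, "MAV2": 0.0, "ApEn": 0.0, "SampEn": math.nan}

        monkeypatch.setattr(feat, "extended", fake_extended)
        vec = feat.channel_features(
            np.arange(200.0), 100.0, WindowSpec(1.0, 1.0), feature_set="extended"
        )
        assert vec["SampEn"] == 0.0


class TestBuildTable:
    def test_row_and_column_structure(self, small_cohort):
        pd_recs = [r for r in small_cohort.recordings if r.group == "pd"]
        table = build_table(pd_recs, feature_set="extended")
        assert len(table.data) == 4  # 2 PD subjects x 2 conditions x 1 task
        assert table.data.index.names == ["subject_id", "condition", "task"]
        feats = {c.split("__")[0] for c in table.columns}
        assert feats == {
            "MAV", "ZC", "WL", "SSC", "IAV", "VAR", "WAMP",
            "MAV1", "MAV2", "ApEn", "SampEn", "n_peaks", "mean_interval_s",
        }
        assert not table.data.isna().any().any()

    def test_standard_set_is_strict_subset(self, small_cohort):
        pd_recs = [r for r in small_cohort.recordings if r.group == "pd"]
        ext = build_table(pd_recs, feature_set="extended")
        std = standard_subset(ext)
        assert set(std.columns) < set(ext.columns)
        assert std.data.index.equals(ext.data.index)
        rebuilt = build_table(pd_recs, feature_set="standard", include_burst=False)
        pd.testing.assert_frame_equal(std.data, rebuilt.data)


class TestStandardize:
    def test_fit_on_all_rows(self, rng):
        df = pd.DataFrame(
            rng.standard_normal((6, 3)),
            columns=["a", "b", "c"],
            index=pd.MultiIndex.from_product(
                [["s1", "s2", "s3"], ["off"], ["t"]],
                names=["subject_id", "condition", "task"],
            ).repeat(2)[:6],
        )
        z = standardize(FeatureTable(df, "standard"))
        assert np.allclose(z.data.mean(), 0, atol=1e-9)
        assert np.allclose(z.data.std(ddof=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        z = standardize(FeatureTable(df, "standard"))
        assert np.allclose(z.data["b"], 0.0)

    def test_held_out_row_uses_training_statistics(self):
        df = pd.DataFrame({"a": [0.0, 2.0, 10.0]}, index=["r1", "r2", "r3"])
        table = FeatureTable(df, "standard")
        z = standardize(table, fit_rows=["r1", "r2"])
        # train stats: mean 1, sd 1 (population) -> held-out row z = (10-1)/1
        held = apply_standardization(
            FeatureTable(df.loc[["r3"]], "standard"), z.scaler
        )
        assert held.loc["r3", "a"] == pytest.approx(9.0)
        assert z.data.loc["r3", "a"] == pytest.approx(9.0)
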