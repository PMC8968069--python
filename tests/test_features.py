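"""Sliding windows, the four time-domain operators, feature screening, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from seegstate.containers import ACTIVE, IDLE, ChannelInfo, GroundTruth, TraceSet
from seegstate.features import (
    FOUR_TYPE,
    WindowFeatureMatrix,
    WindowSpec,
    avg_amplitude,
    extract_features,
    label_window,
    line_length,
    make_windows,
    pca_reduce,
    restrict_feature_set,
    rms,
    select_feature_dims,
    slope,
)

FS = 1000.0


class TestWindows:
    def test_one_second_400ms_50ms_gives_13(self):
        starts = make_windows(1000, FS, WindowSpec(400.0, 50.0))
        assert len(starts) == 13
        assert starts[0] == 0 and starts[-1] == 600

    def test_exact_fit_single_window(self):
        starts = make_windows(150, FS, WindowSpec(150.0, 50.0))
        assert len(starts) == (150 - 150) // 50 + 1
        assert starts[0] == 0

    def test_step_larger_than_window_needs_override(self):
        with pytest.raises(ValueError, match="gaps"):
            WindowSpec(100.0, 200.0)
        spec = WindowSpec(100.0, 200.0, allow_gaps=True)
        assert len(make_windows(1000, FS, spec)) == 5

    def test_session_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            make_windows(100, FS, WindowSpec(400.0, 50.0))


class TestLabelWindow:
    def _timeline(self):
        tl = np.full(1000, IDLE, dtype=object)
        tl[400:700] = ACTIVE
        return tl

    def test_fully_inside_active(self):
        assert label_window(450, 200, self._timeline()) == ACTIVE

    def test_straddling_midpoint_idle(self):
        # window [250, 550): midpoint 400 is active; [150, 450): midpoint 300 idle
        tl = self._timeline()
        assert label_window(250, 300, tl) == ACTIVE
        assert label_window(150, 300, tl) == IDLE

    def test_rules_agree_except_straddling(self):
        tl = self._timeline()
        for start in range(0, 800, 10):
            mid = label_window(start, 200, tl, rule="midpoint")
            maj = label_window(start, 200, tl, rule="majority")
            straddles = (start < 400 < start + 200) or (start < 700 < start + 200)
            if not straddles:
                assert mid == maj


def _brute_A(x):
    return sum(x) / len(x)


def _brute_rms(x):
    return (sum(v * v for v in x) / len(x)) ** 0.5


def _brute_slope(x, fs):
    n = len(x)
    t = [i / fs for i in range(n)]
    tm = sum(t) / n
    xm = sum(x) / n
    num = sum((ti - tm) * (xi - xm) for ti, xi in zip(t, x))
    den = sum((ti - tm) ** 2 for ti in t)
    return num / den


def _brute_L(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


class TestOperators:
    def test_line_length_example(self):
        assert line_length(np.array([1.0, 3.0, 2.0])) == 3.0

    def test_rms_example(self):
        assert np.isclose(rms(np.array([3.0, 4.0])), np.sqrt(12.5))

    def test_constant_window(self):
        x = np.full(10, 4.2)
        assert np.isclose(avg_amplitude(x), 4.2)
        assert np.isclose(rms(x), 4.2)
        assert np.isclose(slope(x, FS), 0.0, atol=1e-9)
        assert line_length(x) == 0.0

    def test_slope_closed_form(self):
        assert np.isclose(slope(np.array([0.0, 1.0, 2.0]), FS), 1000.0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            rms(np.array([1.0]))

    def test_matches_bruteforce_on_random_windows(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 60))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            assert abs(avg_amplitude(x) - _brute_A(x)) < 1e-9
            assert abs(rms(x) - _brute_rms(x)) < 1e-9
            assert abs(slope(x, FS) - _brute_slope(x, FS)) < 1e-6 * max(
                1.0, abs(_brute_slope(x, FS))
            )
            assert abs(line_length(x) - _brute_L(x)) < 1e-9

    @given(
        arrays(np.float64, st.integers(2, 50),
               elements=st.floats(-1e6, 1e6, allow_nan=False))
    )
    @settings(max_examples=100, deadline=None)
    def test_rms_dominates_amplitude(self, x):
        assert rms(x) >= abs(avg_amplitude(x)) - 1e-7 * (1 + abs(avg_amplitude(x)))

    @given(
        arrays(np.float64, st.integers(2, 50),
               elements=st.floats(-1e6, 1e6, allow_nan=False))
    )
    @settings(max_examples=100, deadline=None)
    def test_line_length_zero_iff_constant(self, x):
        assert (line_length(x) == 0.0) == bool(np.all(x == x[0]))


def _traces_and_truth(n_ch=3, n=5000, seed=0):
    rng = np.random.default_rng(seed)
    channels = [ChannelInfo(f"A{i+1}", "A", i + 1) for i in range(n_ch)]
    traces = {
        kind: TraceSet(kind, rng.standard_normal((n_ch, n)) + 2.0, FS, channels)
        for kind in ("high_gamma", "beta", "alpha", "erp")
    }
    tl = np.full(n, IDLE, dtype=object)
    tl[1000:2000] = ACTIVE
    return traces, GroundTruth(tl, FS)


class TestExtractFeatures:
    def test_column_count_and_order(self):
        traces, truth = _traces_and_truth()
        sels = {k: ["A1", "A2"] for k in traces}
        starts = make_windows(5000, FS, WindowSpec(400.0, 50.0))
        m = extract_features(traces, sels, starts, WindowSpec(400.0, 50.0),
                             truth=truth)
        assert m.X.shape[1] == 4 * 2 * 4  # kinds x channels x operators
        assert list(m.X.columns[:4]) == [
            "high_gamma:A1:A", "high_gamma:A1:RMS", "high_gamma:A1:k",
            "high_gamma:A1:L",
        ]

    def test_single_channel_single_trace(self):
        traces, truth = _traces_and_truth()
        m = extract_features(
            {"erp": traces["erp"]}, {"erp": ["A2"]},
            make_windows(5000, FS, WindowSpec(400.0, 50.0)),
            WindowSpec(400.0, 50.0), truth=truth,
        )
        assert m.X.shape[1] == 4

    def test_empty_selection_errors(self):
        traces, truth = _traces_and_truth()
        with pytest.raises(ValueError):
            extract_features(traces, {k: [] for k in traces},
                             np.array([0]), WindowSpec(400.0, 50.0))

    def test_four_type_restriction(self):
        traces, truth = _traces_and_truth()
        sels = {k: ["A1"] for k in traces}
        spec = WindowSpec(400.0, 50.0)
        m = extract_features(traces, sels, make_windows(5000, FS, spec), spec,
                             truth=truth)
        m4 = restrict_feature_set(m, "four_type")
        assert set(m4.X.columns) == {
            "high_gamma:A1:A", "high_gamma:A1:RMS", "high_gamma:A1:L",
            "erp:A1:L",
        }

    def test_values_match_operators(self):
        traces, truth = _traces_and_truth()
        spec = WindowSpec(400.0, 50.0)
        starts = make_windows(5000, FS, spec)
        m = extract_features({"erp": traces["erp"]}, {"erp": ["A1"]}, starts,
                             spec, truth=truth)
        w0 = traces["erp"].data[0, starts[3] : starts[3] + 400]
        assert np.isclose(m.X["erp:A1:A"].iloc[3], avg_amplitude(w0))
        assert np.isclose(m.X["erp:A1:L"].iloc[3], line_length(w0))

    def test_tsv_roundtrip(self, tmp_path):
        traces, truth = _traces_and_truth()
        spec = WindowSpec(400.0, 50.0)
        m = extract_features({"erp": traces["erp"]}, {"erp": ["A1"]},
                             make_windows(5000, FS, spec), spec, truth=truth)
        m.to_tsv(tmp_path / "m.tsv")
        m2 = WindowFeatureMatrix.from_tsv(str(tmp_path / "m.tsv"))
        assert np.allclose(m2.X.to_numpy(), m.X.to_numpy())
        assert np.array_equal(m2.labels.astype(str), m.labels.astype(str))


class TestFeatureDimSelection:
    def _matrix(self, rng, n=300, n_info=3, n_noise=17):
        labels = np.where(rng.random(n) < 0.5, ACTIVE, IDLE).astype(object)
        sign = np.where(labels == ACTIVE, 1.0, 0.0)
        cols = {}
        for j in range(n_info):
            cols[f"info{j}"] = sign * 3.0 + rng.standard_normal(n)
        for j in range(n_noise):
            cols[f"noise{j:02d}"] = rng.standard_normal(n)
        return pd.DataFrame(cols), labels

    def test_informative_columns_rank_first(self, rng):
        X, labels = self._matrix(rng)
        fs = select_feature_dims(X, labels, keep=10, n_perm=300, seed=0)
        assert {"info0", "info1", "info2"} <= set(fs.kept)
        info_p = fs.p[[c for c in X if c.startswith("info")]].max()
        assert info_p < fs.p[[c for c in X if c.startswith("noise")]].min()

    def test_few_columns_all_kept(self, rng):
        X, labels = self._matrix(rng, n_info=2, n_noise=3)
        fs = select_feature_dims(X, labels, keep=10, n_perm=100, seed=0)
        assert fs.kept == list(X.columns)

    def test_degenerate_column_p_one(self, rng):
        X, labels = self._matrix(rng, n_info=1, n_noise=2)
        X["const"] = 5.0
        fs = select_feature_dims(X, labels, keep=10, n_perm=100, seed=0)
        assert fs.p["const"] == 1.0


class TestPca:
    def test_rank_one_single_component(self, rng):
        base = rng.standard_normal(50)
        X = pd.DataFrame(np.outer(base, [1.0, 2.0, -1.0]), columns=list("abc"))
        fs = select_feature_dims(X, np.array([ACTIVE, IDLE] * 25, object),
                                 keep=10, n_perm=50, seed=0)
        fs = pca_reduce(fs, X)
        assert fs.n_components == 1

    def test_isotropic_needs_all_components(self, rng):
        X = pd.DataFrame(rng.standard_normal((5000, 10)))
        X.columns = [f"c{i}" for i in range(10)]
        fs = select_feature_dims(
            X, np.array([ACTIVE, IDLE] * 2500, object), keep=10, n_perm=50,
            seed=0,
        )
        fs = pca_reduce(fs, X)
        assert fs.n_components == 10

    def test_retained_variance_above_threshold(self, rng):
        X = pd.DataFrame(
            rng.standard_normal((400, 6)) * np.array([5, 3, 1, 0.5, 0.1, 0.05])
        )
        X.columns = [f"c{i}" for i in range(6)]
        fs = select_feature_dims(X, np.array([ACTIVE, IDLE] * 200, object),
                                 keep=10, n_perm=50, seed=0)
        fs = pca_reduce(fs, X)
        evr = fs.pca.explained_variance_ratio_
        assert evr[: fs.n_components].sum() > 0.95
        assert evr[: fs.n_components - 1].sum() <= 0.95
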