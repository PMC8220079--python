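import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import emgmotion as em
from emgmotion.errors import InputError
from naive import (
    naive_mav,
    naive_mavs,
    naive_rms,
    naive_slope_sign_changes,
    naive_waveform_length,
    naive_zero_crossings,
)

windows = arrays(
    float,
    st.integers(3, 60),
    elements=st.floats(-5, 5, allow_nan=False, width=32),
)


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x, T, expected",
        [
            ([1, -1, 1, -1], 0.5, 3),  # every adjacent pair crosses with |delta|=2
            ([1, 1, 1], 0.0, 0),  # no sign change
            ([0.1, -0.1], 0.5, 0),  # crossing exists but |delta|=0.2 < T
            ([0, 1, -1], 0.0, 1),  # exact zero never crosses (strict signs)
        ],
    )
    def test_hand_cases(self, x, T, expected):
        assert em.zero_crossings(np.array(x, float), T) == expected

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            em.zero_crossings(np.array([1.0]), 0.0)


class TestSlopeSignChanges:
    @pytest.mark.parametrize(
        "x, T, expected",
        [
            ([0, 1, 0], 0.5, 1),  # peak, both deltas 1 >= T
            ([0, 1, 2, 3], 0.0, 0),  # monotone
            ([0, 1, 0], 2.0, 0),  # threshold exceeds both deltas
            ([0, 1, 0, 1, 0], 0.5, 3),
        ],
    )
    def test_hand_cases(self, x, T, expected):
        assert em.slope_sign_changes(np.array(x, float), T) == expected

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            em.slope_sign_changes(np.array([1.0, 2.0]), 0.0)


class TestAmplitudeFeatures:
    def test_hand_case(self):
        rms, mav, mavs, wl = em.amplitude_features(np.array([3.0, -4.0]))
        assert rms == pytest.approx(np.sqrt(12.5))
        assert mav == pytest.approx(3.5)
        assert mavs == pytest.approx(4 - 3)
        assert wl == pytest.approx(7)

    def test_constant_signal(self):
        rms, mav, mavs, wl = em.amplitude_features(np.full(10, -2.5))
        assert (rms, mav, mavs, wl) == (2.5, 2.5, 0.0, 0.0)

    @settings(derandomize=True, deadline=None)
    @given(windows, st.sampled_from([0.25, 0.5, 2.0, 8.0]))
    def test_positive_homogeneity(self, x, alpha):
        base = np.array(em.amplitude_features(x))
        scaled = np.array(em.amplitude_features(alpha * x))
        np.testing.assert_allclose(scaled, alpha * base, rtol=1e-9, atol=1e-12)


class TestThresholdInvariants:
    @settings(derandomize=True, deadline=None)
    @given(windows)
    def test_zc_ssc_monotone_in_threshold(self, x):
        grid = [0.0, 1e-3, 1e-2, 0.1, 1.0, 10.0]
        zc = [em.zero_crossings(x, T) for T in grid]
        ssc = [em.slope_sign_changes(x, T) for T in grid]
        assert zc == sorted(zc, reverse=True)
        assert ssc == sorted(ssc, reverse=True)

    # power-of-two scale factors keep the scaling exact in floating point,
    # so the invariance holds without a tolerance on the threshold gate
    @settings(derandomize=True, deadline=None)
    @given(windows, st.floats(0.0, 2.0), st.sampled_from([0.25, 0.5, 2.0, 8.0]))
    def test_joint_scaling_invariance(self, x, T, alpha):
        assert em.zero_crossings(alpha * x, alpha * T) == em.zero_crossings(x, T)
        assert em.slope_sign_changes(alpha * x, alpha * T) == em.slope_sign_changes(x, T)

    def test_huge_threshold_forces_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        T = np.abs(np.diff(x)).max() * 1.01
        assert em.zero_crossings(x, T) == 0
        assert em.slope_sign_changes(x, T) == 0

    def test_counts_bounded_by_window_length(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert 0 <= em.zero_crossings(x, 0.0) <= 29
        assert 0 <= em.slope_sign_changes(x, 0.0) <= 28


class TestExtractFeatures:
    def test_shape_and_names(self, small_recording):
        ws = em.segment(small_recording, 200, 100)
        table = em.extract_features(ws, 1e-8)
        assert table.values.shape == (ws.n_windows, 6 * ws.n_channels)
        assert table.names[:6] == [f"{f}_0" for f in em.FEATURE_ORDER]
        assert table.threshold_used == 1e-8

    def test_null_signal(self):
        rec = em.Recording(
            emg=np.zeros((200, 2)), fs=200, stimulus=np.zeros(200, int), repetition=np.zeros(200, int)
        )
        table = em.extract_features(em.segment(rec, 100, 100), 0.0)
        np.testing.assert_array_equal(table.values, 0.0)

    def test_matches_per_window_naive_oracle(self):
        rng = np.random.default_rng(7)
        n, W, C = 40, 25, 3
        ws = em.WindowSet(
            windows=rng.normal(size=(n, W, C)),
            labels=np.zeros(n, int),
            repetitions=np.zeros(n, int),
            routing_repetitions=np.zeros(n, int),
            start_indices=np.arange(n),
            window_ms=125,
            stride_ms=125,
            fs=200,
            channel_index=tuple(range(C)),
        )
        T = 0.3
        table = em.extract_features(ws, T)
        for i in range(n):
            for ci in range(C):
                x = ws.windows[i, :, ci]
                expected = [
                    naive_rms(x),
                    naive_mav(x),
                    naive_mavs(list(x)),
                    naive_zero_crossings(x, T),
                    naive_slope_sign_changes(x, T),
                    naive_waveform_length(x),
                ]
                np.testing.assert_allclose(table.values[i, 6 * ci : 6 * ci + 6], expected, rtol=1e-12)


class TestStandardizer:
    def make_table(self, values):
        values = np.asarray(values, float)
        return em.FeatureTable(
            values=values,
            names=[f"f{i}" for i in range(values.shape[1])],
            labels=np.zeros(len(values), int),
            repetitions=np.zeros(len(values), int),
            threshold_used=0.0,
        )

    def test_centering_with_population_std(self):
        table = self.make_table([[1.0], [2.0], [3.0]])
        params = em.fit_standardizer(table)
        assert params.mean[0] == pytest.approx(2.0)
        assert params.std[0] == pytest.approx(np.sqrt(2 / 3))  # ddof=0
        out = em.apply_standardizer(params, table)
        assert abs(out.values[:, 0].mean()) < 1e-9
        assert out.values[:, 0].std() == pytest.approx(1.0, abs=1e-6)

    def test_train_statistics_used_on_test(self):
        train = self.make_table([[0.0], [2.0]])
        test = self.make_table([[10.0], [12.0]])
        params = em.fit_standardizer(train)
        out = em.apply_standardizer(params, test)
        assert out.values[:, 0].mean() != pytest.approx(0.0, abs=1.0)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(2)
        table = self.make_table(rng.normal(5, 3, size=(20, 4)))
        params = em.fit_standardizer(table)
        back = em.invert_standardizer(params, em.apply_standardizer(params, table))
        np.testing.assert_allclose(back.values, table.values, rtol=1e-12, atol=1e-12)

    def test_zero_variance_column_flagged_and_centered(self):
        table = self.make_table([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        params = em.fit_standardizer(table)
        assert params.zero_variance.tolist() == [False, True]
        out = em.apply_standardizer(params, table)
        np.testing.assert_array_equal(out.values[:, 1], 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            em.fit_standardizer(self.make_table([[1.0, 2.0]]))
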