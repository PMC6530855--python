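import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_feature_matrix, small_feature_matrix
from gaitmood.features import (
    FeatureLabel,
    FeatureMatrix,
    build_feature_matrix,
    fft_amplitudes,
    make_selector,
    select_features,
    zscore,
)
from gaitmood.preprocess import RETAINED_JOINTS, Segment


def naive_dft_amplitudes(x):
    """O(N^2) direct evaluation of |sum_n x_n e^{-i 2 pi k n / N}|."""
    n_idx = np.arange(64)
    return np.array(
        [abs(np.sum(x * np.exp(-2j * np.pi * k * n_idx / 64))) for k in range(64)]
    )


class TestFftAmplitudes:
    def test_constant_series_is_dc_only(self):
        amps = fft_amplitudes(np.full(64, 2.5))
        assert amps[0] == pytest.approx(64 * 2.5)
        np.testing.assert_allclose(amps[1:], 0.0, atol=1e-9)

    def test_single_tone_splits_between_mirror_bins(self):
        x = np.cos(2 * np.pi * np.arange(64) * 4 / 64)
        amps = fft_amplitudes(x)
        assert amps[4] == pytest.approx(32.0)
        assert amps[60] == pytest.approx(32.0)
        others = np.delete(amps, [4, 60])
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_matches_naive_dft_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=64)
            np.testing.assert_allclose(
                fft_amplitudes(x), naive_dft_amplitudes(x), rtol=1e-9
            )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="64"):
            fft_amplitudes(np.ones(63))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_parseval_scaling(self, seed):
        """Sum |X_k|^2 = N * sum x_n^2 under the unscaled DFT convention."""
        x = np.random.default_rng(seed).normal(size=64)
        amps = fft_amplitudes(x)
        assert np.sum(amps**2) == pytest.approx(64 * np.sum(x**2), rel=1e-6)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_amplitude_symmetry_for_real_input(self, seed):
        amps = fft_amplitudes(np.random.default_rng(seed).normal(size=64))
        np.testing.assert_allclose(amps[1:], amps[:0:-1], rtol=1e-9, atol=1e-9)


def make_segment(seed, subject="S"):
    rng = np.random.default_rng(seed)
    return Segment(subject_id=subject, start_frame=0, positions=rng.normal(size=(64, 24, 3)))


class TestBuildFeatureMatrix:
    def test_dimensions_are_subjects_by_4608(self):
        segments = {f"S{i}": make_segment(i, f"S{i}") for i in range(10)}
        fm = build_feature_matrix(segments)
        assert fm.values.shape == (10, 4608)
        assert not fm.normalized

    def test_sixty_four_columns_per_joint_axis(self):
        fm = build_feature_matrix({"A": make_segment(0)})
        counts = fm.data.columns.to_frame(index=False).groupby(["joint", "axis"]).size()
        assert (counts == 64).all() and len(counts) == 72

    def test_identical_segments_give_identical_rows(self):
        seg = make_segment(3)
        fm = build_feature_matrix({"A": seg, "B": seg})
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_columns_agree_with_fft_amplitudes(self):
        seg = make_segment(5)
        fm = build_feature_matrix({"A": seg})
        joint, axis = RETAINED_JOINTS[7], 1
        expected = fft_amplitudes(seg.positions[:, 7, axis])
        got = fm.data[joint]["Y"].loc["A"].to_numpy()
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestZscore:
    def test_columns_become_standardized(self):
        fm = random_feature_matrix(20, np.random.default_rng(0))
        z = zscore(fm)
        assert z.normalized
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0), 1.0, atol=1e-9)

    def test_population_sd_convention(self):
        fm = random_feature_matrix(3, np.random.default_rng(0))
        fm.data.iloc[:, 0] = [1.0, 2.0, 3.0]
        z = zscore(fm)
        np.testing.assert_allclose(
            z.values[:, 0], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-12
        )

    def test_constant_column_becomes_zero(self):
        fm = random_feature_matrix(5, np.random.default_rng(0))
        fm.data.iloc[:, 10] = 4.2
        z = zscore(fm)
        np.testing.assert_array_equal(z.values[:, 10], np.zeros(5))

    def test_single_subject_rejected(self):
        fm = random_feature_matrix(1, np.random.default_rng(0))
        with pytest.raises(ValueError, match="at least 2"):
            zscore(fm)

    def test_double_normalization_rejected(self):
        fm = random_feature_matrix(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            zscore(zscore(fm))


class TestSelectFeatures:
    def make_normalized(self, n=50, seed=0):
        return zscore(random_feature_matrix(n, np.random.default_rng(seed)))

    def test_output_has_360_columns(self):
        fm = self.make_normalized()
        target = np.random.default_rng(1).normal(size=50)
        selected, report = select_features(fm, target)
        assert selected.n_features == 360
        assert len(report) == 360
        assert selected.normalized

    def test_target_equal_to_column_selects_it(self):
        fm = self.make_normalized(n=30)
        target = fm.data.iloc[:, 130].to_numpy()
        selected, report = select_features(fm, target)
        label = fm.data.columns[130]
        assert label in selected.data.columns
        r = report.set_index(["joint", "axis", "freq_index"]).loc[label, "r"]
        assert r == pytest.approx(1.0)

    def test_matches_exhaustive_sort_oracle(self):
        fm = self.make_normalized(n=50, seed=3)
        target = np.random.default_rng(4).normal(size=50)
        selected, _ = select_features(fm, target)
        chosen = set(selected.data.columns)
        oracle = set()
        for joint in RETAINED_JOINTS:
            for axis in ("X", "Y", "Z"):
                cols = fm.data[joint][axis]
                rs = {
                    k: abs(np.corrcoef(cols[k], target)[0, 1]) for k in cols.columns
                }
                top5 = sorted(rs, key=lambda k: (-rs[k], k))[:5]
                oracle.update((joint, axis, k) for k in top5)
        assert chosen == oracle

    def test_selection_is_column_subset_with_untouched_values(self):
        fm = self.make_normalized(n=20, seed=5)
        target = np.random.default_rng(6).normal(size=20)
        selected, _ = select_features(fm, target)
        for col in selected.data.columns:
            np.testing.assert_array_equal(selected.data[col], fm.data[col])

    def test_permutation_equivariance(self):
        fm = self.make_normalized(n=25, seed=7)
        target = np.random.default_rng(8).normal(size=25)
        perm = np.random.default_rng(9).permutation(25)
        permuted = FeatureMatrix(fm.data.iloc[perm], normalized=True)
        a, _ = select_features(fm, target)
        b, _ = select_features(permuted, target[perm])
        assert set(a.data.columns) == set(b.data.columns)

    def test_ties_break_toward_lower_frequency(self):
        values = np.zeros((6, 64))
        rng = np.random.default_rng(10)
        base = rng.normal(size=6)
        values[:, :] = rng.normal(size=(6, 64)) * 0.01
        for k in (3, 9, 17, 30, 41, 55, 60):  # 7 exactly-tied perfect columns
            values[:, k] = base
        fm = small_feature_matrix((values - values.mean(0)) / values.std(0))
        selected, report = select_features(fm, base, top_k=5)
        group = report[(report.joint == RETAINED_JOINTS[0]) & (report.axis == "X")]
        assert list(group.freq_index) == [3, 9, 17, 30, 41]

    def test_zero_variance_target_rejected(self):
        fm = self.make_normalized(n=10)
        with pytest.raises(ValueError, match="zero variance"):
            select_features(fm, np.ones(10))

    def test_unnormalized_matrix_rejected(self):
        fm = random_feature_matrix(10, np.random.default_rng(0))
        with pytest.raises(ValueError, match="z-scored"):
            select_features(fm, np.arange(10.0))

    def test_selector_callable_matches_select_features(self):
        fm = self.make_normalized(n=30, seed=11)
        target = np.random.default_rng(12).normal(size=30)
        cols = make_selector()(fm.values, fm.data.columns, target)
        selected, _ = select_features(fm, target)
        assert list(fm.data.columns[cols]) == list(selected.data.columns)


class TestFeatureLabel:
    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            FeatureLabel("SpineBase", "X", 0)  # dropped by re-centering
        with pytest.raises(ValueError):
            FeatureLabel("Head", "W", 0)
        with pytest.raises(ValueError):
            FeatureLabel("Head", "X", 64)
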