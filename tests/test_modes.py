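import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dynstab.io import Recording
from dynstab.modes import (BandDefinition, EXACT_ENUMERATION_MAX_N,
                           build_mode_table, decompose, decompose_matrix,
                           loading_kurtosis, mode_statistics, mode_trajectory,
                           normalize_loadings, onset_contrast,
                           subsample_robustness)


def _rot(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestDecompose:
    def test_scaled_identity_closed_form(self):
        modes, defective = decompose_matrix(0.9 * np.eye(2), fs=512.0)
        assert not defective
        for m in modes:
            assert m.stability == pytest.approx(0.9)
            assert m.frequency == pytest.approx(0.0)
            assert m.growth_rate == pytest.approx(512 * math.log(0.9))
            assert m.is_real_mode

    def test_rotation_scaling_closed_form(self):
        A = 0.98 * _rot(2 * math.pi * 64 / 512)
        modes, _ = decompose_matrix(A, fs=512.0)
        assert len(modes) == 1  # conjugate pair retained once
        assert modes[0].frequency == pytest.approx(64.0)
        assert modes[0].stability == pytest.approx(0.98)
        assert not modes[0].is_real_mode

    def test_retained_count_and_trace_identity(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 5))
        modes, _ = decompose_matrix(A, fs=100.0)
        eigvals = np.linalg.eigvals(A)
        n_real = int(np.sum(eigvals.imag == 0))
        n_pairs = int(np.sum(eigvals.imag > 0))
        assert len(modes) == n_real + n_pairs
        total = sum(m.eigenvalue.real if m.is_real_mode
                    else 2 * m.eigenvalue.real for m in modes)
        assert total == pytest.approx(np.trace(A), abs=1e-10)

    def test_reconstruction_invariant_on_fitted_windows(self, surrogate_track):
        _, track = surrogate_track(0)
        for model in list(track)[::25]:
            A = model.A
            ev, V = np.linalg.eig(A)
            err = np.linalg.norm(A - (V * ev) @ np.linalg.inv(V))
            assert err <= 1e-8 * np.linalg.norm(A)

    def test_null_eigenvalues_have_zero_frequency(self):
        # rank-1 A has n-1 numerically-zero eigenvalues whose angles carry
        # no frequency information
        A = np.outer([1.0, -2.0, 0.5], [0.3, 0.1, -0.2])
        modes, _ = decompose_matrix(A, fs=512.0)
        null_modes = [m for m in modes if m.stability < 1e-9]
        assert null_modes
        assert all(m.frequency == 0.0 for m in null_modes)

    def test_left_eigenvector_is_inverse_row(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((4, 4))
        modes, _ = decompose_matrix(A, fs=10.0)
        for m in modes:
            # left vector maps A to lambda times itself
            np.testing.assert_allclose(m.left_eigenvector @ A,
                                       m.eigenvalue * m.left_eigenvector,
                                       atol=1e-8)

    def test_defective_matrix_flagged_not_fatal(self):
        A = np.array([[1.0, 1.0], [0.0, 1.0]])  # Jordan block
        modes, defective = decompose_matrix(A, fs=10.0)
        assert defective
        assert len(modes) >= 1


class TestNormalizeLoadings:
    def test_examples(self):
        np.testing.assert_array_equal(
            normalize_loadings(np.array([1.0, 0, 0, 0])), [1, 0, 0, 0])
        np.testing.assert_allclose(
            normalize_loadings(np.array([0.5, -0.5j, 0.25, 0])),
            [1.0, 1.0, 0.5, 0.0])

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize_loadings(np.zeros(3))

    @given(arrays(np.complex128, st.integers(1, 12),
                  elements=st.complex_numbers(max_magnitude=1e6,
                                              allow_nan=False,
                                              allow_infinity=False)))
    def test_range_and_peak(self, v):
        if np.abs(v).max() == 0:
            return
        out = normalize_loadings(v)
        assert np.all(out >= 0) and np.all(out <= 1)
        assert np.sum(out == 1.0) >= 1


class TestModeStatistics:
    def _mode(self, freq, loadings, stability=0.9):
        from dynstab.modes import EigenMode
        loadings = np.asarray(loadings, dtype=float)
        return EigenMode(
            eigenvalue=stability * np.exp(2j * math.pi * freq / 512),
            stability=stability, angle=2 * math.pi * freq / 512,
            frequency=freq, growth_rate=0.0, loadings=loadings,
            right_eigenvector=loadings.astype(complex),
            left_eigenvector=loadings.astype(complex),
            is_real_mode=False, window_center=0.0)

    def test_focal_mode_moments(self):
        # one-hot loading over 10 channels: m2 = 0.09, m4 = 0.0657
        loadings = np.zeros(10)
        loadings[0] = 1.0
        band = BandDefinition("g", 25, 55)
        s = mode_statistics([self._mode(30.0, loadings)], band)
        assert s.max_loading == pytest.approx(1.0)
        assert s.kurtosis == pytest.approx(0.0657 / 0.0081)

    def test_zero_variance_flagged_undefined(self):
        band = BandDefinition("g", 25, 55)
        s = mode_statistics([self._mode(30.0, np.ones(5))], band)
        assert s.defined and math.isnan(s.kurtosis)

    def test_empty_band_flagged(self):
        band = BandDefinition("g", 25, 55)
        s = mode_statistics([self._mode(5.0, np.ones(4))], band)
        assert not s.defined and s.n_modes_in_band == 0

    def test_kurtosis_matches_direct_moments(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.uniform(0, 1, size=rng.integers(3, 30))
            d = x - x.mean()
            expected = np.mean(d**4) / np.mean(d**2) ** 2
            assert abs(loading_kurtosis(x) - expected) < 1e-12

    def test_dominant_mode_option(self):
        band = BandDefinition("g", 25, 55)
        weak = self._mode(30.0, [1.0, 0.0], stability=0.5)
        strong = self._mode(40.0, [0.0, 1.0], stability=0.99)
        s = mode_statistics([weak, strong], band, loading_mode="dominant")
        np.testing.assert_array_equal(s.channel_loadings, [0.0, 1.0])


class TestModeTrajectory:
    def test_diagonal_system_picks_channel(self):
        A = np.diag([0.5, 0.8])
        modes, _ = decompose_matrix(A, fs=10.0)
        modes.sort(key=lambda m: m.eigenvalue.real)
        seg = np.arange(10, dtype=float).reshape(1, -1) * np.ones((2, 1))
        seg[1] *= -3
        z = mode_trajectory(seg, modes[0])  # eigenvalue 0.5 -> channel 1
        np.testing.assert_allclose(z.real, seg[0], atol=1e-12)

    def test_modal_coordinate_decays_geometrically(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((4, 4))
        A *= 0.9 / np.abs(np.linalg.eigvals(A)).max()
        x = np.empty((4, 51))
        x[:, 0] = rng.standard_normal(4)
        for k in range(1, 51):
            x[:, k] = A @ x[:, k - 1]
        modes, _ = decompose_matrix(A, fs=100.0)
        for m in modes:
            z = mode_trajectory(x, m)
            if abs(z[0]) < 1e-9:
                continue
            ratio = np.abs(z) / abs(z[0])
            np.testing.assert_allclose(ratio, m.stability ** np.arange(51),
                                       atol=1e-8)

    def test_dimension_mismatch(self):
        modes, _ = decompose_matrix(np.eye(3), fs=1.0)
        with pytest.raises(ValueError):
            mode_trajectory(np.zeros((2, 5)), modes[0])


class TestModeTable:
    def test_record_count_bounds(self, surrogate_track):
        _, track = surrogate_track(0)
        table = build_mode_table(track)
        n, j = track.n_channels, len(track)
        assert j * math.ceil(n / 2) <= len(table) <= j * n

    def test_mode_id_is_frequency_rank(self, surrogate_track):
        _, track = surrogate_track(0)
        table = build_mode_table(track)
        for _, grp in itertools.islice(
                table.records.groupby("window_center_s"), 5):
            freqs = grp.sort_values("mode_id")["frequency_hz"].to_numpy()
            assert np.all(np.diff(freqs) <= 0)

    def test_figure1_table_contains_late_64hz_track(self, figure1_track):
        _, track = figure1_track
        table = build_mode_table(track)
        rec = table.records
        late = rec[(rec.mode_id == 1) & (rec.window_center_s >= 6.5)
                   & (rec.window_center_s <= 7.5)]
        assert np.all(np.abs(late.frequency_hz - 64.0) < 1.0)

    def test_windows_decomposed_independently(self, figure1_track):
        _, track = figure1_track
        full = build_mode_table(track).records
        sub_track = type(track)(
            models=track.models[10:20], window_s=track.window_s,
            shift_s=track.shift_s, channel_labels=track.channel_labels,
            fs=track.fs, events=track.events)
        sub = build_mode_table(sub_track).records
        merged = full.merge(sub, on=["window_center_s", "mode_id"],
                            suffixes=("", "_sub"))
        assert len(merged) == len(sub)
        np.testing.assert_array_equal(merged["frequency_hz"],
                                      merged["frequency_hz_sub"])


class TestOnsetContrast:
    def test_identical_samples_give_p_one(self):
        r = onset_contrast([1, 2, 3], [1, 2, 3])
        assert r.method == "exact"
        assert r.pvalue == pytest.approx(1.0)

    def test_separated_samples_exact_p(self):
        r = onset_contrast([1, 2, 3, 4], [5, 6, 7, 8])
        assert r.pvalue == pytest.approx(2 / 70)

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=5),
           st.lists(st.integers(0, 5), min_size=1, max_size=5))
    def test_exact_p_matches_brute_force_permutations(self, a, b):
        if len(a) + len(b) > 10:
            return
        r = onset_contrast(a, b)
        assert r.method == "exact"
        # independent oracle: enumerate distinct allocations directly on
        # the pooled data values
        from scipy.stats import rankdata
        pooled = np.array(a + b, dtype=float)
        n, n2 = len(pooled), len(b)
        ranks = rankdata(pooled)
        mu = n2 * (n + 1) / 2
        obs = abs(ranks[len(a):].sum() - mu)
        hits = total = 0
        for comb in itertools.combinations(range(n), n2):
            total += 1
            hits += abs(ranks[list(comb)].sum() - mu) >= obs - 1e-12
        assert r.pvalue == pytest.approx(hits / total)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 35)
        r = onset_contrast(a, b)
        assert r.method == "normal"
        from scipy.stats import mannwhitneyu
        p_scipy = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic",
                               use_continuity=False).pvalue
        assert r.pvalue == pytest.approx(p_scipy, rel=1e-9)
        assert len(a) + len(b) > EXACT_ENUMERATION_MAX_N

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            onset_contrast([], [1.0])


class TestPlantedModeRecovery:
    def test_post_onset_dominant_mode_recovers_plant(self, surrogate_track):
        """Mirror of the focal-onset recovery property: across seeds the
        dominant post-onset mode sits within 2 Hz of the planted frequency
        and its loadings concentrate on the SOZ channels."""
        for seed in range(5):
            sur, track = surrogate_track(seed)
            idx = track.onset_windows(10, fully_after=True)
            freqs, soz_load, off_load = [], [], []
            soz = list(sur.soz_channels)
            off = [c for c in range(20) if c not in sur.soz_channels]
            for i in idx:
                modes = decompose(track[i])
                dom = max(modes, key=lambda m: m.stability)
                freqs.append(dom.frequency)
                soz_load.append(dom.loadings[soz].mean())
                off_load.append(dom.loadings[off].mean())
            assert abs(np.mean(freqs) - sur.f_ictal) < 2.0
            assert np.mean(soz_load) > 0.7
            assert np.mean(off_load) < 0.3


class TestSubsampleRobustness:
    def test_noop_condition_equals_full_analysis(self, surrogate_track):
        sur, track = surrogate_track(0)
        rec = sur.recording
        grid = subsample_robustness(rec, [rec.fs], [rec.n_channels],
                                    n_rep=1, seed=0)
        band_rows = grid[grid.band == "gamma"]
        assert len(band_rows) == 1
        from dynstab.modes import DEFAULT_BANDS, band_summary_per_window
        direct = band_summary_per_window(track, DEFAULT_BANDS[0])
        assert band_rows.iloc[0]["mean_max_loading"] == pytest.approx(
            direct["max_loading"].mean())

    def test_grid_shape(self):
        rng = np.random.default_rng(2)
        rec = Recording(data=rng.standard_normal((6, 4096)), fs=512.0)
        bands = (BandDefinition("lo", 1, 30), BandDefinition("hi", 30, 120))
        grid = subsample_robustness(rec, [512.0, 256.0], [6, 3], n_rep=2,
                                    seed=1, bands=bands)
        assert len(grid) == 2 * 2 * 2 * 2

    def test_two_channels_support_one_oscillation(self):
        rng = np.random.default_rng(3)
        rec = Recording(data=rng.standard_normal((6, 4096)), fs=512.0)
        wide = (BandDefinition("all", 0.0001, 256.0),)
        grid = subsample_robustness(rec, [512.0], [2], n_rep=2, seed=4,
                                    bands=wide)
        # floor(n/2) oscillatory (nonzero-frequency) modes at most
        assert np.all(grid["mean_n_modes"] <= 1.0)
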