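"""Motion metrics, scrubbing, filtering, nuisance regression and FC extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcbiomarker.connectivity import (
    FcVector,
    FrameMask,
    MotionTrace,
    NuisanceSignals,
    RoiTimeSeries,
    bandpass,
    cohort_fc_matrix,
    edge_pairs,
    exclude_zero_variance_rois,
    fc_vector,
    frame_displacement,
    mean_relative_displacement,
    nuisance_regress,
    scrub_mask,
)

rng = np.random.default_rng(42)


class TestMeanRelativeDisplacement:
    def test_constant_trace_is_zero(self):
        m = MotionTrace(np.ones((20, 6)))
        assert np.array_equal(mean_relative_displacement(m), np.zeros(6))

    def test_single_bump_forced_arithmetic(self):
        data = np.zeros((3, 6))
        data[1, 2] = 1.0  # parameter tz goes 0 → 1 → 0
        got = mean_relative_displacement(MotionTrace(data))
        expected = np.zeros(6)
        expected[2] = 1.0  # (|1| + |−1|) / 2
        assert np.allclose(got, expected)

    def test_matches_loop_oracle(self):
        data = rng.standard_normal((50, 6))
        got = mean_relative_displacement(MotionTrace(data))
        oracle = np.zeros(6)
        for j in range(6):
            acc = 0.0
            for i in range(49):
                acc += abs(data[i + 1, j] - data[i, j])
            oracle[j] = acc / 49
        assert np.allclose(got, oracle, atol=1e-12)

    def test_single_frame_fails(self):
        with pytest.raises(ValueError):
            mean_relative_displacement(MotionTrace(np.zeros((1, 6))))


class TestFrameDisplacement:
    def test_flat_trace(self):
        assert np.array_equal(
            frame_displacement(MotionTrace(np.zeros((10, 6)))), np.zeros(9)
        )

    def test_single_translation_step(self):
        data = np.zeros((5, 6))
        data[2:, 0] = 0.6
        fd = frame_displacement(MotionTrace(data))
        assert np.allclose(fd, [0.0, 0.6, 0.0, 0.0])

    def test_matches_loop_oracle_mm(self):
        data = rng.standard_normal((40, 6))
        fd = frame_displacement(MotionTrace(data, rotation_units="mm"))
        oracle = [
            sum(abs(data[t + 1, j] - data[t, j]) for j in range(6))
            for t in range(39)
        ]
        assert np.allclose(fd, oracle, atol=1e-12)

    def test_angular_rotations_converted_to_arc_length(self):
        data = np.zeros((3, 6))
        data[1, 3] = 0.01  # radians
        fd = frame_displacement(
            MotionTrace(data, rotation_units="radians"), head_radius_mm=50.0
        )
        assert np.allclose(fd, [0.5, 0.5])  # 0.01 rad × 50 mm

    def test_undeclared_units_fail(self):
        with pytest.raises(ValueError, match="rotation_units"):
            frame_displacement(MotionTrace(np.zeros((5, 6)), rotation_units=None))


class TestScrubMask:
    def test_all_below_threshold_keeps_everything(self):
        mask = scrub_mask(np.full(9, 0.2))
        assert mask.n_retained == 10

    def test_single_exceedance_removes_four_frame_window(self):
        fd = np.zeros(9)
        fd[4] = 0.7  # transition frames 4→5 flags frame 5
        mask = scrub_mask(fd)
        removed = np.flatnonzero(~mask.retained)
        assert list(removed) == [4, 5, 6, 7]
        assert mask.n_retained == 6

    def test_adjacent_exceedances_union_windows(self):
        fd = np.zeros(11)
        fd[3] = 0.8
        fd[4] = 0.8
        mask = scrub_mask(fd)
        removed = set(np.flatnonzero(~mask.retained))
        assert removed == {3, 4, 5, 6, 7}  # union, no double counting

    @pytest.mark.parametrize("seed", range(5))
    def test_removal_count_matches_window_union_oracle(self, seed):
        local = np.random.default_rng(seed)
        fd = local.uniform(0, 1, size=30)
        mask = scrub_mask(fd, threshold_mm=0.5)
        union = set()
        for t in np.flatnonzero(fd > 0.5):
            union |= set(range(max(t, 0), min(t + 4, 31)))
        assert mask.n_frames - mask.n_retained == len(union)
        assert set(np.flatnonzero(~mask.retained)) == union


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=60))
def test_scrub_removal_equals_window_union(fd_values):
    """Removed-frame count always equals the union of 4-frame windows."""
    fd = np.asarray(fd_values)
    mask = scrub_mask(fd, threshold_mm=0.5)
    union = set()
    for t in np.flatnonzero(fd > 0.5):
        union |= set(range(t, min(t + 4, fd.size + 1)))
    assert set(np.flatnonzero(~mask.retained)) == union


class TestBandpass:
    @staticmethod
    def tone_amplitude(signal_1d, freq_hz, tr):
        """FFT amplitude of one column at the driven frequency."""
        spectrum = np.fft.rfft(signal_1d)
        freqs = np.fft.rfftfreq(signal_1d.size, d=tr)
        return 2 * np.abs(spectrum[np.argmin(np.abs(freqs - freq_hz))]) / signal_1d.size

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(512) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, tr_seconds=2.0)[:, 0]
        trim = slice(64, -64)
        amp_in = self.tone_amplitude(x[trim], 0.05, 2.0)
        amp_out = self.tone_amplitude(y[trim], 0.05, 2.0)
        assert amp_out == pytest.approx(amp_in, rel=0.05)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(2048) * 0.5  # TR 0.5 s → Nyquist 1 Hz
        x = np.sin(2 * np.pi * 0.5 * t)
        y = bandpass(x, tr_seconds=0.5)[:, 0]
        trim = slice(256, -256)
        amp_in = self.tone_amplitude(x[trim], 0.5, 0.5)
        amp_out = self.tone_amplitude(y[trim], 0.5, 0.5)
        assert amp_out < 0.1 * amp_in

    def test_zero_input_zero_output(self):
        assert np.allclose(bandpass(np.zeros((100, 3)), 2.0), 0.0)

    def test_band_outside_nyquist_fails(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros((100, 2)), tr_seconds=2.0, high_hz=0.3)

    def test_too_few_frames_fails(self):
        with pytest.raises(ValueError, match="frames"):
            bandpass(np.zeros((10, 2)), tr_seconds=2.0)


class TestNuisanceRegress:
    def make_inputs(self, n=200):
        series = rng.standard_normal((n, 4))
        motion = MotionTrace(0.01 * rng.standard_normal((n, 6)))
        nuisance = NuisanceSignals(rng.standard_normal((n, 3)))
        return series, motion, nuisance

    def test_series_equal_to_regressor_gives_zero_residual(self):
        n = 200
        motion = MotionTrace(0.01 * rng.standard_normal((n, 6)))
        nuisance = NuisanceSignals(rng.standard_normal((n, 3)))
        filtered_global = bandpass(nuisance.data, 2.0)[:, 2]
        series = np.column_stack([filtered_global, 2.0 * filtered_global])
        resid = nuisance_regress(series, motion, nuisance, 2.0)
        assert np.abs(resid).max() < 1e-8

    def test_residuals_orthogonal_to_design(self):
        series, motion, nuisance = self.make_inputs()
        resid = nuisance_regress(series, motion, nuisance, 2.0)
        design = np.column_stack(
            [np.ones(200), motion.data, bandpass(nuisance.data, 2.0)]
        )
        inner = design.T @ resid
        scale = np.linalg.norm(design, axis=0)[:, None] * np.linalg.norm(
            resid, axis=0
        )
        assert np.all(np.abs(inner) <= 1e-8 * np.maximum(scale, 1.0))

    def test_matches_normal_equations_oracle(self):
        series, motion, nuisance = self.make_inputs()
        resid = nuisance_regress(series, motion, nuisance, 2.0)
        design = np.column_stack(
            [np.ones(200), motion.data, bandpass(nuisance.data, 2.0)]
        )
        beta = np.linalg.solve(design.T @ design, design.T @ series)
        oracle = series - design @ beta
        assert np.allclose(resid, oracle, atol=1e-10)

    def test_collinear_design_named(self):
        series, motion, nuisance = self.make_inputs()
        bad = motion.data.copy()
        bad[:, 1] = bad[:, 0]  # ty duplicates tx
        with pytest.raises(ValueError, match="collinear"):
            nuisance_regress(series, MotionTrace(bad), nuisance, 2.0)

    def test_frame_count_mismatch(self):
        series, motion, nuisance = self.make_inputs()
        with pytest.raises(ValueError, match="mismatch"):
            nuisance_regress(series[:100], motion, nuisance, 2.0)


class TestFcVector:
    def make_series(self, data):
        return RoiTimeSeries(
            "sub-x", data, 2.0, [f"R{k}" for k in range(data.shape[1])]
        )

    def test_identical_columns_correlate_to_one(self):
        col = rng.standard_normal(50)
        fc = fc_vector(self.make_series(np.column_stack([col, col])))
        assert fc.values[0] == pytest.approx(1.0)

    def test_negated_column_correlates_to_minus_one(self):
        col = rng.standard_normal(50)
        fc = fc_vector(self.make_series(np.column_stack([col, -col])))
        assert fc.values[0] == pytest.approx(-1.0)

    def test_matches_pairwise_loop_oracle(self):
        data = rng.standard_normal((60, 5))
        fc = fc_vector(self.make_series(data))
        for k, (i, j) in enumerate(fc.edge_index):
            oracle = np.corrcoef(data[:, i], data[:, j])[0, 1]
            assert fc.values[k] == pytest.approx(oracle, abs=1e-12)

    def test_mask_restricts_frames(self):
        data = rng.standard_normal((40, 3))
        mask = FrameMask(np.arange(40) < 20)
        fc = fc_vector(self.make_series(data), mask)
        oracle = np.corrcoef(data[:20], rowvar=False)
        assert fc.values[0] == pytest.approx(oracle[0, 1], abs=1e-12)

    def test_zero_variance_roi_is_named(self):
        data = rng.standard_normal((40, 3))
        data[:, 1] = 7.0
        with pytest.raises(ValueError, match="R1"):
            fc_vector(self.make_series(data))

    def test_too_few_retained_frames(self):
        data = rng.standard_normal((40, 3))
        with pytest.raises(ValueError, match="retained"):
            fc_vector(self.make_series(data), FrameMask(np.arange(40) < 5))

    def test_permutation_equivariance(self):
        data = rng.standard_normal((60, 5))
        perm = [3, 0, 4, 1, 2]
        fc = fc_vector(self.make_series(data))
        fc_p = fc_vector(self.make_series(data[:, perm]))
        for k, (i, j) in enumerate(fc_p.edge_index):
            oi, oj = sorted((perm[i], perm[j]))
            orig_k = next(
                kk
                for kk, (a, b) in enumerate(fc.edge_index)
                if (a, b) == (oi, oj)
            )
            assert fc_p.values[k] == pytest.approx(fc.values[orig_k], abs=1e-12)


class TestZeroVarianceExclusion:
    def make_cohort(self, n_participants=4, n_rois=5, flat=()):
        cohort = []
        for p in range(n_participants):
            data = rng.standard_normal((40, n_rois))
            for pp, roi in flat:
                if pp == p:
                    data[:, roi] = 1.23
            cohort.append(
                (
                    RoiTimeSeries(
                        f"sub-{p}", data, 2.0, [f"R{k}" for k in range(n_rois)]
                    ),
                    None,
                )
            )
        return cohort

    def test_no_flat_rois_identity(self):
        retained, report = exclude_zero_variance_rois(self.make_cohort())
        assert retained == [f"R{k}" for k in range(5)]
        assert report == {}

    def test_one_flat_roi_dropped_for_all(self):
        retained, report = exclude_zero_variance_rois(
            self.make_cohort(flat=[(2, 3)])
        )
        assert "R3" not in retained
        assert report == {"R3": ["sub-2"]}

    def test_matches_brute_force_scan(self):
        flat = [(0, 1), (3, 1), (2, 4)]
        cohort = self.make_cohort(flat=flat)
        retained, report = exclude_zero_variance_rois(cohort)
        brute = set()
        for series, _ in cohort:
            for k in range(5):
                if series.data[:, k].var() < 1e-12:
                    brute.add(series.roi_names[k])
        assert set(report) == brute
        assert [r for r in cohort[0][0].roi_names if r not in brute] == retained


def test_edge_pairs_is_bijection():
    pairs = edge_pairs(7)
    assert pairs.shape == (21, 2)
    assert len({tuple(p) for p in pairs}) == 21
    assert np.all(pairs[:, 0] < pairs[:, 1])


def test_cohort_fc_matrix_shapes_and_edge_names(planted_cohort):
    fc, attrs, _ = planted_cohort
    assert fc.shape == (16, 45)
    assert fc.columns[0] == "ROI000__ROI001"
    assert np.all(np.abs(fc.to_numpy()) <= 1.0)
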