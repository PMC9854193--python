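"""Normalization, SNR, initiation detection, activation classes, plateau and
memory statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryotrace import synth
from embryotrace.trace_quant import (
    ActivationRecord,
    AlleleTracePair,
    RoiMeasurement,
    classify_activation,
    detect_initiation,
    measure_movie,
    memory_statistics,
    normalized_intensity,
    plateau_time,
    snr,
)


class TestNormalizedIntensity:
    @pytest.mark.parametrize(
        "roi1,roi2,expected", [(100.0, 100.0, 0.0), (300.0, 100.0, 2.0)]
    )
    def test_arithmetic(self, roi1, roi2, expected):
        m = RoiMeasurement(t=0.0, roi1_max=roi1, roi2_mean=roi2)
        assert normalized_intensity(m) == pytest.approx(expected)

    def test_unidentified_puncta_assigned_to_background(self):
        m = RoiMeasurement(t=0.0, roi1_max=500.0, roi2_mean=100.0, identified=False)
        assert normalized_intensity(m) == 0.0

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            normalized_intensity(RoiMeasurement(0.0, 10.0, 0.0))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1000.0), st.floats(1.0, 1000.0), st.floats(0.01, 100.0))
    def test_invariant_to_joint_multiplicative_gain(self, gain, roi2, excess):
        # the photobleaching-correction claim, exactly
        roi1 = roi2 + excess
        plain = normalized_intensity(RoiMeasurement(0.0, roi1, roi2))
        gained = normalized_intensity(RoiMeasurement(0.0, gain * roi1, gain * roi2))
        assert gained == pytest.approx(plain, rel=1e-9)


class TestSnr:
    def test_zero_when_signal_equals_background(self):
        assert snr(50.0, 50.0, 10.0) == 0.0

    def test_forced_arithmetic(self):
        assert snr(150.0, 50.0, 10.0) == pytest.approx(10.0)

    def test_synthetic_movie_snr_matches_amplitude_over_noise(self):
        # SNR definition applied to ground truth, averaged over seeds
        amp, sigma = 80.0, 5.0
        values = []
        for seed in range(15):
            movie = synth.gen_spot_movie(
                [(32, 32, amp, 1.0)], background_mean=100.0, noise_sd=sigma,
                n_frames=1, seed=seed,
            )
            df = measure_movie(movie, [(32, 32)], roi1_diameter_um=3.0,
                               pixel_size_um=0.5)
            values.append(snr(df["roi1_max"][0], df["roi2_mean"][0],
                              df["roi2_sd"][0]))
        # the annulus still contains a little spot light, and the disc max
        # rides on noise, so the match is approximate
        assert np.mean(values) == pytest.approx(amp / sigma, rel=0.15)


class TestMeasureMovie:
    def test_flat_image_measures_background_everywhere(self):
        movie = synth.gen_spot_movie([], background_mean=7.0, n_frames=2, seed=0)
        df = measure_movie(movie, [(32, 32)])
        assert np.allclose(df["roi1_max"], 7.0)
        assert np.allclose(df["roi2_mean"], 7.0)
        assert np.allclose(df["roi2_sd"], 0.0)

    def test_single_bright_pixel_max(self):
        frames = np.full((1, 64, 64), 10.0)
        frames[0, 30, 30] = 110.0
        df = measure_movie(frames, [(30, 30)], roi1_diameter_um=2.0,
                           pixel_size_um=0.5)
        assert df["roi1_max"][0] == 110.0
        assert df["roi2_mean"][0] == pytest.approx(10.0)

    def test_bleaching_movie_has_time_invariant_normalized_trace(self):
        movie = synth.gen_spot_movie(
            [(32, 32, 60.0, 2.0)], background_mean=100.0, noise_sd=0.0,
            n_frames=10, seed=0, bleach_tau_frames=5.0,
        )
        df = measure_movie(movie, [(32, 32)])
        norm = (df["roi1_max"] - df["roi2_mean"]) / df["roi2_mean"]
        assert np.all(np.abs(norm - norm[0]) / norm[0] < 0.01)


class TestDetectInitiation:
    T = np.arange(0, 40, 2.0)

    def test_all_zero_trace_has_no_initiation(self):
        assert detect_initiation(np.zeros_like(self.T), self.T, 0.5) is None

    def test_single_frame_spike_debounced(self):
        vals = np.zeros_like(self.T)
        vals[5] = 10.0
        assert detect_initiation(vals, self.T, 0.5, min_consecutive=2) is None
        assert detect_initiation(vals, self.T, 0.5, min_consecutive=1) == 10.0

    def test_reports_first_of_the_consecutive_run(self):
        vals = np.zeros_like(self.T)
        vals[7:] = 1.0
        assert detect_initiation(vals, self.T, 0.5) == 14.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.abs(rng.normal(size=30)).cumsum() * rng.uniform(0.01, 1.0)
        t = np.arange(30.0)
        lo = detect_initiation(vals, t, 0.2)
        hi = detect_initiation(vals, t, 2.0)
        if hi is not None:
            assert lo is not None and lo <= hi

    def test_synthetic_offsets_20_and_42_give_difference_22(self):
        t = np.arange(0, 120, 2.0)
        mk = lambda t0: np.clip((t - t0) / 30.0, 0, 1)
        pair = AlleleTracePair("c", "de_novo", t, mk(20.0), mk(42.0))
        rec = classify_activation(pair, threshold=0.2, same_time_window=2.0)
        assert rec.time_difference_min == pytest.approx(22.0, abs=2.0)
        assert rec.pattern == "sequential"


class TestClassifyActivation:
    T = np.arange(0, 60, 5.0)

    def _pair(self, v1, v2):
        return AlleleTracePair("c", "de_novo", self.T, v1, v2)

    def test_neither_allele_fires(self):
        rec = classify_activation(self._pair(np.zeros(12), np.zeros(12)), 0.5)
        assert rec.pattern == "none" and rec.time_difference_min is None

    def test_one_allele_only(self):
        v1 = np.zeros(12)
        v1[4:] = 2.0
        rec = classify_activation(self._pair(v1, np.zeros(12)), 0.5)
        assert rec.pattern == "one_allele"

    def test_simultaneous_firing_is_same_time(self):
        v = np.zeros(12)
        v[4:] = 2.0
        rec = classify_activation(self._pair(v, v.copy()), 0.5, same_time_window=5.0)
        assert rec.pattern == "same_time" and rec.time_difference_min == 0.0

    def test_every_pair_gets_exactly_one_pattern(self):
        cohort = synth.gen_trace_pairs(
            synth.TracePairParams(n_cells=30, p_silent_second_allele=0.3, seed=3)
        )
        patterns = [
            classify_activation(p, 0.15, same_time_window=2.0).pattern
            for p in cohort.pairs
        ]
        assert set(patterns) <= {"none", "one_allele", "same_time", "sequential"}

    def test_silent_allele_fraction_recovered(self):
        # cohort simulated with a 38% silent second allele, as seen for the
        # eppk1 de novo cycle
        p_silent = 0.3818
        cohort = synth.gen_trace_pairs(
            synth.TracePairParams(n_cells=400, p_silent_second_allele=p_silent,
                                  seed=5)
        )
        recs = [classify_activation(p, 0.15, same_time_window=2.0)
                for p in cohort.pairs]
        frac = np.mean([r.pattern == "one_allele" for r in recs])
        # binomial tolerance: 3 SE at n=400
        assert abs(frac - p_silent) < 3 * np.sqrt(p_silent * (1 - p_silent) / 400)


class TestPlateauTime:
    def test_step_function_plateaus_at_the_step(self):
        t = np.arange(0, 50, 2.0)
        vals = np.where(t >= 10.0, 3.0, 0.0)
        assert plateau_time(vals, t, smooth_window=1) == 10.0

    def test_linear_ramp_reaches_90pct_at_09T(self):
        t = np.linspace(0, 100, 101)
        vals = t / 100.0
        assert plateau_time(vals, t, fraction=0.9, smooth_window=1) == pytest.approx(90.0)

    def test_all_zero_trace_has_no_plateau(self):
        assert plateau_time(np.zeros(10), np.arange(10.0)) is None

    def test_de_novo_vs_reactivation_cohort_kinetics(self):
        # slow de novo rise (~180 min) vs fast post-mitotic rise (~25 min)
        slow = synth.gen_trace_pairs(synth.TracePairParams(
            n_cells=20, n_timepoints=120, dt_min=2.0, plateau_time=180.0,
            first_init_mean=0.0, first_init_sd=0.0, offset_mean=0.0,
            offset_sd=0.0, seed=6))
        fast = synth.gen_trace_pairs(synth.TracePairParams(
            n_cells=20, n_timepoints=120, dt_min=2.0, plateau_time=25.0,
            first_init_mean=0.0, first_init_sd=0.0, offset_mean=0.0,
            offset_sd=0.0, seed=7, cycle="reactivation"))
        t_slow = np.mean([plateau_time(p.allele1, p.t_min) for p in slow.pairs])
        t_fast = np.mean([plateau_time(p.allele1, p.t_min) for p in fast.pairs])
        # with initiation at t=0 the 90% point sits near 0.9 x rise time
        assert t_slow == pytest.approx(0.9 * 180.0, rel=0.15)
        assert t_fast == pytest.approx(0.9 * 25.0, rel=0.25)
        assert t_slow > 4 * t_fast


class TestMemoryStatistics:
    def _rec(self, cycle, diff):
        return ActivationRecord("c", cycle, 0.0, diff, "sequential", diff)

    def test_identical_differences_have_zero_sd(self):
        recs = [self._rec("a", 5.0) for _ in range(4)]
        summary, _ = memory_statistics(recs)
        assert summary["sd_min"].iloc[0] == pytest.approx(0.0)

    def test_identical_groups_give_p_near_one(self):
        recs = [self._rec("a", d) for d in (1, 2, 3)] + [
            self._rec("b", d) for d in (1, 2, 3)
        ]
        _, p = memory_statistics(recs)
        assert p == pytest.approx(1.0)

    def test_generator_echo_within_two_standard_errors(self):
        cohort = synth.gen_trace_pairs(synth.TracePairParams(
            n_cells=55, offset_mean=44.2, offset_sd=33.5, n_timepoints=130,
            seed=8))
        recs = [classify_activation(p, 0.15, same_time_window=2.0)
                for p in cohort.pairs]
        summary, _ = memory_statistics(recs)
        assert abs(summary["mean_min"].iloc[0] - 44.2) < 2 * 33.5 / np.sqrt(55)

    def test_small_group_has_no_sd(self):
        recs = [self._rec("a", 5.0)]
        summary, p = memory_statistics(recs)
        assert np.isnan(summary["sd_min"].iloc[0])
        assert p is None
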