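"""MCQ family and global zigzag index: hand oracles, ranges, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eicqc.eic_quality import (
    QualityError,
    background_index,
    effective_peak_intensity,
    filter_eics,
    global_zigzag_index,
    mcq_index,
    score_eic,
    smooth_chromatogram,
    spike_index,
)


class TestSmoothing:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth_chromatogram(np.full(10, 7.0), 5), np.full(10, 7.0))

    def test_edge_truncation_hand_example(self):
        np.testing.assert_allclose(smooth_chromatogram(np.array([0.0, 3.0, 0.0]), 3),
                                   [1.5, 1.0, 1.5])

    def test_interior_impulse_reduced_by_window(self):
        series = np.zeros(11)
        series[5] = 9.0
        smoothed = smooth_chromatogram(series, 3)
        assert smoothed[5] == pytest.approx(3.0)

    @pytest.mark.parametrize("window", [2, 4, 13])
    def test_bad_window_rejected(self, window):
        with pytest.raises(QualityError):
            smooth_chromatogram(np.arange(10.0), window)


class TestSpikeIndex:
    def test_smooth_ramp_is_near_one(self):
        assert spike_index(np.linspace(1, 100, 50)) >= 0.999

    def test_spike_strictly_lowers_index(self):
        clean = np.ones(30) * 10.0
        clean[10:20] = [10, 20, 40, 70, 90, 90, 70, 40, 20, 10]
        spiked = clean.copy()
        spiked[25] *= 50
        assert spike_index(spiked) < spike_index(clean)

    def test_all_zero_rejected(self):
        with pytest.raises(QualityError):
            spike_index(np.zeros(10))


class TestBackgroundIndex:
    def test_matches_closed_form(self):
        """Cosine of a series with its centered self equals sd/sqrt(sd^2+mean^2)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            series = rng.uniform(0, 50, 40)
            sd = series.std()
            expected = sd / np.sqrt(sd**2 + series.mean() ** 2)
            assert background_index(series) == pytest.approx(expected, rel=1e-9)

    def test_offset_strictly_decreases_index(self):
        series = np.array([0, 1, 5, 20, 5, 1, 0], dtype=float)
        assert background_index(series + 100.0) < background_index(series)

    def test_zero_baseline_peak_near_one(self):
        series = np.zeros(60)
        series[30] = 1000.0
        assert background_index(series) > 0.95

    def test_constant_rejected(self):
        with pytest.raises(QualityError):
            background_index(np.full(10, 3.0))


class TestMCQ:
    def test_clean_gaussian_high(self):
        # the background index of a peak of width sigma in an N-long window is
        # sqrt(1 - 2*sqrt(pi)*sigma/N); N=200, sigma=4 leaves room above 0.95
        x = np.arange(200.0)
        series = 100 * np.exp(-0.5 * ((x - 100) / 4) ** 2)
        assert mcq_index(series) >= 0.95

    def test_high_flat_background_low_despite_good_peak(self):
        """The known failure mode: one clean peak on heavy background scores low."""
        x = np.arange(60.0)
        series = 2000 + 100 * np.exp(-0.5 * ((x - 30) / 4) ** 2)
        assert mcq_index(series) < 0.3

    def test_range_clamped_over_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            series = rng.uniform(0, 100, rng.integers(10, 80))
            assert 0.0 <= mcq_index(series) <= 1.0

    def test_bounded_by_sub_indices(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            series = rng.uniform(0, 100, 50)
            m = mcq_index(series)
            assert m <= min(spike_index(series), background_index(series)) + 0.05

    def test_degenerate_series_rejected(self):
        with pytest.raises(QualityError):
            mcq_index(np.zeros(10))
        with pytest.raises(QualityError):
            mcq_index(np.full(10, 5.0))


class TestEPI:
    def test_zero_baseline_triangle(self):
        assert effective_peak_intensity(np.array([0, 1, 2, 1, 0.0])) == 2.0

    def test_minimum_baseline_rule(self):
        assert effective_peak_intensity(np.array([10, 11, 20, 11, 10.0])) == 10.0

    def test_constant_series_zero(self):
        assert effective_peak_intensity(np.full(5, 4.0)) == 0.0


class TestGlobalZigzag:
    def test_linear_ramp_is_zero(self):
        assert global_zigzag_index(np.array([0, 1, 2, 3, 4.0])) == 0.0

    def test_triangle_hand_value(self):
        assert global_zigzag_index(np.array([0, 1, 2, 1, 0.0])) == pytest.approx(0.2)

    def test_alternating_hand_value(self):
        assert global_zigzag_index(np.array([0, 4, 0, 4, 0.0])) == pytest.approx(2.4)

    def test_range_bound_and_supremum(self):
        """Index stays below 4 and alternating series approach 4 as N grows."""
        values = []
        for n in range(5, 501):
            series = np.zeros(n)
            series[1::2] = 7.0
            values.append(global_zigzag_index(series))
        assert max(values) < 4.0
        assert values[-1] > 3.9

    def test_random_series_within_range(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            series = rng.uniform(0, 100, rng.integers(5, 120))
            if series.max() > series.min():
                assert 0.0 <= global_zigzag_index(series) < 4.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.uniform(0, 100, 30)
        if series.max() == series.min():
            return
        base = global_zigzag_index(series)
        for c in (0.01, 3.0, 1e4):
            assert global_zigzag_index(c * series) == pytest.approx(base, rel=1e-9)

    def test_shift_invariance_exact(self):
        """Adding a constant moves the baseline estimate with it, leaving EPI fixed."""
        series = np.array([0, 3, 9, 4, 1, 0.0])
        assert effective_peak_intensity(series + 50) == effective_peak_intensity(series)
        assert global_zigzag_index(series + 50) == pytest.approx(global_zigzag_index(series))

    def test_flat_series_rejected(self):
        with pytest.raises(QualityError):
            global_zigzag_index(np.full(10, 2.0))


class TestFilterAndFailureCases:
    def _eics_with_reports(self):
        from eicqc.eic_extraction import EIC

        rng = np.random.default_rng(0)
        eics = []
        for i in range(12):
            x = np.arange(80.0)
            series = 50 + 500 * np.exp(-0.5 * ((x - 40) / (3 + i)) ** 2)
            series *= 1 + 0.02 * i * rng.uniform(-1, 1, 80)
            eics.append(EIC(i, 100.0 + i, 0, 79, np.maximum(series, 0),
                            np.full(80, 100.0 + i), x * 1.2))
        return eics, [score_eic(e) for e in eics]

    def test_mcq_min_zero_keeps_all(self):
        eics, reports = self._eics_with_reports()
        assert len(filter_eics(eics, reports, mcq_min=0.0, mode="mcq")) == len(eics)

    def test_threshold_extremes_bracket_keepset(self):
        eics, reports = self._eics_with_reports()
        kept = [len(filter_eics(eics, reports, zigzag_max=z, mode="zigzag"))
                for z in (1e-9, 0.01, 0.1, 0.9, 4.0)]
        assert kept[0] == 0
        assert kept[-1] == len(eics)
        assert all(a <= b for a, b in zip(kept, kept[1:]))

    def test_missing_report_rejected(self):
        eics, reports = self._eics_with_reports()
        with pytest.raises(QualityError):
            filter_eics(eics, reports[:-1], mode="zigzag")

    def test_mcq_and_zigzag_disagree_on_failure_cases(self):
        """High flat background + clean peak: MCQ rejects, zigzag keeps.
        Alternation-dominated noise: both reject."""
        x = np.arange(100.0)
        background_case = 2000 + 300 * np.exp(-0.5 * ((x - 50) / 4) ** 2)
        noise_case = np.full(100, 50.0)
        noise_case[1::2] = 400.0
        rng = np.random.default_rng(3)
        noise_case *= 1 + 0.1 * rng.uniform(-1, 1, 100)
        assert mcq_index(background_case) < 0.6  # MCQ calls a fine EIC bad
        assert global_zigzag_index(background_case) < 0.9  # zigzag keeps it
        assert mcq_index(noise_case) < 0.6
        assert global_zigzag_index(noise_case) > 0.9  # both flag genuine garbage

    def test_score_eic_marks_degenerate_metrics_none(self):
        from eicqc.eic_extraction import EIC

        eic = EIC(0, 100.0, 0, 9, np.full(10, 5.0), np.full(10, 100.0),
                  np.arange(10) * 1.2)
        report = score_eic(eic)
        assert report.mcq_index is None
        assert report.zigzag_index is None
        assert report.epi == 0.0
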