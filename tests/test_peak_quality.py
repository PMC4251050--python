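"""The six peak metrics: hand oracles, orderings, the combined filter, clustering."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

from eicqc.eic_quality import QualityError
from eicqc.peak_quality import (
    PeakQualityReport,
    filter_peaks,
    gaussian_similarity,
    local_zigzag_index,
    normalized_metric_matrix,
    peak_significance,
    sharpness,
    tpasr,
)
from eicqc.synthetic_data import SyntheticSpec, TruthPeak, generate_eic, peak_shape


from _cases import BAD_CASES, GOOD_CASES, best_scored as _best_scored, case_eic as _case_eic


@pytest.fixture(scope="module")
def case_reports():
    return [_best_scored(_case_eic(**kw)) for kw in GOOD_CASES + BAD_CASES]


class TestSharpness:
    def test_hand_example(self):
        assert sharpness(np.array([1, 2, 4, 2, 1.0]), 2) == pytest.approx(4.0)

    def test_flat_slice_zero(self):
        assert sharpness(np.full(5, 3.0), 2) == 0.0

    def test_taller_apex_strictly_sharper(self):
        lo = sharpness(np.array([1, 2, 4, 2, 1.0]), 2)
        hi = sharpness(np.array([1, 2, 8, 2, 1.0]), 2)
        assert hi > lo

    def test_zero_points_offset_before_ratio(self):
        # boundary zeros are routine; the slice is offset by 1 unit first
        value = sharpness(np.array([0, 2, 4, 2, 0.0]), 2)
        assert np.isfinite(value) and value > 0

    def test_too_short_rejected(self):
        with pytest.raises(QualityError):
            sharpness(np.array([1.0, 2.0]), 1)


class TestGaussianSimilarity:
    def test_pure_gaussian_self_fit(self):
        x = np.arange(40.0)
        series = 100 * np.exp(-0.5 * ((x - 20) / 4) ** 2)
        assert gaussian_similarity(series, 20) >= 0.999

    def test_tailed_scores_below_symmetric_twin(self):
        rts = np.arange(150) * 1.2
        sym = peak_shape(TruthPeak(mz=200.0, rt_apex=90.0, height=1, sigma=5), rts, 1.2)
        tail = peak_shape(TruthPeak(mz=200.0, rt_apex=90.0, height=1, sigma=5,
                                    tail_tau=10.0), rts, 1.2)
        g_sym = gaussian_similarity(1000 * sym[50:100], int(np.argmax(sym[50:100])))
        g_tail = gaussian_similarity(1000 * tail[50:110], int(np.argmax(tail[50:110])))
        assert g_tail < g_sym - 0.005

    def test_high_baseline_does_not_fake_gaussianity(self):
        rng = np.random.default_rng(0)
        flatnoise = 5000 + rng.uniform(-50, 50, 40)
        assert gaussian_similarity(flatnoise, int(np.argmax(flatnoise))) < 0.9

    def test_too_short_rejected(self):
        with pytest.raises(QualityError):
            gaussian_similarity(np.array([0, 1, 0.0]), 1)


class TestSNR:
    def test_noiseless_peak_large(self):
        report = _best_scored(_case_eic(height=1000, sigma_s=5, zigzag=0.0))
        assert report.snr >= 20

    def test_strictly_decreasing_with_noise(self):
        values = [_best_scored(_case_eic(height=1000, sigma_s=5, zigzag=amp, seed=7)).snr
                  for amp in (0.0, 0.1, 0.3)]
        assert values[0] > values[1] > values[2]


class TestPeakSignificance:
    def test_hand_example(self):
        value = peak_significance(np.array([1, 1, 5, 1, 1.0]), 2,
                                  apex_halfwin=1, edge_count=1)
        assert value == pytest.approx(7 / 3)

    def test_flat_slice_is_one(self):
        assert peak_significance(np.full(7, 4.0), 3) == pytest.approx(1.0)

    def test_zero_boundaries_give_infinity(self):
        value = peak_significance(np.array([0, 0, 9, 0, 0.0]), 2)
        assert value == np.inf

    def test_too_short_rejected(self):
        with pytest.raises(QualityError):
            peak_significance(np.array([1, 2, 1.0]), 1, edge_count=2)


class TestTPASR:
    def test_discrete_triangle_is_zero(self):
        assert tpasr(np.array([0, 2, 4, 2, 0.0])) == pytest.approx(0.0)

    def test_impulse_hand_value(self):
        assert tpasr(np.array([0, 0, 4, 0, 0.0])) == pytest.approx(0.5)

    def test_zero_apex_rejected(self):
        with pytest.raises(QualityError):
            tpasr(np.zeros(5))


class TestLocalZigzag:
    def test_triangle_matches_global_definition(self):
        assert local_zigzag_index(np.array([0, 1, 2, 1, 0.0])) == pytest.approx(0.2)

    def test_smooth_gaussian_slice_small(self):
        x = np.arange(30.0)
        series = 100 * np.exp(-0.5 * ((x - 15) / 4) ** 2)
        assert local_zigzag_index(series) < 0.05


class TestScorePeakRegimes:
    def test_clean_gaussian_all_good(self):
        r = _best_scored(_case_eic(height=2000, sigma_s=5, zigzag=0.02))
        assert r.sharpness >= 2.0
        assert r.gaussian_similarity >= 0.9
        assert r.snr >= 1.3
        assert r.peak_significance >= 3.0
        assert r.tpasr <= 0.8
        assert r.zigzag <= 0.1

    def test_noisy_low_blob_bad_regime(self):
        good = _best_scored(_case_eic(height=2000, sigma_s=5, zigzag=0.02, seed=5))
        bad = _best_scored(_case_eic(height=15, sigma_s=5, baseline=20,
                                     zigzag=0.3, seed=5))
        assert bad.sharpness < good.sharpness / 3
        assert bad.peak_significance < good.peak_significance / 3
        assert bad.zigzag > good.zigzag

    def test_tailed_peak_low_gaussian_others_good(self):
        tailed = _best_scored(_case_eic(height=2500, sigma_s=4, tau_s=9.0, zigzag=0.01))
        symmetric = _best_scored(_case_eic(height=2500, sigma_s=4, zigzag=0.01))
        assert tailed.gaussian_similarity < symmetric.gaussian_similarity
        assert tailed.sharpness >= 2.0 and tailed.tpasr <= 0.8


class TestCombinedFilter:
    def test_all_disabled_keeps_all(self, case_reports):
        flags = filter_peaks(case_reports, sharpness_min=None, gauss_min=None,
                             snr_min=None, signif_min=None, tpasr_max=None,
                             zigzag_max=None)
        assert all(flags)

    def test_defaults_separate_good_from_bad_cases(self, case_reports):
        """At the combined defaults the six good case peaks pass, the six bad fail."""
        flags = filter_peaks(case_reports)
        assert flags[:6] == [True] * 6
        assert flags[6:] == [False] * 6

    def test_tightening_any_threshold_shrinks_keepset(self, case_reports):
        base = sum(filter_peaks(case_reports))
        tighter = [
            dict(sharpness_min=50.0), dict(gauss_min=0.999), dict(snr_min=1e6),
            dict(signif_min=1e6), dict(tpasr_max=1e-6), dict(zigzag_max=1e-9),
        ]
        for kw in tighter:
            assert sum(filter_peaks(case_reports, **kw)) <= base

    def test_missing_metric_fails_its_clause(self):
        report = PeakQualityReport(eic_id=0, scan_apex=0, sharpness=None,
                                   gaussian_similarity=0.9, snr=5.0,
                                   peak_significance=5.0, tpasr=0.1, zigzag=0.1)
        assert filter_peaks([report]) == [False]
        assert filter_peaks([report], sharpness_min=None) == [True]

    def test_infinite_significance_passes(self):
        report = PeakQualityReport(eic_id=0, scan_apex=0, sharpness=5.0,
                                   gaussian_similarity=0.9, snr=5.0,
                                   peak_significance=float("inf"), tpasr=0.1, zigzag=0.1)
        assert filter_peaks([report]) == [True]


class TestMetricStructure:
    def test_two_cluster_partition_separates_good_from_bad(self, case_reports):
        """Normalized six-metric vectors of the 12 case peaks split exactly
        into the good and bad groups under average-linkage clustering."""
        mat = normalized_metric_matrix(case_reports)
        assert np.all(mat >= -1.0 - 1e-9) and np.all(mat <= 1.0 + 1e-9)
        labels = fcluster(linkage(mat, method="average"), 2, criterion="maxclust")
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_good_bad_ordering_across_seeds(self):
        """Good peaks beat bad peaks on sharpness/significance (higher) and
        zigzag (lower) in at least 95% of seeded draws."""
        wins = compared = 0
        for s in range(40):
            good = _best_scored(_case_eic(height=2000, sigma_s=5, zigzag=0.05, seed=100 + s))
            try:
                bad = _best_scored(_case_eic(height=13, sigma_s=5, baseline=20,
                                             zigzag=0.15, seed=200 + s))
            except AssertionError:
                continue  # a blob so poor the detector never saw it
            compared += 1
            if (good.sharpness > bad.sharpness
                    and good.peak_significance > bad.peak_significance
                    and good.zigzag < bad.zigzag):
                wins += 1
        assert compared >= 30
        assert wins >= 0.95 * compared

    def test_sharpness_significance_snr_rank_correlated(self):
        """The redundant trio rises and falls together across random peaks."""
        from eicqc.eic_extraction import EIC
        from eicqc.synthetic_data import SyntheticSpec, TruthPeak, generate_eic

        # peaks of varying height over a *constant absolute* noise floor —
        # the regime where taller means sharper, more significant, and
        # higher SNR all at once (a high noise_floor makes the jitter
        # amplitude level-independent)
        def abs_noise_eic(height, sigma_s, seed):
            spec = SyntheticSpec(
                truth_peaks=[TruthPeak(mz=200.0, rt_apex=90.0, height=height,
                                       sigma=sigma_s)],
                n_scans=150, scan_rate=1.2, baseline_level=100.0,
                zigzag_amplitude=0.004, noise_floor=10000.0, seed=seed,
            )
            series, _ = generate_eic(spec)
            return EIC(0, 200.0, 0, 149, series, np.full(150, 200.0), spec.rts)

        rng = np.random.default_rng(0)
        reports = []
        for s in range(120):
            reports.append(_best_scored(abs_noise_eic(
                float(10 ** rng.uniform(2.5, 4.0)),
                float(rng.uniform(3, 7)),
                1000 + s,
            )))
        sh = [r.sharpness for r in reports]
        sig = [r.peak_significance for r in reports]
        snr = [r.snr for r in reports]
        assert spearmanr(sh, sig).statistic > 0
        assert spearmanr(sh, snr).statistic > 0
        assert spearmanr(sig, snr).statistic > 0
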