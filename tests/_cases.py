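"""The twelve case chromatographic peaks shared by quality and acceptance tests.

Six good peaks — ideal, high baseline, long tail, apex dip, zigzag-but-good,
garden variety — and six bad twins (low humps on an elevated base with rough
point-to-point noise).
"""

import numpy as np

from eicqc.eic_extraction import EIC
from eicqc.peak_detection import detect_peaks
from eicqc.peak_quality import score_peak
from eicqc.synthetic_data import SyntheticSpec, TruthPeak, generate_eic

GOOD_CASES = [
    dict(height=3000, sigma_s=5, seed=11),
    dict(height=2500, sigma_s=6, baseline=400, seed=12),
    dict(height=2800, sigma_s=5, tau_s=4.0, seed=13),
    dict(height=2600, sigma_s=5, seed=14, dip=True),
    dict(height=2200, sigma_s=4, baseline=10, zigzag=0.10, seed=15),
    dict(height=4000, sigma_s=7, tau_s=1.5, baseline=20, zigzag=0.05, seed=16),
]
BAD_CASES = [
    dict(height=14, sigma_s=5, baseline=20, zigzag=0.15, seed=21),
    dict(height=11, sigma_s=6, baseline=25, zigzag=0.18, seed=22),
    dict(height=12, sigma_s=5, tau_s=4.0, baseline=20, zigzag=0.15, seed=23),
    dict(height=13, sigma_s=7, baseline=30, zigzag=0.15, seed=24),
    dict(height=14, sigma_s=4, baseline=20, zigzag=0.18, seed=25),
    dict(height=11, sigma_s=6, tau_s=2.0, baseline=25, zigzag=0.15, seed=26),
]


def case_eic(height, sigma_s, tau_s=0.0, baseline=5.0, zigzag=0.02, seed=0, dip=False):
    spec = SyntheticSpec(
        truth_peaks=[TruthPeak(mz=200.0, rt_apex=90.0, height=height,
                               sigma=sigma_s, tail_tau=tau_s)],
        n_scans=150, scan_rate=1.2, baseline_level=baseline,
        zigzag_amplitude=zigzag, noise_floor=3.0, seed=seed,
    )
    series, _ = generate_eic(spec)
    if dip:
        series[int(np.argmax(series))] *= 0.55
    return EIC(0, 200.0, 0, 149, series, np.full(150, 200.0), spec.rts)


def best_scored(eic):
    peaks = detect_peaks(eic)
    assert peaks, "fixture must contain a detectable peak"
    return score_peak(eic, max(peaks, key=lambda p: p.cwt_coeff))


def case_reports():
    return [best_scored(case_eic(**kw)) for kw in GOOD_CASES + BAD_CASES]
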