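"""End-to-end four-stage pipeline: extract -> QC EICs -> detect -> QC peaks."""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

from .eic_extraction import EIC, extract_eics
from .eic_quality import EICQualityReport, filter_eics, score_eic
from .lcms_io import LCMSRun, PeakRecord, PipelineConfig
from .peak_detection import ChromPeak, detect_peaks
from .peak_quality import PeakQualityReport, filter_peaks, score_peak


@dataclass
class PipelineRunRecord:
    """Bookkeeping for one pipeline run: config snapshot and per-stage counts."""

    config: dict
    seed: int
    n_points: int = 0
    n_eics: int = 0
    n_eics_kept: int = 0
    n_peaks_detected: int = 0
    n_peaks_kept: int = 0
    started_at: float = field(default_factory=time.time)
    finished_at: float | None = None


@dataclass
class PipelineResult:
    kept_records: list[PeakRecord]
    kept_peaks: list[ChromPeak]
    kept_reports: list[PeakQualityReport]
    eics: list[EIC]
    eic_reports: list[EICQualityReport]
    all_peaks: list[ChromPeak]
    all_reports: list[PeakQualityReport]
    record: PipelineRunRecord


def peak_to_record(eic: EIC, peak: ChromPeak) -> PeakRecord:
    return PeakRecord(
        eic_id=peak.eic_id,
        mz_apex=peak.mz_apex,
        rt_apex=peak.rt_apex,
        scan_apex=peak.scan_apex,
        scan_left=peak.scan_left,
        scan_right=peak.scan_right,
        source="eicqc",
    )


def run_pipeline(run: LCMSRun, config: PipelineConfig | None = None,
                 eic_filter: bool = True, peak_filter: bool = True) -> PipelineResult:
    """Run all four stages on a centroided run.

    The two filtering stages can be disabled individually (for sweeps and
    ablation comparisons).  Deterministic for a fixed run and config.
    """
    config = config or PipelineConfig()
    record = PipelineRunRecord(config=asdict(config), seed=config.seed,
                               n_points=run.n_points)

    eics = extract_eics(run, ppm_tolerance=config.ppm_tolerance,
                        min_trace_points=config.min_trace_points,
                        max_gap=config.max_gap)
    record.n_eics = len(eics)

    eic_reports = [score_eic(e, window=config.smooth_window) for e in eics]
    if eic_filter:
        kept_eics = filter_eics(eics, eic_reports, mcq_min=config.mcq_min,
                                zigzag_max=config.eic_zigzag_max,
                                mode=config.eic_filter_mode)
    else:
        kept_eics = list(eics)
    record.n_eics_kept = len(kept_eics)

    scales = range(config.cwt_scale_min, config.cwt_scale_max + 1)
    by_id = {e.eic_id: e for e in eics}
    all_peaks: list[ChromPeak] = []
    for eic in kept_eics:
        all_peaks.extend(
            detect_peaks(eic, scales=scales, snr_floor=config.snr_floor,
                         min_width=config.min_peak_width,
                         max_width=config.max_peak_width,
                         smooth_window=config.smooth_window)
        )
    record.n_peaks_detected = len(all_peaks)

    all_reports = [score_peak(by_id[p.eic_id], p) for p in all_peaks]
    if peak_filter:
        flags = filter_peaks(all_reports,
                             sharpness_min=config.sharpness_min,
                             gauss_min=config.gauss_min,
                             snr_min=config.snr_min,
                             signif_min=config.signif_min,
                             tpasr_max=config.tpasr_max,
                             zigzag_max=config.peak_zigzag_max)
    else:
        flags = [True] * len(all_peaks)
    kept_peaks = [p for p, f in zip(all_peaks, flags) if f]
    kept_reports = [r for r, f in zip(all_reports, flags) if f]
    record.n_peaks_kept = len(kept_peaks)
    record.finished_at = time.time()

    return PipelineResult(
        kept_records=[peak_to_record(by_id[p.eic_id], p) for p in kept_peaks],
        kept_peaks=kept_peaks,
        kept_reports=kept_reports,
        eics=eics,
        eic_reports=eic_reports,
        all_peaks=all_peaks,
        all_reports=all_reports,
        record=record,
    )
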