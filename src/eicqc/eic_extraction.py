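"""Acute EIC extraction by region-of-interest (mass-trace) tracking.

Centroid points are chained across scans into regions of interest: a point
extends an open ROI when its m/z lies within the ppm tolerance of the ROI's
running intensity-weighted mean m/z.  ROIs that receive no point for more
than ``max_gap`` consecutive scans are closed; closed ROIs with fewer than
``min_trace_points`` points are discarded.  This is the tracing alternative
to fixed-m/z binning, which splits an analyte whose m/z drifts across a bin
edge.

The resulting EIC stores a *dense* per-scan intensity series between its
first and last scan — gap scans are zero-filled — because the quality
indices are defined on a contiguous series I_1..I_N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lcms_io import LCMSRun


@dataclass
class EIC:
    """One extracted ion chromatogram (mass trace)."""

    eic_id: int
    mz_center: float
    scan_first: int
    scan_last: int
    intensities: np.ndarray  # dense, length N = scan_last - scan_first + 1
    mz_trace: np.ndarray  # per-scan m/z, NaN on gap scans
    rts: np.ndarray  # seconds, per scan of the dense series

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mz_trace = np.asarray(self.mz_trace, dtype=float)
        self.rts = np.asarray(self.rts, dtype=float)
        if len(self.intensities) != self.N:
            raise ValueError("dense series length must equal scan span")

    @property
    def N(self) -> int:
        return self.scan_last - self.scan_first + 1

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.intensities))


class _ROI:
    __slots__ = ("scans", "mzs", "intens", "last_scan", "weighted_mz", "weight")

    def __init__(self, scan: int, mz: float, intensity: float):
        self.scans = [scan]
        self.mzs = [mz]
        self.intens = [intensity]
        self.last_scan = scan
        self.weighted_mz = mz * max(intensity, 1e-12)
        self.weight = max(intensity, 1e-12)

    @property
    def center(self) -> float:
        return self.weighted_mz / self.weight

    def add(self, scan: int, mz: float, intensity: float) -> None:
        self.scans.append(scan)
        self.mzs.append(mz)
        self.intens.append(intensity)
        self.last_scan = scan
        w = max(intensity, 1e-12)
        self.weighted_mz += mz * w
        self.weight += w


def _close(roi: _ROI, run: LCMSRun) -> EIC:
    first, last = roi.scans[0], roi.scans[-1]
    n = last - first + 1
    intens = np.zeros(n)
    mz_trace = np.full(n, np.nan)
    for s, mz, inten in zip(roi.scans, roi.mzs, roi.intens):
        intens[s - first] = inten
        mz_trace[s - first] = mz
    return EIC(
        eic_id=-1,
        mz_center=roi.center,
        scan_first=first,
        scan_last=last,
        intensities=intens,
        mz_trace=mz_trace,
        rts=run.rts[first : last + 1].copy(),
    )


def extract_eics(
    run: LCMSRun,
    ppm_tolerance: float = 40.0,
    min_trace_points: int = 5,
    max_gap: int = 2,
) -> list[EIC]:
    """Extract EICs from a centroided run by ROI tracking.

    Every centroid point joins at most one ROI; when one scan offers several
    candidate points for the same ROI the closest in m/z wins and the losers
    may seed new ROIs.  EIC ids are assigned in (scan_first, mz_center)
    order after extraction.
    """
    if ppm_tolerance <= 0:
        raise ValueError("ppm_tolerance must be > 0")
    open_rois: list[_ROI] = []
    finished: list[EIC] = []

    for scan in range(run.n_scans):
        mzs = run.mz_arrays[scan]
        intens = run.intensity_arrays[scan]
        # greedy nearest-m/z assignment of this scan's points to open ROIs
        candidates = []
        for ri, roi in enumerate(open_rois):
            center = roi.center
            tol = center * ppm_tolerance * 1e-6
            for pi in range(len(mzs)):
                d = abs(mzs[pi] - center)
                if d <= tol:
                    candidates.append((d, ri, pi))
        candidates.sort()
        taken_roi: set[int] = set()
        taken_pt: set[int] = set()
        for _, ri, pi in candidates:
            if ri in taken_roi or pi in taken_pt:
                continue
            open_rois[ri].add(scan, float(mzs[pi]), float(intens[pi]))
            taken_roi.add(ri)
            taken_pt.add(pi)
        for pi in range(len(mzs)):
            if pi not in taken_pt:
                open_rois.append(_ROI(scan, float(mzs[pi]), float(intens[pi])))
        # close ROIs that have been silent longer than max_gap
        still_open = []
        for roi in open_rois:
            if scan - roi.last_scan > max_gap:
                if len(roi.scans) >= min_trace_points:
                    finished.append(_close(roi, run))
            else:
                still_open.append(roi)
        open_rois = still_open

    for roi in open_rois:
        if len(roi.scans) >= min_trace_points:
            finished.append(_close(roi, run))

    finished.sort(key=lambda e: (e.scan_first, e.mz_center))
    for i, eic in enumerate(finished):
        eic.eic_id = i
    return finished


def max_ppm_deviation(eic: EIC) -> float:
    """Largest relative deviation (ppm) of any trace point from the EIC center."""
    mz = eic.mz_trace[np.isfinite(eic.mz_trace)]
    if len(mz) == 0:
        return 0.0
    return float(np.max(np.abs(mz - eic.mz_center)) / eic.mz_center * 1e6)
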