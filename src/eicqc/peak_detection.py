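"""Chromatographic peak detection by continuous-wavelet-transform ridges.

A Mexican-hat (Ricker) CWT is computed over a grid of scales; local maxima
of the coefficient rows are linked across adjacent scales into ridge lines;
each surviving ridge yields one candidate peak whose apex is the position
of the strongest coefficient along the ridge, snapped to the nearest local
maximum of the smoothed trace.  Boundaries are placed at the nearest local
minima of the smoothed trace on either side of the apex, capped at twice
the ridge's best scale so neighbouring peaks cannot bleed into each other.

Candidates are then vetted by width (5–50 scans by default, the usual
LC peak-width window) and by a wavelet-domain SNR: coefficient at the apex
and best scale over the 95th percentile of |scale-1 coefficients| near the
apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eic_extraction import EIC
from .eic_quality import smooth_chromatogram

DEFAULT_SCALES = tuple(range(1, 17))


def ricker_wavelet(n_points: int, scale: float) -> np.ndarray:
    """Ricker (Mexican hat) wavelet sampled at ``n_points`` integer offsets."""
    amp = 2.0 / (np.sqrt(3.0 * scale) * np.pi**0.25)
    t = np.arange(n_points) - (n_points - 1) / 2.0
    tsq = (t / scale) ** 2
    return amp * (1.0 - tsq) * np.exp(-tsq / 2.0)


def cwt_transform(series: np.ndarray, scales=DEFAULT_SCALES) -> np.ndarray:
    """Ricker CWT coefficients, shape (n_scales, len(series)).

    Edges are handled by reflective padding, so a peak hugging the start or
    end of a trace still produces a usable ridge.
    """
    series = np.asarray(series, dtype=float)
    scales = np.asarray(sorted(scales), dtype=float)
    if len(scales) == 0:
        raise ValueError("scale set must not be empty")
    n = len(series)
    out = np.empty((len(scales), n))
    for i, scale in enumerate(scales):
        width = min(10 * int(np.ceil(scale)) + 1, 2 * n - 1)
        kernel = ricker_wavelet(width, scale)
        half = width // 2
        padded = np.pad(series, half, mode="reflect") if n > 1 else series
        out[i] = np.convolve(padded, kernel[::-1], mode="valid")[:n]
    return out


def _local_maxima(row: np.ndarray) -> list[int]:
    """Indices of strict-or-plateau local maxima with positive value."""
    idx = []
    n = len(row)
    for i in range(n):
        left = row[i - 1] if i > 0 else -np.inf
        right = row[i + 1] if i < n - 1 else -np.inf
        if row[i] > 0 and row[i] >= left and row[i] > right:
            idx.append(i)
    return idx


@dataclass
class RidgeLine:
    """One ridge through the coefficient matrix: (scale index, position) pairs."""

    scale_idx: list[int]
    positions: list[int]
    coeffs: list[float]

    def __len__(self) -> int:
        return len(self.positions)

    def best(self) -> tuple[int, int, float]:
        """(scale_idx, position, coefficient) of the strongest ridge point."""
        k = int(np.argmax(self.coeffs))
        return self.scale_idx[k], self.positions[k], self.coeffs[k]


def find_ridge_lines(coeffs: np.ndarray, scales=DEFAULT_SCALES,
                     gap_max: int = 2, min_length: int = 3) -> list[RidgeLine]:
    """Link per-scale local maxima into ridge lines, largest scale downward.

    A ridge at position p on one scale row connects to a maximum on the
    next-smaller scale row if their distance is at most the current scale
    value; a ridge may miss up to ``gap_max`` consecutive rows before it is
    terminated.  Unclaimed maxima seed new ridges at every row.  Ridges
    shorter than ``min_length`` rows are dropped.
    """
    scales = sorted(scales)
    n_scales = coeffs.shape[0]
    ridges: list[RidgeLine] = []
    active: list[tuple[RidgeLine, int]] = []  # (ridge, gap counter)
    for row_idx in range(n_scales - 1, -1, -1):
        maxima = _local_maxima(coeffs[row_idx])
        unclaimed = set(maxima)
        next_active: list[tuple[RidgeLine, int]] = []
        for ridge, gap in active:
            tol = scales[row_idx]
            cands = [m for m in unclaimed if abs(m - ridge.positions[-1]) <= tol]
            if cands:
                m = min(cands, key=lambda c: (abs(c - ridge.positions[-1]), c))
                unclaimed.discard(m)
                ridge.scale_idx.append(row_idx)
                ridge.positions.append(m)
                ridge.coeffs.append(float(coeffs[row_idx, m]))
                next_active.append((ridge, 0))
            elif gap < gap_max:
                next_active.append((ridge, gap + 1))
            else:
                ridges.append(ridge)
        for m in sorted(unclaimed):
            next_active.append((RidgeLine([row_idx], [m], [float(coeffs[row_idx, m])]), 0))
        active = next_active
    ridges.extend(r for r, _ in active)
    return [r for r in ridges if len(r) >= min_length]


def cwt_snr(series: np.ndarray, apex_idx: int, apex_coeff: float,
            window: int = 50, eps: float = 1e-12) -> float:
    """Wavelet-domain SNR of a peak.

    Numerator: |CWT coefficient| at the apex at the ridge's best scale.
    Denominator: 95th percentile of |scale-1 coefficients| within
    +/- ``window`` scans of the apex, floored at ``eps``.
    """
    noise_row = cwt_transform(series, scales=[1])[0]
    lo = max(apex_idx - window, 0)
    hi = min(apex_idx + window + 1, len(series))
    noise = float(np.percentile(np.abs(noise_row[lo:hi]), 95))
    return abs(apex_coeff) / max(noise, eps)


@dataclass
class ChromPeak:
    """A detected chromatographic peak within one EIC."""

    eic_id: int
    p: int  # apex index within the slice, 0-based
    scan_apex: int
    scan_left: int
    scan_right: int
    mz_apex: float
    rt_apex: float  # seconds
    intensities: np.ndarray  # slice between boundaries, inclusive
    ridge_scale: float
    cwt_coeff: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.scan_left <= self.scan_apex <= self.scan_right):
            raise ValueError("boundaries must bracket the apex")
        if len(self.intensities) != self.N:
            raise ValueError("slice length must match boundary span")

    @property
    def N(self) -> int:
        return self.scan_right - self.scan_left + 1


def _walk_to_minimum(smoothed: np.ndarray, raw: np.ndarray, apex: int,
                     step: int, cap: int) -> int:
    """Boundary = argmin of the smoothed trace within ``cap`` of the apex.

    ``step`` is -1 (left) or +1 (right).  Scanning the whole capped window
    for the minimum (rather than stopping at the first uptick) keeps noisy
    flanks from truncating a peak mid-slope; a zero-intensity sample ends
    the scan early, because a gap is a natural peak boundary.
    """
    best = apex
    i = apex
    limit = apex + step * cap
    while True:
        j = i + step
        if j < 0 or j >= len(smoothed):
            break
        if (step > 0 and j > limit) or (step < 0 and j < limit):
            break
        i = j
        if smoothed[i] < smoothed[best]:
            best = i
        if raw[i] == 0:
            break
    return best


def _halfheight_core(series: np.ndarray, apex: int, left: int, right: int) -> tuple[int, int, int]:
    """Contiguous raw run through the apex above half height.

    Half height is measured above the slice minimum.  Returns
    (run length, run start, run end).  1-3-scan spikes have runs of 1-3;
    genuine chromatographic peaks (>= ~5 scans wide) run 4+.
    """
    base = series[left : right + 1].min()
    level = base + 0.5 * (series[apex] - base)
    lo = apex
    while lo > left and series[lo - 1] >= level:
        lo -= 1
    hi = apex
    while hi < right and series[hi + 1] >= level:
        hi += 1
    return hi - lo + 1, lo, hi


def _core_rise_ratio(series: np.ndarray, core_lo: int, core_hi: int,
                     left: int, right: int) -> float:
    """Largest scan-to-scan ratio across the apex core (run +/- 1 point).

    Measured on the baseline-subtracted slice plus 2% of its range, so a
    smooth flank entering the half-height region scores a few-fold at most,
    while a 1-3-scan spike (or two adjacent spikes masquerading as one
    peak) jumps an order of magnitude right at its core boundary.
    """
    lo = max(core_lo - 1, left)
    hi = min(core_hi + 1, right)
    window = series[lo : hi + 1]
    y = window - series[left : right + 1].min() + 0.02 * (series[left : right + 1].max() - series[left : right + 1].min())
    if np.any(y <= 0) or len(y) < 2:
        return float("inf")
    r = y[1:] / y[:-1]
    return float(max(r.max(), (1.0 / r).max()))


def detect_peaks(
    eic: EIC,
    scales=DEFAULT_SCALES,
    snr_floor: float = 0.0,
    min_width: int = 5,
    max_width: int = 50,
    smooth_window: int = 5,
    ridge_gap_max: int = 2,
    ridge_min_length: int = 3,
    min_fwhm: int = 4,
    trim_frac: float = 0.01,
    max_rise_ratio: float = 6.0,
) -> list[ChromPeak]:
    """Detect peaks in one EIC; returns peaks sorted by apex scan.

    Candidates come from CWT ridge lines; each is vetted by boundary width
    (``min_width``..``max_width`` scans), by the half-height run through
    the apex (``min_fwhm`` scans — this is what rejects 1-3-scan centroid
    spikes, which otherwise acquire padded boundaries wider than they are),
    and by wavelet SNR (``snr_floor``).  Boundaries from the local-minimum
    walk are trimmed inward to the ``trim_frac`` level above base so long
    shallow tails do not inflate the width.  The apex is the raw-intensity
    maximum inside the boundaries, so ``I[p]`` is always the slice maximum;
    ties break to the earlier scan.
    """
    series = eic.intensities
    n = len(series)
    if n < max(min_width, smooth_window):
        return []
    coeffs = cwt_transform(series, scales)
    ridges = find_ridge_lines(coeffs, scales, gap_max=ridge_gap_max, min_length=ridge_min_length)
    smoothed = smooth_chromatogram(series, smooth_window)
    scales_sorted = sorted(scales)

    candidates: dict[int, ChromPeak] = {}
    for ridge in ridges:
        scale_row, pos, coeff = ridge.best()
        best_scale = scales_sorted[scale_row]
        # snap to the nearest local maximum of the smoothed trace
        lo = max(pos - int(best_scale), 0)
        hi = min(pos + int(best_scale) + 1, n)
        local = lo + int(np.argmax(smoothed[lo:hi]))
        cap = int(2 * best_scale)
        left = _walk_to_minimum(smoothed, series, local, -1, cap)
        right = _walk_to_minimum(smoothed, series, local, +1, cap)
        if right - left + 1 < 2:
            continue
        # trim dead baseline/tail: pull boundaries in to the trim_frac level
        base = float(np.min(smoothed[left : right + 1]))
        level = base + trim_frac * (smoothed[local] - base)
        while left < local - 1 and smoothed[left] < level:
            left += 1
        while right > local + 1 and smoothed[right] < level:
            right -= 1
        # apex = raw maximum inside the boundaries (earliest on ties)
        apex = left + int(np.argmax(series[left : right + 1]))
        width = right - left + 1
        if width < min_width or width > max_width:
            continue
        run, core_lo, core_hi = _halfheight_core(series, apex, left, right)
        if run < min_fwhm:
            continue
        if _core_rise_ratio(series, core_lo, core_hi, left, right) > max_rise_ratio:
            continue
        snr = cwt_snr(series, apex, coeff)
        if snr < snr_floor:
            continue
        mz_apex = eic.mz_trace[apex]
        if not np.isfinite(mz_apex):
            mz_apex = eic.mz_center
        peak = ChromPeak(
            eic_id=eic.eic_id,
            p=apex - left,
            scan_apex=eic.scan_first + apex,
            scan_left=eic.scan_first + left,
            scan_right=eic.scan_first + right,
            mz_apex=float(mz_apex),
            rt_apex=float(eic.rts[apex]),
            intensities=series[left : right + 1].copy(),
            ridge_scale=float(best_scale),
            cwt_coeff=float(coeff),
            snr=float(snr),
        )
        prev = candidates.get(apex)
        if prev is None or peak.cwt_coeff > prev.cwt_coeff:
            candidates[apex] = peak

    peaks = sorted(candidates.values(), key=lambda p: p.scan_apex)
    # enforce disjoint boundary intervals between neighbours: split overlaps
    # at the inter-apex valley, or drop the weaker of an unsplittable pair
    pruned: list[ChromPeak] = []
    for peak in peaks:
        while pruned and peak is not None and peak.scan_left <= pruned[-1].scan_right:
            prev = pruned[-1]
            a = prev.scan_apex - eic.scan_first
            b = peak.scan_apex - eic.scan_first
            valley = a + 1 + int(np.argmin(smoothed[a + 1 : b])) if b - a > 1 else a
            prev_right = eic.scan_first + valley
            new_left = eic.scan_first + valley + 1
            splittable = prev_right >= prev.scan_apex and new_left <= peak.scan_apex
            if splittable:
                prev2 = _reslice(prev, eic, prev.scan_left, prev_right)
                peak2 = _reslice(peak, eic, new_left, peak.scan_right)
                splittable = prev2.N >= min_width and peak2.N >= min_width
            if splittable:
                pruned[-1] = prev2
                peak = peak2
                break
            if peak.cwt_coeff > prev.cwt_coeff:
                pruned.pop()  # re-check the survivor against the new last peak
            else:
                peak = None
        if peak is not None:
            pruned.append(peak)
    return pruned


def _reslice(peak: ChromPeak, eic: EIC, scan_left: int, scan_right: int) -> ChromPeak:
    left = scan_left - eic.scan_first
    right = scan_right - eic.scan_first
    return ChromPeak(
        eic_id=peak.eic_id,
        p=peak.scan_apex - scan_left,
        scan_apex=peak.scan_apex,
        scan_left=scan_left,
        scan_right=scan_right,
        mz_apex=peak.mz_apex,
        rt_apex=peak.rt_apex,
        intensities=eic.intensities[left : right + 1].copy(),
        ridge_scale=peak.ridge_scale,
        cwt_coeff=peak.cwt_coeff,
        snr=peak.snr,
    )
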