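"""The six chromatographic-peak quality metrics and the combined filter.

For a detected peak with slice intensities I_1..I_N between its boundaries
and apex index p:

* **sharpness** — summed relative rises from the left boundary to the apex
  plus relative falls from the apex to the right boundary:
  ``sum_{i=2..p} (I_i - I_{i-1})/I_{i-1} + sum_{i=p..N-1} (I_i - I_{i+1})/I_{i+1}``.
  Micro-scale: rewards tall apexes reached through consistent climbs.
* **Gaussian similarity** — cosine between the baseline-subtracted slice
  and a least-squares-fitted Gaussian; symmetric peaks score near 1.
* **SNR** — wavelet-domain ratio carried over from detection (apex
  coefficient at the ridge's best scale over the 95th percentile of
  |scale-1 coefficients| near the apex).
* **peak significance** — mean intensity near the apex over mean intensity
  near the two boundaries.
* **TPASR** — triangle peak area similarity ratio,
  ``|TPA - RPA| / TPA`` with ``TPA = 0.5 * (N - 1) * I_apex`` and
  ``RPA = sum(I)``; 0 means the peak fills its bounding triangle exactly.
* **local zigzag** — the global zigzag index applied to the slice.

High sharpness / Gaussian similarity / SNR / significance and low TPASR /
zigzag characterize a good peak; the combined filter is the conjunction of
the six threshold clauses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .eic_extraction import EIC
from .eic_quality import QualityError, global_zigzag_index
from .peak_detection import ChromPeak, cwt_snr


class GaussianFitError(QualityError):
    """Least-squares Gaussian fit failed to converge or produced NaNs."""


def sharpness(series: np.ndarray, p: int, zero_offset: float = 1.0) -> float:
    """Sharpness of a peak slice with apex at 0-based index ``p``.

    Relative point-to-point increments have the *previous-toward-apex*
    point in the denominator; if any slice point is zero (boundary zeros
    are routine after valley boundary placement) the whole slice is offset
    by ``zero_offset`` intensity units first.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 3:
        raise QualityError("sharpness requires at least 3 points")
    if not 0 <= p < n:
        raise QualityError("apex index outside slice")
    if np.any(series == 0):
        series = series + zero_offset
    left = np.sum((series[1 : p + 1] - series[:p]) / series[:p]) if p >= 1 else 0.0
    right = np.sum((series[p:-1] - series[p + 1 :]) / series[p + 1 :]) if p <= n - 2 else 0.0
    return float(left + right)


def _gauss(x: np.ndarray, height: float, center: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gaussian_similarity(series: np.ndarray, p: int) -> float:
    """Cosine between the baseline-subtracted slice and its fitted Gaussian.

    The slice minimum is subtracted before both the fit and the cosine —
    otherwise a high flat baseline makes any shape look Gaussian.  The fit
    is initialized from the apex and the full width at half maximum.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 4:
        raise QualityError("Gaussian similarity requires at least 4 points")
    y = series - series.min()
    if not np.any(y):
        raise QualityError("flat slice: no peak to fit")
    x = np.arange(n, dtype=float)
    half = y[p] / 2.0
    above = np.nonzero(y >= half)[0]
    fwhm = max(above[-1] - above[0], 1)
    try:
        popt, _ = curve_fit(
            _gauss, x, y,
            p0=[max(y[p], 1e-9), float(p), max(fwhm / 2.355, 0.5)],
            bounds=([0.0, -n, 0.1], [np.inf, 2.0 * n, 10.0 * n]),
            maxfev=5000,
        )
        fitted = _gauss(x, *popt)
    except (RuntimeError, ValueError) as exc:
        raise GaussianFitError(str(exc)) from exc
    if not np.all(np.isfinite(fitted)) or not np.any(fitted):
        raise GaussianFitError("degenerate Gaussian fit")
    value = float(np.dot(y, fitted) / (np.linalg.norm(y) * np.linalg.norm(fitted)))
    return min(max(value, 0.0), 1.0)


def snr(eic: EIC, peak: ChromPeak, window: int = 50) -> float:
    """Wavelet-domain SNR of a detected peak (recomputed from the EIC)."""
    apex_idx = peak.scan_apex - eic.scan_first
    return cwt_snr(eic.intensities, apex_idx, peak.cwt_coeff, window=window)


def peak_significance(series: np.ndarray, p: int, apex_halfwin: int = 1,
                      edge_count: int = 2) -> float:
    """Mean intensity near the apex over mean intensity near the boundaries.

    The apex window is ``[p - apex_halfwin, p + apex_halfwin]`` clipped to
    the slice; the boundary sample is the first and last ``edge_count``
    points.  A zero boundary mean returns +inf (a peak rising out of true
    zero background is maximally significant).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 2 * edge_count + 1:
        raise QualityError("slice too short for the requested edge windows")
    if not 0 <= p < n:
        raise QualityError("apex index outside slice")
    apex_mean = float(np.mean(series[max(p - apex_halfwin, 0) : min(p + apex_halfwin + 1, n)]))
    edge_mean = float(np.mean(np.concatenate([series[:edge_count], series[-edge_count:]])))
    if edge_mean == 0:
        return float("inf")
    return apex_mean / edge_mean


def tpasr(series: np.ndarray) -> float:
    """Triangle peak area similarity ratio, |TPA - RPA| / TPA.

    ``TPA = 0.5 * peak_width * apex_intensity`` with the width measured in
    scan units between the boundaries (N - 1); ``RPA`` is the raw summed
    intensity.  0 is ideal (a triangular peak); large values flag shapes
    whose area is far from the apex-and-boundaries triangle.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise QualityError("TPASR requires at least 2 points")
    apex = float(series.max())
    if apex == 0:
        raise QualityError("TPASR undefined for a zero-apex slice")
    tpa = 0.5 * (len(series) - 1) * apex
    rpa = float(series.sum())
    return abs(tpa - rpa) / tpa


def local_zigzag_index(series: np.ndarray) -> float:
    """Zigzag index of the peak slice itself (EPI taken from the slice)."""
    return global_zigzag_index(series)


@dataclass
class PeakQualityReport:
    """All six metrics for one detected peak; None marks a failed metric."""

    eic_id: int
    scan_apex: int
    sharpness: float | None
    gaussian_similarity: float | None
    snr: float | None
    peak_significance: float | None
    tpasr: float | None
    zigzag: float | None

    METRIC_NAMES = ("sharpness", "gaussian_similarity", "snr",
                    "peak_significance", "tpasr", "zigzag")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in self.METRIC_NAMES], dtype=float)


def score_peak(eic: EIC, peak: ChromPeak, apex_halfwin: int = 1,
               edge_count: int = 2, snr_window: int = 50) -> PeakQualityReport:
    """Compute all six metrics; individual metric errors become None."""
    series = peak.intensities

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except QualityError:
            return None

    return PeakQualityReport(
        eic_id=peak.eic_id,
        scan_apex=peak.scan_apex,
        sharpness=_try(sharpness, series, peak.p),
        gaussian_similarity=_try(gaussian_similarity, series, peak.p),
        snr=_try(snr, eic, peak, window=snr_window),
        peak_significance=_try(peak_significance, series, peak.p,
                               apex_halfwin, edge_count),
        tpasr=_try(tpasr, series),
        zigzag=_try(local_zigzag_index, series),
    )


def filter_peaks(
    reports: list[PeakQualityReport],
    sharpness_min: float | None = 2.0,
    gauss_min: float | None = 0.6,
    snr_min: float | None = 1.3,
    signif_min: float | None = 1.2,
    tpasr_max: float | None = 0.8,
    zigzag_max: float | None = 0.9,
) -> list[bool]:
    """Combined threshold filter; returns one keep-flag per report.

    A peak is kept iff every *enabled* clause passes (pass a threshold of
    None to disable its clause, e.g. for single-metric sweeps).  A missing
    (None) metric fails its clause; an infinite significance passes.
    """
    def ge(value, th):
        return th is None or (value is not None and value >= th)

    def le(value, th):
        return th is None or (value is not None and value <= th)

    return [
        ge(r.sharpness, sharpness_min)
        and ge(r.gaussian_similarity, gauss_min)
        and ge(r.snr, snr_min)
        and ge(r.peak_significance, signif_min)
        and le(r.tpasr, tpasr_max)
        and le(r.zigzag, zigzag_max)
        for r in reports
    ]


def normalized_metric_matrix(reports: list[PeakQualityReport]) -> np.ndarray:
    """Mean-subtract each metric and scale it into [-1, 1] across peaks.

    Infinite significance values are replaced by the largest finite value
    in the column before normalization; a missing metric raises, because a
    normalized comparison across peaks needs every entry.
    """
    mat = np.vstack([r.as_vector() for r in reports])
    if np.any(np.isnan(mat)):
        raise QualityError("cannot normalize: some peaks have missing metrics")
    for j in range(mat.shape[1]):
        col = mat[:, j]
        finite = col[np.isfinite(col)]
        if len(finite) == 0:
            raise QualityError("metric column entirely non-finite")
        col[~np.isfinite(col)] = finite.max()
        col -= col.mean()
        peak_abs = np.abs(col).max()
        if peak_abs > 0:
            col /= peak_abs
        mat[:, j] = col
    return mat
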