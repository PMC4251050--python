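"""EIC-level quality indices: the MCQ (CODA) family and the global zigzag index.

Two complementary views of chromatogram quality:

* The **MCQ index** (mass chromatographic quality, the CODA score) measures
  how much of a trace's energy is smooth, above-background signal.  It is
  the inner product of the unit-norm *smoothed* trace with the unit-norm
  *mean-subtracted* original, and factors into a spike index (cosine of the
  trace with its smoothed self) and a background index (cosine of the trace
  with its centered self).  Range [0, 1]; high is good.  Its known failure
  mode: a trace carrying one clean peak on a high flat background, or only
  a few points, scores low even though the local peak is fine.

* The **global zigzag index** measures point-to-point roughness: the energy
  of second differences, normalized by the trace length and the squared
  effective peak intensity,

      zigzag = sum_n (2*I_n - I_{n-1} - I_{n+1})^2 / (N * EPI^2),

  with EPI = apex intensity minus the baseline.  Range [0, 4); low is good.
  Because it only looks at local transitions it is indifferent to
  background level, which is precisely what the MCQ index is not.

Baseline rule: the baseline under the apex is estimated as the series
minimum, so EPI = max(I) - min(I).  With that estimator each second
difference is bounded by 2*EPI, which proves the index never reaches 4 and
makes it exactly invariant under adding a constant offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class QualityError(ValueError):
    """Series degenerate for the requested index (all-zero, constant, ...)."""


def smooth_chromatogram(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with edge truncation.

    At the boundaries the window simply loses the samples that fall outside
    the series (e.g. window 3 on [0,3,0] gives [1.5, 1, 1.5]).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if window % 2 == 0 or window < 3:
        raise QualityError("window must be odd and >= 3")
    if window > n:
        raise QualityError(f"window {window} exceeds series length {n}")
    half = window // 2
    cumsum = np.concatenate([[0.0], np.cumsum(series)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise QualityError("cosine undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def spike_index(series: np.ndarray, window: int = 5) -> float:
    """Cosine similarity of a trace with its smoothed self; ~1 when spike-free."""
    series = np.asarray(series, dtype=float)
    if not np.any(series):
        raise QualityError("spike index undefined for an all-zero series")
    return _cosine(series, smooth_chromatogram(series, window))


def background_index(series: np.ndarray) -> float:
    """Cosine similarity of a trace with its mean-subtracted self.

    Equals sd / sqrt(sd^2 + mean^2) in closed form; close to 1 when the
    trace has little constant background relative to its variation.
    """
    series = np.asarray(series, dtype=float)
    centered = series - series.mean()
    if not np.any(centered):
        raise QualityError("background index undefined for a constant series")
    return _cosine(series, centered)


def mcq_index(series: np.ndarray, window: int = 5) -> float:
    """CODA-style MCQ: unit-norm smoothed trace vs unit-norm centered trace.

    Clamped to [0, 1]; anti-correlation carries no extra quality meaning.
    """
    series = np.asarray(series, dtype=float)
    smoothed = smooth_chromatogram(series, window)
    centered = series - series.mean()
    if not np.any(centered):
        raise QualityError("MCQ undefined for a constant series")
    if not np.any(smoothed):
        raise QualityError("MCQ undefined for an all-zero series")
    value = _cosine(smoothed, centered)
    return float(min(max(value, 0.0), 1.0))


def effective_peak_intensity(series: np.ndarray) -> float:
    """EPI: apex intensity minus the baseline (series minimum).  Always >= 0."""
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise QualityError("EPI requires at least 3 points")
    return float(series.max() - series.min())


def global_zigzag_index(series: np.ndarray) -> float:
    """Second-difference energy normalized by N * EPI^2.  Range [0, 4).

    Vanishes on any linear series; approaches 4 on long alternating
    zero/apex series; raises on flat series (no peak to judge).
    """
    series = np.asarray(series, dtype=float)
    epi = effective_peak_intensity(series)
    if epi == 0:
        raise QualityError("zigzag index undefined: flat series (EPI = 0)")
    second_diff = 2.0 * series[1:-1] - series[:-2] - series[2:]
    return float(np.sum(second_diff**2) / (len(series) * epi**2))


@dataclass
class EICQualityReport:
    """All EIC-level indices for one trace; None marks a metric that errored."""

    eic_id: int
    spike_index: float | None
    background_index: float | None
    mcq_index: float | None
    epi: float | None
    zigzag_index: float | None


def score_eic(eic, window: int = 5) -> EICQualityReport:
    """Compute every EIC index, recording degenerate-series failures as None."""
    series = eic.intensities

    def _try(fn, *args):
        try:
            return fn(*args)
        except QualityError:
            return None

    return EICQualityReport(
        eic_id=eic.eic_id,
        spike_index=_try(spike_index, series, window),
        background_index=_try(background_index, series),
        mcq_index=_try(mcq_index, series, window),
        epi=_try(effective_peak_intensity, series),
        zigzag_index=_try(global_zigzag_index, series),
    )


def filter_eics(eics, reports, mcq_min: float = 0.6, zigzag_max: float = 0.9,
                mode: str = "zigzag"):
    """Keep high-quality EICs by threshold.

    ``mode="mcq"`` keeps traces with MCQ >= ``mcq_min``; ``mode="zigzag"``
    keeps traces with zigzag < ``zigzag_max``; ``mode="either"`` keeps a
    trace passing either test.  EICs whose relevant metric errored are
    rejected.
    """
    by_id = {r.eic_id: r for r in reports}
    kept = []
    for eic in eics:
        if eic.eic_id not in by_id:
            raise QualityError(f"missing quality report for EIC {eic.eic_id}")
        rep = by_id[eic.eic_id]
        mcq_ok = rep.mcq_index is not None and rep.mcq_index >= mcq_min
        zig_ok = rep.zigzag_index is not None and rep.zigzag_index < zigzag_max
        if mode == "mcq":
            keep = mcq_ok
        elif mode == "zigzag":
            keep = zig_ok
        elif mode == "either":
            keep = mcq_ok or zig_ok
        else:
            raise QualityError(f"unknown filter mode {mode!r}")
        if keep:
            kept.append(eic)
    return kept
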