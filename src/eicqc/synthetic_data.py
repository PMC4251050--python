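"""Synthetic centroided LC/MS runs with fully known planted peaks.

Real electrospray LC/MS chromatograms mix analyte peaks (5–50 scans wide,
sometimes tailed) with background level and drift, point-to-point "zigzag"
noise, and 1–3-scan centroiding spikes.  This module emulates exactly those
features so that extraction, quality scoring, detection and benchmarking can
all be exercised against a known truth table.

Design of the noise channels:

* **Zigzag noise** is a multiplicative, independently signed per-scan jitter
  of relative magnitude ``zigzag_amplitude`` applied to the local expected
  level (floored at ``noise_floor`` so empty baseline regions still jitter).
  This injects second-difference energy directly, which is what the zigzag
  quality index measures.
* **Spikes** are rectangular bursts of 1–3 scans at 5–20x the local level.
* **Decoy peaks** are low humps on an elevated base with rougher
  point-to-point noise than the analytes — the classic "bad peak": a peak
  detector will pick them up geometrically, but their apex barely clears
  the surrounding level, so sharpness and significance stay low.  They
  give the benchmark genuine false-positive pressure for the filters.
* **Mixed channels** emulate the bad *EIC* that still contains one
  fair-looking local peak: a modest smooth hump bridged by low background
  to a long stretch of full-swing alternating intensities.  Peak-level
  metrics alone accept the hump; only an EIC-level roughness filter
  removes the whole trace.

All randomness flows from the single integer ``seed`` through one
``numpy.random.Generator``; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lcms_io import LCMSRun, PeakRecord


class SyntheticSpecError(ValueError):
    """Invalid synthetic-run specification."""


@dataclass
class TruthPeak:
    """A planted chromatographic peak.

    ``sigma`` is the Gaussian width in seconds; ``tail_tau > 0`` convolves
    the Gaussian with an exponential decay of that time constant, producing
    an asymmetric peak with a long right tail (the shape is re-centred so
    the apex stays at ``rt_apex``).
    """

    mz: float
    rt_apex: float  # seconds
    height: float
    sigma: float  # seconds
    tail_tau: float = 0.0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.sigma <= 0 or self.tail_tau < 0 or self.mz <= 0:
            raise SyntheticSpecError("require height > 0, sigma > 0, tail_tau >= 0, mz > 0")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic run (or one EIC channel)."""

    truth_peaks: list[TruthPeak] = field(default_factory=list)
    n_scans: int = 600
    scan_rate: float = 1.2  # seconds per scan
    baseline_level: float = 20.0
    baseline_drift: float = 0.0  # intensity per scan
    zigzag_amplitude: float = 0.0  # fraction of local level
    spike_rate: float = 0.0  # spikes per 100 scans
    spike_width: int = 3  # maximum spike width, scans (1-3)
    ppm_jitter: float = 0.0  # per-scan m/z jitter envelope
    noise_floor: float = 0.0  # minimum local level the jitter acts on
    background_density: float = 0.0  # random background points per scan
    decoy_peaks: list[TruthPeak] = field(default_factory=list)
    decoy_zigzag: float = 0.15  # zigzag amplitude on decoy channels
    mixed_channels: int = 0  # bad-EIC channels: one fair hump + an alternating burst
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 10:
            raise SyntheticSpecError("n_scans must be >= 10")
        for name in ("scan_rate", "zigzag_amplitude", "spike_rate", "ppm_jitter",
                     "noise_floor", "background_density", "decoy_zigzag"):
            if getattr(self, name) < 0:
                raise SyntheticSpecError(f"{name} must be >= 0")
        if not 1 <= self.spike_width <= 3:
            raise SyntheticSpecError("spike_width must be in 1..3")

    @property
    def rts(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.scan_rate

    @property
    def duration(self) -> float:
        return (self.n_scans - 1) * self.scan_rate


def peak_shape(peak: TruthPeak, rts: np.ndarray, scan_rate: float) -> np.ndarray:
    """Unit-height shape of a planted peak sampled on the scan grid.

    Gaussian, optionally convolved with a normalized exponential-decay
    kernel (time constant ``tail_tau``) and rolled so the sampled apex sits
    at the scan nearest ``rt_apex``.
    """
    g = np.exp(-0.5 * ((rts - peak.rt_apex) / peak.sigma) ** 2)
    if peak.tail_tau > 0:
        n_kernel = max(3, int(np.ceil(6 * peak.tail_tau / scan_rate)))
        kernel = np.exp(-np.arange(n_kernel) * scan_rate / peak.tail_tau)
        kernel /= kernel.sum()
        g = np.convolve(g, kernel, mode="full")[: len(rts)]
        apex_target = int(np.argmin(np.abs(rts - peak.rt_apex)))
        g = np.roll(g, apex_target - int(np.argmax(g)))
        peak_max = g.max()
        if peak_max > 0:
            g = g / peak_max
    return g


def expected_eic(spec: SyntheticSpec, peaks: list[TruthPeak] | None = None) -> np.ndarray:
    """Noiseless expected intensity series: baseline + drift + planted peaks."""
    rts = spec.rts
    series = spec.baseline_level + spec.baseline_drift * np.arange(spec.n_scans)
    series = series.astype(float)
    for peak in peaks if peaks is not None else spec.truth_peaks:
        if not 0.0 <= peak.rt_apex <= spec.duration:
            raise SyntheticSpecError(f"peak rt_apex {peak.rt_apex} outside run span [0, {spec.duration}]")
        series += peak.height * peak_shape(peak, rts, spec.scan_rate)
    return series


def _apply_noise(series: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator,
                 zigzag_amplitude: float | None = None) -> np.ndarray:
    amp = spec.zigzag_amplitude if zigzag_amplitude is None else zigzag_amplitude
    out = series.copy()
    if amp > 0:
        local = np.maximum(series, spec.noise_floor)
        jitter = rng.uniform(-1.0, 1.0, len(series))  # independent sign and magnitude per scan
        out = out + amp * local * jitter
    if spec.spike_rate > 0:
        # spikes are centroiding/background artifacts: 1-3-scan bursts at
        # 5-20x the local *background* level (they must be confusable with
        # small peaks, not dwarf the analytes)
        n_spikes = rng.poisson(spec.spike_rate * spec.n_scans / 100.0)
        for _ in range(n_spikes):
            pos = int(rng.integers(0, len(series)))
            width = int(rng.integers(1, spec.spike_width + 1))
            gain = rng.uniform(5.0, 20.0)
            background = spec.baseline_level + spec.baseline_drift * pos
            out[pos : pos + width] += gain * max(background, spec.noise_floor, 1.0)
    return np.maximum(out, 0.0)


def generate_eic(spec: SyntheticSpec) -> tuple[np.ndarray, list[TruthPeak]]:
    """Generate one noisy intensity series for a single m/z channel.

    The noiseless expectation is ``baseline_level + drift*t + sum of peak
    shapes``; zigzag noise and spikes are then layered on.  Deterministic
    for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    series = expected_eic(spec)
    return _apply_noise(series, spec, rng), list(spec.truth_peaks)


def _check_mz_separation(spec: SyntheticSpec) -> None:
    peaks = spec.truth_peaks + spec.decoy_peaks
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i].mz, peaks[j].mz
            if a == b:  # intentional isomer pair sharing a channel
                continue
            if abs(a - b) / min(a, b) * 1e6 <= 3 * spec.ppm_jitter:
                raise SyntheticSpecError(
                    f"truth m/z {a} and {b} closer than 3x the ppm jitter envelope "
                    "and not an exact isomer pair"
                )


def generate_run(spec: SyntheticSpec) -> tuple[LCMSRun, list[TruthPeak]]:
    """Generate a full centroided run with one m/z channel per planted peak.

    Each channel contributes one centroid point per scan inside +/-4 sigma
    (plus tail) of its apex, with per-scan m/z jittered uniformly inside the
    ppm envelope; channels sharing an exact m/z (isomer pairs) are merged.
    Background points are scattered uniformly in m/z at
    ``background_density`` points per scan.  Deterministic given the seed.
    """
    _check_mz_separation(spec)
    if not spec.truth_peaks and not spec.decoy_peaks and spec.background_density == 0:
        raise SyntheticSpecError("empty truth set with zero background: nothing to emit")
    rng = np.random.default_rng(spec.seed)
    rts = spec.rts
    scan_mz: list[list[float]] = [[] for _ in range(spec.n_scans)]
    scan_int: list[list[float]] = [[] for _ in range(spec.n_scans)]

    # group channels by exact m/z so isomer pairs share one trace
    channels: dict[float, tuple[list[TruthPeak], float]] = {}
    for peak in spec.truth_peaks:
        channels.setdefault(peak.mz, ([], spec.zigzag_amplitude))[0].append(peak)
    for peak in spec.decoy_peaks:
        channels.setdefault(peak.mz, ([], spec.decoy_zigzag))[0].append(peak)

    for mz in sorted(channels):
        peaks, amp = channels[mz]
        series = _apply_noise(expected_eic(spec, peaks), spec, rng, zigzag_amplitude=amp)
        emit = np.zeros(spec.n_scans, dtype=bool)
        for peak in peaks:
            span = 4 * peak.sigma + 4 * peak.tail_tau
            emit |= np.abs(rts - peak.rt_apex) <= span
        for t in np.nonzero(emit)[0]:
            jit = rng.uniform(-1.0, 1.0) * spec.ppm_jitter * 1e-6
            scan_mz[t].append(mz * (1.0 + jit))
            scan_int[t].append(max(series[t], 1e-6))

    for k in range(spec.mixed_channels):
        mz = 700.0 + 37.0 * k + float(rng.uniform(-2.0, 2.0))
        hump_rt = float(rng.uniform(100.0, 350.0))
        hump_sigma = float(rng.uniform(4.0, 6.0))
        hump_height = float(rng.uniform(150.0, 220.0))
        base = spec.baseline_level + 5.0
        burst_level = float(rng.uniform(350.0, 450.0))
        burst_start = hump_rt + float(rng.uniform(80.0, 100.0))
        burst_scans = 200
        t0 = max(int((hump_rt - 5 * hump_sigma) / spec.scan_rate), 0)
        b0 = int(burst_start / spec.scan_rate)
        t1 = min(b0 + burst_scans, spec.n_scans - 1)
        hump = TruthPeak(mz=mz, rt_apex=hump_rt, height=hump_height, sigma=hump_sigma)
        series = expected_eic(spec, [hump]) - spec.baseline_level + base
        series = _apply_noise(series, spec, rng, zigzag_amplitude=0.3)
        phase = int(rng.integers(0, 2))
        for t in range(b0, t1 + 1):
            if (t - b0) % 2 == phase:
                series[t] = base + burst_level * float(rng.uniform(0.9, 1.1))
        for t in range(t0, t1 + 1):
            jit = rng.uniform(-1.0, 1.0) * spec.ppm_jitter * 1e-6
            scan_mz[t].append(mz * (1.0 + jit))
            scan_int[t].append(max(series[t], 1e-6))

    if spec.background_density > 0:
        all_mz = [p.mz for p in spec.truth_peaks + spec.decoy_peaks] or [100.0, 500.0]
        lo, hi = 0.8 * min(all_mz), 1.2 * max(all_mz)
        for t in range(spec.n_scans):
            for _ in range(rng.poisson(spec.background_density)):
                scan_mz[t].append(rng.uniform(lo, hi))
                scan_int[t].append(rng.exponential(max(spec.baseline_level, 1.0)) + 1.0)

    mz_arrays, int_arrays = [], []
    for t in range(spec.n_scans):
        order = np.argsort(scan_mz[t]) if scan_mz[t] else []
        mz_arrays.append(np.array(scan_mz[t], dtype=float)[order] if len(scan_mz[t]) else np.empty(0))
        int_arrays.append(np.array(scan_int[t], dtype=float)[order] if len(scan_int[t]) else np.empty(0))
    return LCMSRun(mz_arrays, int_arrays, rts.copy()), list(spec.truth_peaks)


def generate_toolset_peaklists(
    truth: list[TruthPeak],
    per_tool_recall: tuple[float, float, float],
    per_tool_fp: tuple[int, int, int],
    mz_jitter: float = 0.01,
    rt_jitter: float = 1.0,
    seed: int = 0,
    mz_range: tuple[float, float] = (80.0, 600.0),
    rt_range: tuple[float, float] = (0.0, 720.0),
    min_separation: tuple[float, float] = (0.125, 12.5),
) -> list[list[PeakRecord]]:
    """Simulate three peak-detection tools reporting on the same truth set.

    Tool *i* keeps a seeded random subset of the truth (``round(recall*n)``
    peaks), perturbs apex m/z and RT uniformly within the jitter bounds, and
    appends ``per_tool_fp[i]`` false peaks.  False peaks are rejection-
    sampled to stay at least ``min_separation`` (in Da, seconds) away from
    every truth peak and every other false peak so that consensus voting is
    unambiguous.
    """
    for r in per_tool_recall:
        if not 0.0 <= r <= 1.0:
            raise SyntheticSpecError("recalls must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    placed = [(p.mz, p.rt_apex) for p in truth]
    lists: list[list[PeakRecord]] = []
    names = ("tool_a", "tool_b", "tool_c")
    for tool_idx, (recall, n_fp) in enumerate(zip(per_tool_recall, per_tool_fp)):
        records: list[PeakRecord] = []
        n_keep = int(round(recall * len(truth)))
        kept = sorted(rng.choice(len(truth), size=n_keep, replace=False)) if n_keep else []
        for k in kept:
            peak = truth[k]
            records.append(
                PeakRecord(
                    eic_id=int(k),
                    mz_apex=peak.mz + rng.uniform(-mz_jitter, mz_jitter),
                    rt_apex=peak.rt_apex + rng.uniform(-rt_jitter, rt_jitter),
                    scan_apex=int(round(peak.rt_apex / 1.2)),
                    source=names[tool_idx],
                )
            )
        for f in range(n_fp):
            for _ in range(1000):
                mz = rng.uniform(*mz_range)
                rt = rng.uniform(*rt_range)
                if all(abs(mz - m) > min_separation[0] or abs(rt - t) > min_separation[1]
                       for m, t in placed):
                    break
            else:  # pragma: no cover - pathological geometry
                raise SyntheticSpecError("could not place a false peak away from existing peaks")
            placed.append((mz, rt))
            records.append(
                PeakRecord(eic_id=1000 + f, mz_apex=mz, rt_apex=rt,
                           scan_apex=int(round(rt / 1.2)), source=names[tool_idx])
            )
        lists.append(records)
    return lists


def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """The default synthetic benchmark: 20 analyte peaks plus noise features.

    Conditions: a 600-scan run at 1.2 s/scan, analytes 500–5000 counts high
    and 2.5–7 s wide (8–24 scans at the base, inside the 5–50-scan window),
    roughly half with a moderate exponential tail; baseline 20 counts with a
    slow drift; 8 % zigzag noise; 1.5 spikes per 100 scans; 10 ppm m/z
    jitter under a 40 ppm extraction tolerance; plus six broad low decoy
    humps (6-14 counts over the 20-count base, 25 % zigzag) and diffuse
    background points that act as false-positive sources for the filtering
    stages.
    """
    rng = np.random.default_rng(seed)
    truth = []
    rt_slots = np.linspace(60.0, 660.0, 20) + rng.uniform(-8.0, 8.0, 20)
    for i in range(20):
        sigma = float(rng.uniform(2.5, 7.0))
        truth.append(
            TruthPeak(
                mz=100.0 + 17.0 * i + float(rng.uniform(-2.0, 2.0)),
                rt_apex=float(rt_slots[i]),
                height=float(rng.uniform(500.0, 5000.0)),
                sigma=sigma,
                tail_tau=float(rng.uniform(0.3, 0.9) * sigma) if i % 2 else 0.0,
            )
        )
    # decoys mirror the classic "bad peak" regime: a low hump on an elevated
    # base (apex-to-base ratio ~1.3-1.7, hence low sharpness and significance)
    # with noticeably rougher point-to-point noise than the analytes
    decoys = [
        TruthPeak(
            mz=450.0 + 23.0 * j + float(rng.uniform(-2.0, 2.0)),
            rt_apex=float(rng.uniform(80.0, 640.0)),
            height=float(rng.uniform(6.0, 14.0)),
            sigma=float(rng.uniform(5.0, 10.0)),
        )
        for j in range(6)
    ]
    return SyntheticSpec(
        truth_peaks=truth,
        n_scans=600,
        scan_rate=1.2,
        baseline_level=20.0,
        baseline_drift=0.01,
        zigzag_amplitude=0.08,
        spike_rate=1.5,
        spike_width=3,
        ppm_jitter=10.0,
        noise_floor=5.0,
        background_density=1.0,
        decoy_peaks=decoys,
        decoy_zigzag=0.15,
        mixed_channels=2,
        seed=seed,
    )


def truth_table(truth: list[TruthPeak]) -> "np.ndarray":
    """Truth peaks as a structured table (columns mz, rt_apex_s, height, sigma_s, tail_tau_s)."""
    import pandas as pd

    return pd.DataFrame(
        [(p.mz, p.rt_apex, p.height, p.sigma, p.tail_tau) for p in truth],
        columns=["mz", "rt_apex_s", "height", "sigma_s", "tail_tau_s"],
    )
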