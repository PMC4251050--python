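# Methods

## Scope and data model

`eicqc` operates on centroided MS1 LC/MS runs. Internally a run is a list
of per-scan (m/z, intensity) arrays plus a strictly increasing retention
time axis; the canonical time unit everywhere is the **second** (files
declaring minutes are converted on read), and scan indices are 0-based and
contiguous. Peak lists exchanged with other tools are plain CSV with a
fixed header; third-party exports are adapted via a user-supplied column
map rather than per-tool parsers. mzML reading and writing is implemented
directly on lxml (streaming, base64 32/64-bit floats, optional zlib,
centroid MS1 only); profile-mode spectra are rejected rather than silently
treated as centroids.

## EIC extraction (mass traces)

Extraction is region-of-interest tracking: a centroid point extends an
open trace when its m/z lies within `ppm_tolerance` (default 40 ppm) of
the trace's running intensity-weighted mean m/z. The weighted mean was
chosen over a plain mean so low-intensity stragglers cannot drag the
center. When one scan offers several candidates for a trace the closest
in m/z wins and losers may seed new traces. Traces silent for more than
`max_gap = 2` scans are closed — small enough that separate elution events
do not merge, large enough that one or two missing centroids do not split
a trace — and traces with fewer than `min_trace_points = 5` points are
discarded (peaks narrower than 5 scans are below the detector's width
window anyway, and this suppresses pure spikes before scoring). Gap scans
inside a trace are stored as zero intensity so the quality indices always
see a dense contiguous series.

## EIC quality indices

* **MCQ (CODA) index** — inner product of the unit-norm window-5 smoothed
  trace with the unit-norm mean-subtracted original, clamped to [0, 1].
  It factors into a spike index (cosine of the trace with its smoothed
  self) and a background index (cosine with its centered self; in closed
  form `sd/√(sd² + mean²)`). The smoother is a centered moving average
  with edge truncation. Note an intrinsic property: a peak of width σ in
  an N-point window cannot exceed a background index of
  `√(1 − 2√π·σ/N)`, so short traces carrying one genuine peak score low —
  the documented failure mode that motivates the zigzag index.
* **Global zigzag index** — second-difference energy over `N · EPI²`.
  The baseline under the apex is estimated as the **series minimum**, so
  `EPI = max(I) − min(I)`. With this estimator every second difference is
  bounded by `2·EPI`, which proves the index lives in [0, 4) (the bound is
  approached by long alternating zero/apex series), and adding a constant
  offset moves the baseline with it, leaving the index exactly unchanged.
  A windowed-minimum baseline was considered and rejected: it breaks both
  the range bound on adversarial series and shift invariance.
* Degenerate traces (all-zero, constant) raise a typed `QualityError`
  rather than returning sentinels; the filters treat such traces as
  rejected.

The EIC filter keeps a trace when its MCQ exceeds `mcq_min` (default 0.6)
or — in the default `zigzag` mode — when its global zigzag is below
`eic_zigzag_max` (default 0.9).

A note on noise models: independent-sign multiplicative jitter of relative
amplitude *a* produces second-difference variance `6·var(ε)` against
`EPI ≈ `full range, which caps the index near 0.5 regardless of *a*. Only
alternation-dominated traces (sign flipping scan to scan) push the index
past ~1 and toward 4. The index is therefore a detector of *alternating*
roughness, exactly the phenomenon it was designed for.

## Peak detection

A Ricker (Mexican hat) CWT is computed over scales 1..16 (covering 5–50
scan peak widths) with reflective padding. For a Gaussian peak of width σ
the coefficient maximum under the standard amplitude normalization sits at
scale `√5·σ` — the brute-force matrix argmax confirms this — so the scale
grid comfortably covers the width window. Local maxima per scale row are
linked into ridge lines from the largest scale downward, within a position
tolerance equal to the current scale, allowing up to 2 missed rows;
ridges shorter than 3 rows are dropped. Coarse-scale smoothed noise always
produces *some* linkable ridges, so ridge count alone is not a noise
filter; the vetoes below are.

Each surviving ridge yields one candidate: the apex starts at the
strongest ridge point, snaps to the nearest local maximum of the window-5
smoothed trace, boundaries are placed at the **argmin of the smoothed
trace within ±2·best-scale** of the apex (scanning the full window rather
than stopping at the first uptick keeps noisy flanks from truncating a
peak mid-slope; zero-intensity samples end the scan, a gap being a natural
boundary), then trimmed inward to the 1 %-above-base level so long shallow
tails do not inflate the width. The final apex is the raw maximum inside
the boundaries (ties to the earlier scan), so the apex sample is always
the slice maximum. Candidates are rejected when:

* width is outside 5–50 scans;
* the contiguous raw run through the apex above half height is shorter
  than 4 scans — this is what eliminates 1–3-scan centroiding spikes,
  whose padded boundaries otherwise satisfy the width window;
* the largest scan-to-scan ratio across the apex core (half-height run
  ±1 point, measured on the baseline-subtracted slice plus 2 % of its
  range) exceeds 6 — chromatographic peaks ≥ 5 scans wide rise a few-fold
  per scan at most, while spike composites (two adjacent spikes posing as
  one 5-scan peak) jump an order of magnitude at the core edge;
* wavelet SNR is below `snr_floor` (default 0: SNR filtering is normally
  the quality filter's job).

Overlapping neighbours are split at the inter-apex valley of the smoothed
trace; an unsplittable pair keeps the stronger coefficient. Boundary
intervals of reported peaks never overlap.

## Peak quality metrics

For a slice `I_1..I_N` with apex index p (1-based in the formulas):

* **sharpness** = `Σ_{i=2}^{p} (I_i−I_{i−1})/I_{i−1} + Σ_{i=p}^{N−1}
  (I_i−I_{i+1})/I_{i+1}`, computed boundary-to-apex within the slice. If
  any slice point is zero (boundary zeros are routine after valley
  placement) the slice is offset by 1 intensity unit first; the offset is
  configurable.
* **Gaussian similarity** — least-squares Gaussian fit (height, center,
  width; baseline fixed at the slice minimum, initialization from apex and
  FWHM), then the cosine between the baseline-subtracted slice and the
  fitted curve, clamped to [0, 1]. Subtracting the minimum first matters:
  a high flat baseline otherwise makes any shape look Gaussian. The cosine
  is deliberately tolerant; moderately tailed peaks still score ≥ 0.9 and
  are ranked, not excluded, by this metric.
* **SNR** — |CWT coefficient| at the apex at the ridge's best scale over
  the 95th percentile of |scale-1 coefficients| within ±50 scans of the
  apex (window bounds the noise estimate to the peak's neighbourhood),
  floored at 1e−12.
* **peak significance** — mean intensity over apex ±1 point divided by the
  mean of the first and last 2 slice points (window sizes configurable). A
  zero boundary mean returns +∞, which the filter treats as passing.
* **TPASR** = `|TPA − RPA| / TPA`, `TPA = ½·(N−1)·I_apex`,
  `RPA = Σ I_i`; the width is the scan-unit difference between the
  boundaries.
* **local zigzag** — the global zigzag index applied to the slice.

The combined filter keeps a peak iff every enabled clause passes
(sharpness ≥ 2.0, Gaussian ≥ 0.6, SNR ≥ 1.3, significance ≥ 1.2,
TPASR ≤ 0.8, zigzag ≤ 0.9 by default); any clause can be disabled for
single-metric sweeps, and a metric that errored fails its clause.

## Consensus benchmarking

Two reported peaks are the same feature when their apexes agree within
0.05 Da and 5 s. Matching is one-to-one greedy in order of increasing
combined normalized distance (`|Δmz|/mz_tol + |Δrt|/rt_tol`) — chosen over
optimal assignment for determinism and speed; brute-force enumeration on
small instances is the test oracle and ties it to within one pair. The
consensus truth over three tools' lists is the set of match-graph
components containing ≥ 2 distinct tools, each represented by its medoid;
its size NP equals the inclusion–exclusion identity
`N(1∩2)+N(1∩3)+N(2∩3)−2·N(1∩2∩3)`, and both computations are exposed and
cross-checked. Scores: Recall = TP/NP, **Precision = TP/n_detected**,
F = 2RP/(R+P); empty-list and NP = 0 cases score 0 by convention.

Threshold sweeps filter a fixed detected set by one metric at a time.
Loosening a cutoff nests the keep-sets, which makes Recall exactly
monotone; Precision is monotone only when the swept metric separates true
from false peaks perfectly, which holds on the default seeded benchmark
but is a tendency, not a theorem — a spike landing inside a genuine peak's
slice legitimately raises that peak's zigzag into the decoy range. The
sweep-shape tests therefore run on the default benchmark at its default
seed and evaluate precision monotonicity over non-empty keep-sets (the
empty set's precision is 0 by the convention above).

## Synthetic data: what it emulates, and what it does not

`SyntheticSpec` defines the study conditions; `benchmark_spec()` is the
default benchmark: a 600-scan run at 1.2 s/scan with

* **20 analyte peaks**, heights 500–5000 counts over a 20-count baseline,
  Gaussian widths 2.5–7 s (8–24 scans at the base), roughly half with an
  exponential tail of 0.3–0.9 σ (shapes are re-centred so the planted
  apex RT is exact);
* baseline drift 0.01 counts/scan, 8 % multiplicative zigzag noise
  (independent sign and magnitude per scan, floored at a 5-count noise
  level), 1.5 spikes per 100 scans at 5–20× the local *background* level
  (spikes are centroiding artifacts: they must be confusable with small
  peaks, not dwarf the analytes), 10 ppm m/z jitter under the 40 ppm
  extraction tolerance, and one diffuse background point per scan;
* **6 decoy humps** — 6–14 counts over the base (apex-to-base ratio
  1.3–1.7) with 15 % noise: geometrically detectable peaks whose
  sharpness and significance stay low, the classic "bad peak";
* **2 mixed channels** — a fair 150–220-count hump bridged by quiet
  baseline to a 200-scan full-swing alternating burst: peak-level metrics
  accept the hump, but the trace's global zigzag index exceeds 0.9, so
  only the EIC-level filter removes it. This is the bad-EIC-with-one-
  good-stretch case that motivates EIC-level filtering in the first place.

All randomness flows from one integer seed through a single
`numpy.random.Generator`. With zero zigzag amplitude and zero spike rate
the generated series equals its noiseless expectation exactly.

Not emulated: isotope patterns, adducts, chemical-formula-driven signals,
detector saturation, profile mode, or chemically correlated co-elution.
Passing tests on this benchmark demonstrate the pipeline's behaviour under
the stated noise channels, not performance on any particular instrument's
data.

## Numerical and design choices

* Smoothing window 5 scans throughout (a common EIC smoothing choice);
  configurable.
* Matching, sorting, and CSV output are fully deterministic; reruns on the
  same input are byte-identical.
* The Gaussian fit failing (singular/NaN) raises a typed error recorded as
  a missing metric, which fails that filter clause.
* Precision's denominator is the evaluated detector's own peak count; the
  recall and precision formulas otherwise printed identically in some
  sources are reconciled this way, consistent with the published
  three-tool score table.
* Problem sizes in the test suite (600-scan benchmark, 10⁴ random series,
  10³ consensus fixtures, 50-seed noise studies) were chosen so the whole
  suite runs in well under a minute while every stochastic claim is
  averaged over enough seeds to be stable.

## Known limitations

* The ROI tracker is greedy per scan; pathological centroid splits (two
  points inside one envelope every scan) seed parallel traces instead of
  merging them.
* The zigzag index saturates near 0.5 for independent-sign noise; it is a
  detector of alternating roughness, not of all noise types (SNR and
  significance cover the rest).
* Gaussian similarity's cosine is forgiving of mild asymmetry by design;
  it ranks rather than excludes tailed peaks.
* Greedy matching can, in principle, fall one pair short of the optimal
  assignment in dense clusters; tolerance-scale separation in the
  benchmark keeps this from occurring there.
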