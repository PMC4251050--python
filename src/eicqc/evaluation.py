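"""Consensus ground truth, tolerance matching, and Recall/Precision/F-Score.

Peaks from different detectors are considered the same feature when their
apex m/z and RT fall within the match tolerances (defaults 0.05 Da, 5 s).
A consensus ground-truth list is built by voting: any feature reported by
at least two of three independent tools is a true peak.  The resulting
count NP equals the inclusion–exclusion identity

    NP = N(1&2) + N(1&3) + N(2&3) - 2 * N(1&2&3),

and both computations are exposed so they can be cross-checked.

Scores for an evaluated detector X:
Recall = TP/NP, Precision = TP/|X|, F = 2RP/(R+P).  (Precision uses the
detector's own peak count as denominator; the harmonic-mean F-Score is
reported alongside.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lcms_io import PeakRecord


@dataclass
class MatchSpec:
    """Tolerances for deciding that two reported peaks are the same feature."""

    mz_tol: float = 0.05  # Daltons
    rt_tol: float = 5.0  # seconds

    def __post_init__(self) -> None:
        if self.mz_tol <= 0 or self.rt_tol <= 0:
            raise ValueError("match tolerances must be > 0")


def match_peaks(a: list[PeakRecord], b: list[PeakRecord],
                spec: MatchSpec = MatchSpec()) -> list[tuple[int, int]]:
    """One-to-one greedy matching between two peak lists.

    Candidate pairs within both tolerances are accepted in order of
    increasing combined normalized distance |dmz|/mz_tol + |drt|/rt_tol;
    each peak participates in at most one accepted pair.  Deterministic:
    ties break on the (i, j) index pair.
    """
    cands = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            dmz = abs(pa.mz_apex - pb.mz_apex)
            drt = abs(pa.rt_apex - pb.rt_apex)
            if dmz <= spec.mz_tol and drt <= spec.rt_tol:
                cands.append((dmz / spec.mz_tol + drt / spec.rt_tol, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _match_groups(lists: list[list[PeakRecord]], spec: MatchSpec) -> list[list[tuple[int, int]]]:
    """Connected components of the pairwise match graph across all lists.

    Nodes are (list index, peak index); edges come from one-to-one matching
    between every list pair.  Returns each component as a sorted node list.
    """
    offsets = np.cumsum([0] + [len(l) for l in lists])
    uf = _UnionFind(int(offsets[-1]))
    for li in range(len(lists)):
        for lj in range(li + 1, len(lists)):
            for i, j in match_peaks(lists[li], lists[lj], spec):
                uf.union(int(offsets[li]) + i, int(offsets[lj]) + j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for li in range(len(lists)):
        for i in range(len(lists[li])):
            root = uf.find(int(offsets[li]) + i)
            groups.setdefault(root, []).append((li, i))
    return [sorted(g) for g in sorted(groups.values())]


def _medoid(members: list[tuple[int, int]], lists: list[list[PeakRecord]],
            spec: MatchSpec) -> PeakRecord:
    """Member with minimal summed tolerance-normalized distance to the others."""
    recs = [lists[li][i] for li, i in members]
    best_idx, best_cost = 0, float("inf")
    for k, rk in enumerate(recs):
        cost = sum(
            abs(rk.mz_apex - r.mz_apex) / spec.mz_tol + abs(rk.rt_apex - r.rt_apex) / spec.rt_tol
            for r in recs
        )
        if cost < best_cost - 1e-12:
            best_idx, best_cost = k, cost
    return recs[best_idx]


def ground_truth_peaks(l1: list[PeakRecord], l2: list[PeakRecord], l3: list[PeakRecord],
                       spec: MatchSpec = MatchSpec()) -> tuple[list[PeakRecord], int]:
    """Consensus truth: features reported by >= 2 of the 3 tools.

    Matched groups are deduplicated (a triple-detected feature counts
    once) and each is represented by its medoid member.  Returns the truth
    list and NP = its length.
    """
    lists = [l1, l2, l3]
    truth = []
    for members in _match_groups(lists, spec):
        if len({li for li, _ in members}) >= 2:
            truth.append(_medoid(members, lists, spec))
    return truth, len(truth)


def np_inclusion_exclusion(l1: list[PeakRecord], l2: list[PeakRecord], l3: list[PeakRecord],
                           spec: MatchSpec = MatchSpec()) -> int:
    """NP via inclusion–exclusion over pairwise and triple overlap counts."""
    n12 = len(match_peaks(l1, l2, spec))
    n13 = len(match_peaks(l1, l3, spec))
    n23 = len(match_peaks(l2, l3, spec))
    n123 = sum(
        1
        for members in _match_groups([l1, l2, l3], spec)
        if len({li for li, _ in members}) == 3
    )
    return n12 + n13 + n23 - 2 * n123


def fscore(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both are 0."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


@dataclass
class PRFResult:
    """Benchmark scores of one detector against the consensus truth."""

    NP: int
    TP: int
    n_detected: int
    recall: float
    precision: float
    fscore: float


def prf(detected: list[PeakRecord], truth: list[PeakRecord], NP: int | None = None,
        spec: MatchSpec = MatchSpec()) -> PRFResult:
    """Recall/Precision/F-Score of a detected list against the truth list."""
    if NP is None:
        NP = len(truth)
    tp = len(match_peaks(detected, truth, spec))
    recall = tp / NP if NP > 0 else 0.0
    precision = tp / len(detected) if detected else 0.0
    return PRFResult(NP=NP, TP=tp, n_detected=len(detected),
                     recall=recall, precision=precision,
                     fscore=fscore(recall, precision))


# threshold sweeps -------------------------------------------------------

_HIGHER_BETTER = {"sharpness", "gaussian_similarity", "snr", "peak_significance", "mcq"}
_LOWER_BETTER = {"tpasr", "zigzag", "eic_zigzag"}
SWEEPABLE_METRICS = tuple(sorted(_HIGHER_BETTER | _LOWER_BETTER))


@dataclass
class SweepResult:
    """PRF as a function of one metric's cutoff threshold."""

    metric: str
    grid: list[float]
    results: list[PRFResult] = field(default_factory=list)


def _peak_metric_value(report, metric: str) -> float | None:
    return getattr(report, metric)


def sweep_threshold(
    records: list[PeakRecord],
    peak_reports,
    metric: str,
    grid,
    truth: list[PeakRecord],
    NP: int | None = None,
    spec: MatchSpec = MatchSpec(),
    eic_reports=None,
) -> SweepResult:
    """Single-metric threshold sweep of the final detection PRF.

    ``records`` and ``peak_reports`` are the unfiltered detected peaks and
    their quality reports (parallel lists).  For the two EIC-level metrics
    (``mcq``, ``eic_zigzag``) a peak is kept when its parent EIC passes,
    which requires ``eic_reports``.  Peaks whose swept metric is missing
    are always rejected.
    """
    if metric not in _HIGHER_BETTER and metric not in _LOWER_BETTER:
        raise ValueError(f"unknown sweep metric {metric!r}; choose from {SWEEPABLE_METRICS}")
    grid = sorted(float(g) for g in grid)
    if metric in ("mcq", "eic_zigzag"):
        if eic_reports is None:
            raise ValueError("EIC-level sweeps need eic_reports")
        by_eic = {r.eic_id: r for r in eic_reports}
        attr = "mcq_index" if metric == "mcq" else "zigzag_index"
        values = [
            getattr(by_eic[rec.eic_id], attr) if rec.eic_id in by_eic else None
            for rec in records
        ]
    else:
        values = [_peak_metric_value(rep, metric) for rep in peak_reports]

    out = SweepResult(metric=metric, grid=list(grid))
    for th in grid:
        if metric in _HIGHER_BETTER:
            kept = [rec for rec, v in zip(records, values) if v is not None and v >= th]
        else:
            kept = [rec for rec, v in zip(records, values) if v is not None and v <= th]
        out.results.append(prf(kept, truth, NP, spec))
    return out
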