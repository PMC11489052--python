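"""Staged Dynamic-Time-Warping comparison of endpoint trajectories, Pearson
correlation of DTW profiles between conditions, and piecewise-linear
change-point detection.

A trajectory is split into contiguous stages (default equal thirds labelled
early/mid/late, remainder to the last stage; optionally boundaries from
detected change points). For each endpoint node and stage, the DTW score
between a condition's sub-series and a reference condition's matching
sub-series quantifies dissimilarity: a lower DTW score means higher
similarity. Pearson correlation of two conditions' per-endpoint DTW score
vectors flags highly concordant subgroup pairs (r >= 0.98 by default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulator import TrajectoryEnsemble

__all__ = [
    "DTWStageTable",
    "ChangePointFit",
    "dtw",
    "dtw_path",
    "split_stages",
    "stage_slices",
    "stage_dtw_table",
    "correlate_dtw_profiles",
    "detect_change_points",
]

STAGE_LABELS_3 = ("early", "mid", "late")
HIGH_SIMILARITY_THRESHOLD = 0.98


# ---------------------------------------------------------------------------
# Dynamic Time Warping
# ---------------------------------------------------------------------------

def dtw(a: Sequence[float], b: Sequence[float],
        cost: Callable[[float, float], float] | None = None,
        window: int | None = None) -> float:
    """Classic DP dynamic time warping score.

    Boundary-aligned (first<->first, last<->last), step pattern
    {match, insert, delete}, local cost |a_i - b_j| unless ``cost`` is given.
    ``window`` adds a Sakoe-Chiba band (|i - j| <= window) for long series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty series")
    n, m = a.size, b.size
    if window is not None and window < abs(n - m):
        raise ValueError("Sakoe-Chiba window too narrow for length difference")

    if cost is None and window is None:
        # vectorised row sweep on the full |a_i - b_j| cost matrix
        local = np.abs(a[:, None] - b[None, :])
        prev = np.empty(m)
        prev[0] = local[0, 0]
        for j in range(1, m):
            prev[j] = prev[j - 1] + local[0, j]
        cur = np.empty(m)
        for i in range(1, n):
            cur[0] = prev[0] + local[i, 0]
            row = local[i]
            for j in range(1, m):
                cur[j] = row[j] + min(prev[j], prev[j - 1], cur[j - 1])
            prev, cur = cur, prev
        return float(prev[m - 1])

    fn = cost if cost is not None else (lambda u, v: abs(u - v))
    inf = math.inf
    D = np.full((n + 1, m + 1), inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        lo = 1 if window is None else max(1, i - window)
        hi = m if window is None else min(m, i + window)
        for j in range(lo, hi + 1):
            c = fn(a[i - 1], b[j - 1])
            D[i, j] = c + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    return float(D[n, m])


def dtw_path(a: Sequence[float], b: Sequence[float]) -> list[tuple[int, int]]:
    """The optimal warping path (index pairs) for the default absolute cost."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), math.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = abs(a[i - 1] - b[j - 1]) + min(
                D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min(moves, key=lambda ij: D[ij])
        path.append((i - 1, j - 1))
    return path[::-1]


# ---------------------------------------------------------------------------
# Stage splitting
# ---------------------------------------------------------------------------

def stage_slices(n_points: int, n_stages: int = 3,
                 boundaries: Sequence[int] | None = None,
                 ) -> list[tuple[str, slice]]:
    """Contiguous stage windows over a series of ``n_points`` samples.

    Equal lengths with the remainder absorbed by the last stage; or, when
    ``boundaries`` (strictly increasing interior indices) are supplied, the
    windows [0, b1), [b1, b2), ..., [bk, n).
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if boundaries is not None:
        bounds = list(boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])) or \
                any(not (0 < b < n_points) for b in bounds):
            raise ValueError("boundaries must be strictly increasing and "
                             "interior to the series")
        edges = [0] + bounds + [n_points]
    else:
        if n_points < n_stages:
            raise ValueError("series shorter than the number of stages")
        base = n_points // n_stages
        edges = [i * base for i in range(n_stages)] + [n_points]
    labels = (list(STAGE_LABELS_3) if len(edges) - 1 == 3
              else [f"stage_{i + 1}" for i in range(len(edges) - 1)])
    return [(lab, slice(lo, hi))
            for lab, lo, hi in zip(labels, edges, edges[1:])]


def split_stages(traj: TrajectoryEnsemble, n_stages: int = 3,
                 boundaries: Sequence[int] | None = None,
                 ) -> dict[str, dict[str, np.ndarray]]:
    """Per-stage sub-series per node: {stage: {node: values}}."""
    windows = stage_slices(traj.prob.shape[0], n_stages, boundaries)
    return {label: {node: traj.prob[sl, i]
                    for i, node in enumerate(traj.nodes)}
            for label, sl in windows}


# ---------------------------------------------------------------------------
# Staged DTW tables
# ---------------------------------------------------------------------------

@dataclass
class DTWStageTable:
    """Long table of DTW scores: (endpoint, condition, stage, dtw)."""

    table: pd.DataFrame  # columns endpoint, condition, stage, dtw
    reference: str

    def scores(self, condition: str, stage: str) -> pd.Series:
        sub = self.table[(self.table["condition"] == condition)
                         & (self.table["stage"] == stage)]
        return sub.set_index("endpoint")["dtw"]

    def to_wide(self) -> pd.DataFrame:
        """Tables-7-to-11-like layout: stage/endpoint rows, condition columns."""
        return self.table.pivot_table(index=["stage", "endpoint"],
                                      columns="condition", values="dtw")


def stage_dtw_table(conditions: Mapping[str, TrajectoryEnsemble],
                    reference: str = "pairwise",
                    endpoints: Sequence[str] | None = None,
                    n_stages: int = 3,
                    boundaries: Sequence[int] | None = None,
                    ) -> DTWStageTable:
    """Staged DTW scores of endpoint trajectories across conditions.

    In reference mode every condition (including the reference itself, which
    scores zero) is compared stage-by-stage against the named reference
    condition; in ``"pairwise"`` mode all unordered condition pairs are
    compared and labelled ``"A|B"``.
    """
    names = sorted(conditions)
    if not names:
        raise ValueError("no conditions supplied")
    first = conditions[names[0]]
    for name in names[1:]:
        e = conditions[name]
        if e.prob.shape[0] != first.prob.shape[0] or e.nodes != first.nodes:
            raise ValueError(
                f"condition {name!r} does not share the reference step count "
                f"and node set")
    if endpoints is None:
        endpoints = first.nodes
    for ep in endpoints:
        if ep not in first.nodes:
            raise KeyError(f"endpoint {ep!r} absent from the trajectories")

    staged = {name: split_stages(conditions[name], n_stages, boundaries)
              for name in names}
    stage_names = list(staged[names[0]].keys())

    records = []
    if reference == "pairwise":
        for c1, c2 in itertools.combinations(names, 2):
            for stage in stage_names:
                for ep in endpoints:
                    score = dtw(staged[c1][stage][ep], staged[c2][stage][ep])
                    records.append({"endpoint": ep,
                                    "condition": f"{c1}|{c2}",
                                    "stage": stage, "dtw": score})
    else:
        if reference not in conditions:
            raise KeyError(f"reference condition {reference!r} not supplied")
        for name in names:
            for stage in stage_names:
                for ep in endpoints:
                    score = dtw(staged[name][stage][ep],
                                staged[reference][stage][ep])
                    records.append({"endpoint": ep, "condition": name,
                                    "stage": stage, "dtw": score})
    return DTWStageTable(table=pd.DataFrame.from_records(records),
                         reference=reference)


def correlate_dtw_profiles(table: DTWStageTable,
                           pair: tuple[str, str], stage: str,
                           threshold: float = HIGH_SIMILARITY_THRESHOLD,
                           ) -> dict:
    """Pearson r between two conditions' per-endpoint DTW score vectors at a
    stage, with a high-similarity flag at ``r >= threshold``.

    Zero variance in either vector leaves r undefined (NaN, flagged)."""
    s1 = table.scores(pair[0], stage)
    s2 = table.scores(pair[1], stage)
    shared = s1.index.intersection(s2.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared endpoints")
    x = s1.loc[shared].to_numpy()
    y = s2.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"pair": pair, "stage": stage, "r": float("nan"),
                "undefined": True, "high_similarity": False,
                "n_endpoints": len(shared)}
    r = float(sps.pearsonr(x, y).statistic)
    return {"pair": pair, "stage": stage, "r": r, "undefined": False,
            "high_similarity": bool(r >= threshold),
            "n_endpoints": len(shared)}


# ---------------------------------------------------------------------------
# Change-point detection
# ---------------------------------------------------------------------------

@dataclass
class ChangePointFit:
    """Piecewise-linear fit: interior breakpoints, per-segment (intercept,
    slope), and the BIC used for model selection."""

    breakpoints: list[int]
    segments: list[tuple[float, float]]
    rss: float
    bic: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _segment_cost_fn(y: np.ndarray):
    """O(1) SSE of a least-squares line on y[i:j] via prefix sums."""
    n = y.size
    x = np.arange(n, dtype=float)
    c1 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])

    def sse(i: int, j: int) -> tuple[float, float, float]:
        """(SSE, intercept, slope) of the fit on indices [i, j)."""
        m = c1[j] - c1[i]
        sx = cx[j] - cx[i]
        sxx = cxx[j] - cxx[i]
        sy = cy[j] - cy[i]
        syy = cyy[j] - cyy[i]
        sxy = cxy[j] - cxy[i]
        det = m * sxx - sx * sx
        if det <= 0:
            mean = sy / m
            return float(syy - m * mean * mean), float(mean), 0.0
        slope = (m * sxy - sx * sy) / det
        intercept = (sy - slope * sx) / m
        resid = (syy - 2 * intercept * sy - 2 * slope * sxy
                 + m * intercept ** 2 + 2 * intercept * slope * sx
                 + slope ** 2 * sxx)
        return float(max(resid, 0.0)), float(intercept), float(slope)

    return sse


def detect_change_points(series: Sequence[float], max_breaks: int,
                         min_segment: int = 3) -> ChangePointFit:
    """Multiple-change-point piecewise-linear regression.

    Dynamic-programming search over all breakpoint placements (segments of at
    least ``min_segment`` points), with the number of segments selected by
    BIC: n*log(RSS/n) + k*log(n) over k fitted parameters (two per segment
    plus one per breakpoint). The optimal RSS is non-increasing in the number
    of allowed breaks.
    """
    if max_breaks < 0:
        raise ValueError("max_breaks must be >= 0")
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 2 * (max_breaks + 1):
        raise ValueError("series too short for the requested breaks")
    min_segment = max(2, min_segment)
    sse = _segment_cost_fn(y)

    max_segs = min(max_breaks + 1, n // min_segment)
    # dp[k][j]: best RSS for fitting y[0:j] with k segments
    inf = math.inf
    dp = [[inf] * (n + 1) for _ in range(max_segs + 1)]
    back = [[-1] * (n + 1) for _ in range(max_segs + 1)]
    dp[0][0] = 0.0
    for k in range(1, max_segs + 1):
        for j in range(k * min_segment, n + 1):
            best, arg = inf, -1
            for i in range((k - 1) * min_segment, j - min_segment + 1):
                if dp[k - 1][i] == inf:
                    continue
                cand = dp[k - 1][i] + sse(i, j)[0]
                if cand < best:
                    best, arg = cand, i
            dp[k][j] = best
            back[k][j] = arg

    best_fit: ChangePointFit | None = None
    eps = 1e-12
    for k in range(1, max_segs + 1):
        rss = dp[k][n]
        if rss == inf:
            continue
        n_params = 2 * k + (k - 1)
        bic = n * math.log(max(rss, eps) / n) + n_params * math.log(n)
        if best_fit is None or bic < best_fit.bic - 1e-9:
            cuts = []
            j = n
            for kk in range(k, 0, -1):
                i = back[kk][j]
                if kk > 1:
                    cuts.append(i)
                j = i
            cuts = cuts[::-1]
            edges = [0] + cuts + [n]
            segments = [(sse(a, b)[1], sse(a, b)[2])
                        for a, b in zip(edges, edges[1:])]
            best_fit = ChangePointFit(breakpoints=cuts, segments=segments,
                                      rss=rss, bic=bic)
    assert best_fit is not None
    return best_fit
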