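"""Plateau extraction and conductance-state statistics.

A TV reconstruction is piecewise constant up to solver tolerance, but on
noisy traces it is a staircase: each true conductance plateau appears as a
run of small steps around the true level, fragmenting into several nearly
constant segments.  Plateaus are therefore recovered in stages:

1. segment the reconstruction into maximal constant runs (tolerance far
   above solver precision, far below any physical step);
2. cluster adjacent segments agglomeratively while all member levels stay
   within the identical-state bound log(2) ~ 0.3 (two conductance levels
   closer than a factor of two are the same state);
3. discard clusters outside the molecular conductance window or shorter
   than a minimum length — no conductance window is needed to *define*
   plateaus, only to exclude metal-contact and open-gap segments;
4. assign each remaining plateau to the nearest known conductance state
   (validation uses the high/low states at log10(G/G0) = -2.5 and -3.0)
   when within a maximum distance;
5. consolidate: adjacent plateaus assigned to the same state are one state
   visit, and the short staircase shoulders between a plateau and its
   neighbours are attributed to the nearer plateau, so a plateau's extent
   runs up to the step that actually leaves the state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .denoise import TVDConfig, tvd_admm
from .simulate import DISTANCE_STEP_NM, LabeledTrace

__all__ = [
    "Plateau",
    "DetectionSummary",
    "StateStats",
    "segment_piecewise_constant",
    "cluster_segments",
    "filter_plateaus",
    "assign_states",
    "consolidate_states",
    "detect_plateaus",
    "detection_summary",
    "DEFAULT_LEVEL_TOL",
    "DEFAULT_SPAN_TOL",
    "DEFAULT_MIN_POINTS",
    "DEFAULT_REGION",
    "DEFAULT_STATE_LEVELS",
    "DEFAULT_MAX_DIST",
]

# segmentation tolerance: far above ADMM tolerance, far below the smallest
# meaningful conductance step (log(2) ~ 0.3)
DEFAULT_LEVEL_TOL = 1e-3
DEFAULT_SPAN_TOL = 0.3           # log(2): levels closer than this are one state
DEFAULT_MIN_POINTS = 10          # 0.1 nm; suppresses edge micro-segments
DEFAULT_REGION = (-5.0, -0.3)    # molecular window, excludes metal & baseline
DEFAULT_STATE_LEVELS = (-2.5, -3.0)
DEFAULT_MAX_DIST = 0.25          # < log(2) identical-state bound

STATE_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Plateau:
    """A constant-conductance segment: [start_index, end_index) of a trace."""

    start_index: int
    end_index: int
    level: float
    assigned_state: str | None = None

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")
        if not np.isfinite(self.level):
            raise ValueError("level must be finite")

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index

    @property
    def length_nm(self) -> float:
        return self.n_points * DISTANCE_STEP_NM


@dataclass(frozen=True)
class StateStats:
    """Summary of all plateaus assigned to one conductance state."""

    n_plateaus: int
    mean_level: float
    mean_length_nm: float
    levels: np.ndarray
    lengths_nm: np.ndarray


@dataclass(frozen=True)
class DetectionSummary:
    """Both-state detection rate and per-state plateau statistics."""

    n_traces: int
    n_both_detected: int
    per_state: dict[str, StateStats]

    @property
    def rate(self) -> float:
        return self.n_both_detected / self.n_traces


def segment_piecewise_constant(rec, level_tol: float = DEFAULT_LEVEL_TOL
                               ) -> list[Plateau]:
    """Partition a reconstructed series into maximal near-constant runs.

    Consecutive points belong to the same segment when they differ by less
    than ``level_tol``; every point lands in exactly one segment and segments
    are returned in trace order.
    """
    rec = np.asarray(rec, dtype=float)
    if rec.ndim != 1 or rec.size == 0:
        raise ValueError("rec must be a non-empty 1-D series")
    breaks = np.flatnonzero(np.abs(np.diff(rec)) >= level_tol) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [rec.size]))
    return [
        Plateau(int(s), int(e), float(np.mean(rec[s:e])))
        for s, e in zip(starts, ends)
    ]


def cluster_segments(segments: Sequence[Plateau],
                     span_tol: float = DEFAULT_SPAN_TOL) -> list[Plateau]:
    """Agglomeratively fuse adjacent segments into single-state plateaus.

    Two adjacent clusters merge (closest levels first) only while every
    constituent segment level in the union stays within ``span_tol`` — the
    identical-state bound.  Bounding the span, rather than just the gap,
    keeps a genuine high/low transition from being chained across by
    intermediate shoulder segments.  A fused cluster's level is the
    point-weighted mean.
    """
    if span_tol < 0:
        raise ValueError("span_tol must be >= 0")
    items: list[tuple[Plateau, float, float]] = [
        (s, s.level, s.level) for s in segments
    ]
    while len(items) > 1:
        best_gap = None
        best_i = None
        for i in range(len(items) - 1):
            (a, alo, ahi), (b, blo, bhi) = items[i], items[i + 1]
            if max(ahi, bhi) - min(alo, blo) < span_tol:
                gap = abs(b.level - a.level)
                if best_gap is None or gap < best_gap:
                    best_gap, best_i = gap, i
        if best_i is None:
            break
        (a, alo, ahi), (b, blo, bhi) = items[best_i], items[best_i + 1]
        if b.start_index != a.end_index:
            raise ValueError("segments must be contiguous to merge")
        level = (a.level * a.n_points + b.level * b.n_points) / (
            a.n_points + b.n_points)
        items[best_i:best_i + 2] = [
            (Plateau(a.start_index, b.end_index, level),
             min(alo, blo), max(ahi, bhi))
        ]
    return [it[0] for it in items]


def filter_plateaus(segments: Sequence[Plateau],
                    min_points: int = DEFAULT_MIN_POINTS,
                    region: tuple[float, float] = DEFAULT_REGION
                    ) -> list[Plateau]:
    """Keep segments long enough and inside the molecular conductance window."""
    lo, hi = region
    if lo >= hi:
        raise ValueError("region must satisfy lo < hi")
    return [p for p in segments
            if p.n_points >= min_points and lo <= p.level <= hi]


def assign_states(plateaus: Sequence[Plateau],
                  state_levels: Sequence[float] = DEFAULT_STATE_LEVELS,
                  max_dist: float = DEFAULT_MAX_DIST) -> list[Plateau]:
    """Assign each plateau to the nearest conductance state within max_dist.

    State names are ``high`` and ``low`` for two levels (ordered by
    conductance), ``state_k`` otherwise.  Ties go to the
    higher-conductance state.  Out-of-reach plateaus become ``unassigned``.
    """
    levels = sorted((float(s) for s in state_levels), reverse=True)
    if not levels:
        raise ValueError("state_levels must be non-empty")
    if len(levels) == 2:
        names = ["high", "low"]
    else:
        names = [f"state_{k + 1}" for k in range(len(levels))]
    out = []
    for p in plateaus:
        dists = [abs(p.level - s) for s in levels]
        best = int(np.argmin(dists))  # argmin takes the first == higher state on ties
        state = names[best] if dists[best] <= max_dist else STATE_UNASSIGNED
        out.append(replace(p, assigned_state=state))
    return out


def consolidate_states(assigned: Sequence[Plateau],
                       segments: Sequence[Plateau],
                       rec,
                       region: tuple[float, float] = DEFAULT_REGION
                       ) -> list[Plateau]:
    """Merge same-state visits and attach boundary shoulders.

    Consecutive state-assigned plateaus with the same state (ignoring
    unassigned material between them) are one state visit.  The raw
    staircase ``segments`` lying between consecutive visits — transition
    shoulders and short fragments dropped by the length filter — are then
    attributed to the nearer visit by level, provided they sit inside the
    molecular ``region``, so each visit's extent runs out to the step that
    leaves the molecular window.  Levels are recomputed as the pointwise
    mean of ``rec`` over the final extent.
    """
    rec = np.asarray(rec, dtype=float)
    lo, hi = region
    visits: list[Plateau] = []
    for p in assigned:
        if p.assigned_state in (None, STATE_UNASSIGNED):
            continue
        if visits and p.assigned_state == visits[-1].assigned_state:
            q = visits[-1]
            level = (q.level * q.n_points + p.level * p.n_points) / (
                q.n_points + p.n_points)
            visits[-1] = Plateau(q.start_index, p.end_index, level,
                                 assigned_state=p.assigned_state)
        else:
            visits.append(p)
    if not visits:
        return []
    n_total = max(f.end_index for f in segments) if segments else 0
    out = list(visits)
    for k, p in enumerate(out):
        start, end = p.start_index, p.end_index
        left_lim = out[k - 1].end_index if k > 0 else 0
        left = [f for f in segments
                if f.end_index <= start and f.start_index >= left_lim]
        for f in reversed(left):
            d_self = abs(f.level - p.level)
            d_other = (abs(f.level - out[k - 1].level)
                       if k > 0 else np.inf)
            if lo <= f.level <= hi and d_self <= d_other:
                start = f.start_index
            else:
                break
        right_lim = out[k + 1].start_index if k + 1 < len(out) else n_total
        right = [f for f in segments
                 if f.start_index >= end and f.end_index <= right_lim]
        for f in right:
            d_self = abs(f.level - p.level)
            d_other = (abs(f.level - out[k + 1].level)
                       if k + 1 < len(out) else np.inf)
            if lo <= f.level <= hi and d_self <= d_other:
                end = f.end_index
            else:
                break
        out[k] = Plateau(start, end, float(np.mean(rec[start:end])),
                         assigned_state=p.assigned_state)
    return out


def detect_plateaus(trace: LabeledTrace,
                    config: TVDConfig | None = None,
                    level_tol: float = DEFAULT_LEVEL_TOL,
                    span_tol: float = DEFAULT_SPAN_TOL,
                    min_points: int = DEFAULT_MIN_POINTS,
                    region: tuple[float, float] = DEFAULT_REGION,
                    state_levels: Sequence[float] = DEFAULT_STATE_LEVELS,
                    max_dist: float = DEFAULT_MAX_DIST) -> list[Plateau]:
    """Full per-trace pipeline: denoise, segment, cluster, filter, assign,
    consolidate.  Returns the final state-assigned plateaus in trace order.

    Uses ``trace.reconstructed`` when already present, otherwise runs the
    ADMM TV denoiser with ``config``.
    """
    rec = trace.reconstructed
    if rec is None:
        rec = tvd_admm(trace.log_g, config).reconstructed
    segments = segment_piecewise_constant(rec, level_tol)
    clusters = cluster_segments(segments, span_tol)
    kept = filter_plateaus(clusters, min_points, region)
    assigned = assign_states(kept, state_levels, max_dist)
    return consolidate_states(assigned, segments, rec, region)


def detection_summary(traces: Sequence[LabeledTrace],
                      config: TVDConfig | None = None,
                      **pipeline_kwargs) -> DetectionSummary:
    """Run the plateau pipeline over traces and summarize state detection.

    A trace counts as detected when at least one plateau is assigned to
    *each* state.  Per-state mean levels and mean lengths pool every
    assigned plateau across all traces.
    """
    if len(traces) == 0:
        raise ValueError("traces must be non-empty")
    state_levels = pipeline_kwargs.get("state_levels", DEFAULT_STATE_LEVELS)
    names = (["high", "low"] if len(state_levels) == 2
             else [f"state_{k + 1}" for k in range(len(state_levels))])
    levels: dict[str, list[float]] = {s: [] for s in names}
    lengths: dict[str, list[float]] = {s: [] for s in names}
    n_both = 0
    for trace in traces:
        plateaus = detect_plateaus(trace, config, **pipeline_kwargs)
        seen = set()
        for p in plateaus:
            if p.assigned_state in levels:
                seen.add(p.assigned_state)
                levels[p.assigned_state].append(p.level)
                lengths[p.assigned_state].append(p.length_nm)
        if len(seen) == len(names):
            n_both += 1
    per_state = {
        s: StateStats(
            n_plateaus=len(levels[s]),
            mean_level=float(np.mean(levels[s])) if levels[s] else float("nan"),
            mean_length_nm=float(np.mean(lengths[s])) if lengths[s] else float("nan"),
            levels=np.asarray(levels[s]),
            lengths_nm=np.asarray(lengths[s]),
        )
        for s in names
    }
    return DetectionSummary(len(traces), n_both, per_state)
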