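"""RR-interval cleaning and the 48-segment session grid.

Preprocessing follows the standard intradialytic HRV workflow: intervals
differing by more than 20% from the running reference are discarded as
ectopic, the cleaned tachogram is cut into 5-minute wall-clock segments
(48 for a full 240-minute dialysis session), and three analysis phases —
early, middle, late — each take two consecutive segments.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .series import BeatSeries

log = logging.getLogger(__name__)

#: 1-based segment pairs of the three analysis phases on the 48-segment grid.
PHASE_SEGMENTS: dict[str, tuple[int, int]] = {
    "early": (1, 2),
    "middle": (24, 25),
    "late": (47, 48),
}

#: Default ectopic-rejection threshold: fractional deviation from the
#: reference interval above which a beat is discarded.
ECTOPIC_THRESHOLD = 0.20


@dataclasses.dataclass(frozen=True)
class CleanSeries:
    """A filtered tachogram plus the indices removed from the input."""

    series: BeatSeries
    removed_indices: np.ndarray
    n_input: int

    @property
    def removed_fraction(self) -> float:
        return len(self.removed_indices) / self.n_input if self.n_input else 0.0

    def removal_report(self, raw: BeatSeries) -> pd.DataFrame:
        """Tabulate removed beats (index, time, rr, reason) for audit output."""
        idx = self.removed_indices
        return pd.DataFrame(
            {
                "index": idx,
                "time_s": raw.time[idx],
                "rr_ms": raw.rr[idx],
                "reason": "ectopic>20%",
            }
        )


def filter_ectopic(series: BeatSeries, threshold: float = ECTOPIC_THRESHOLD) -> CleanSeries:
    """Remove ectopic beats: RRIs more than ``threshold`` (default 20%)
    different from the reference interval.

    The reference is the most recent *retained* interval, not the raw
    predecessor.  This prevents a single ectopic beat from cascading into
    the removal of the normal beats that follow it, and makes the filter
    idempotent: filtering an already-clean series removes nothing.
    """
    if len(series) < 2:
        raise ValueError("ectopic filtering needs at least two beats")
    rr = series.rr
    rr_list = rr.tolist()  # scalar loop is much faster on a plain list
    keep = np.ones(len(rr), dtype=bool)
    ref = rr_list[0]  # first beat is always retained
    for i in range(1, len(rr_list)):
        x = rr_list[i]
        if abs(x - ref) / ref > threshold:
            keep[i] = False
        else:
            ref = x
    removed = np.flatnonzero(~keep)
    clean = BeatSeries(series.time[keep], rr[keep])
    if removed.size:
        log.debug("removed %d / %d beats as ectopic", removed.size, len(rr))
    return CleanSeries(series=clean, removed_indices=removed, n_input=len(rr))


@dataclasses.dataclass(frozen=True)
class SegmentGrid:
    """Partition of a tachogram into consecutive wall-clock segments.

    Segment k (1-based) covers the half-open window
    ``[(k-1)*segment_length, k*segment_length)`` seconds.  ``starts[k-1]``
    and ``starts[k]`` bound the beat indices of segment k in ``series``.
    """

    series: BeatSeries
    segment_length: float
    n_segments: int
    starts: np.ndarray  # length n_segments + 1, beat-index bounds

    def window(self, k: int) -> tuple[float, float]:
        """Time window (s) of 1-based segment ``k``."""
        self._check(k)
        return ((k - 1) * self.segment_length, k * self.segment_length)

    def indices(self, k: int) -> np.ndarray:
        """Beat indices (into ``series``) of 1-based segment ``k``."""
        self._check(k)
        return np.arange(self.starts[k - 1], self.starts[k])

    def segment(self, k: int) -> BeatSeries:
        idx = self.indices(k)
        return BeatSeries(self.series.time[idx], self.series.rr[idx])

    def _check(self, k: int) -> None:
        if not 1 <= k <= self.n_segments:
            raise IndexError(
                f"segment {k} unavailable: grid has {self.n_segments} segments"
            )


def segment_series(
    series: BeatSeries | CleanSeries,
    segment_length: float = 300.0,
    n_segments: int = 48,
    allow_partial: bool = False,
    coverage_tol: float = 5.0,
) -> SegmentGrid:
    """Cut a (cleaned) tachogram into ``n_segments`` 5-minute segments.

    The recording must span the full grid — its last beat must reach the end
    of the final segment to within ``coverage_tol`` seconds (a few beats of
    slack for the discreteness of the heartbeat).  Shorter recordings raise
    unless ``allow_partial`` is set, in which case the grid is truncated to
    the segments actually covered and a warning is logged.
    """
    if isinstance(series, CleanSeries):
        series = series.series
    if segment_length <= 0 or n_segments < 1:
        raise ValueError("segment_length and n_segments must be positive")
    span_needed = n_segments * segment_length
    if series.duration < span_needed - coverage_tol:
        if not allow_partial:
            raise ValueError(
                f"recording spans {series.duration:.0f} s but "
                f"{span_needed:.0f} s are needed for {n_segments} segments; "
                "pass allow_partial=True for a truncated grid"
            )
        n_segments = int((series.duration + coverage_tol) // segment_length)
        if n_segments < 1:
            raise ValueError("recording shorter than a single segment")
        log.warning(
            "partial grid: recording spans %.0f s, using %d segments",
            series.duration,
            n_segments,
        )
    edges = np.arange(n_segments + 1) * segment_length
    # beats with (k-1)*L <= t < k*L belong to segment k (half-open windows)
    starts = np.searchsorted(series.time, edges, side="left")
    return SegmentGrid(
        series=series,
        segment_length=float(segment_length),
        n_segments=int(n_segments),
        starts=starts,
    )


def select_phase_segments(grid: SegmentGrid, phase: str) -> tuple[int, int]:
    """Return the two 1-based segment indices of an analysis phase."""
    try:
        pair = PHASE_SEGMENTS[phase]
    except KeyError:
        raise ValueError(
            f"unknown phase {phase!r}; expected one of {sorted(PHASE_SEGMENTS)}"
        ) from None
    for k in pair:
        if k > grid.n_segments:
            raise ValueError(
                f"phase {phase!r} needs segment {k} but the grid has only "
                f"{grid.n_segments} segments"
            )
    return pair
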