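"""Onset-aligned peri-event analysis.

Each contest's events are shifted so that dominance onset sits at time
zero, then binned into 1-min half-open intervals.  Point acts (lunge,
wing flick) are counted per bin; state acts (fence, box/tussle, chase,
pursuit, climb) contribute the fraction of bin time occupied.  Bins not
fully covered by a contest's recording are marked missing.  Cohort
summaries are per-bin medians with interquartile ranges (linear
interpolation between order statistics).  Paired pre/post comparisons
aggregate the same measure over equal-length windows ``[-w, 0)`` and
``[0, w)`` and apply the two-sided Wilcoxon signed-rank test with an
exact small-sample null.

Alignment uses the *initial* onset only; post-reversal periods are not
re-aligned here (status-conditioned tallies live in the outcomes
module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .dominance import DominanceTimeline
from .ethogram_io import (
    BEHAVIORS,
    EventTable,
    EventTableError,
    POINT_BEHAVIORS,
    STATE_BEHAVIORS,
)
from .stats import SignedRankResult, signed_rank_test, stars

__all__ = [
    "PeriEventMatrix",
    "PairedWindowResult",
    "default_measure",
    "align_and_bin",
    "summarize",
    "paired_window_test",
    "raster_table",
]


def default_measure(behavior: str) -> str:
    """count_per_min for point acts, fraction_of_time for state acts."""
    if behavior in POINT_BEHAVIORS:
        return "count_per_min"
    if behavior in STATE_BEHAVIORS:
        return "fraction_of_time"
    raise EventTableError(f"unknown behavior {behavior!r}")


def _check_measure(behavior: str, measure: Optional[str]) -> str:
    if behavior not in BEHAVIORS:
        raise EventTableError(
            f"unknown behavior {behavior!r}; allowed: {sorted(BEHAVIORS)}"
        )
    if measure is None:
        return default_measure(behavior)
    if measure not in ("count_per_min", "fraction_of_time"):
        raise ValueError(f"unknown measure {measure!r}")
    if measure != default_measure(behavior):
        raise ValueError(
            f"measure {measure!r} incompatible with "
            f"{'point' if behavior in POINT_BEHAVIORS else 'state'} "
            f"behavior {behavior!r}"
        )
    return measure


@dataclass
class PeriEventMatrix:
    """Contest x onset-aligned-bin matrix (NaN marks uncovered bins)."""

    behavior: str
    measure: str
    bin_edges_s: np.ndarray  # len n_bins + 1, multiples of bin_s, onset at 0
    values: np.ndarray  # (n_contests, n_bins)
    contest_ids: List[str]

    @property
    def bin_left_edges(self) -> np.ndarray:
        return self.bin_edges_s[:-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.contest_ids, name="contest_id"),
            columns=[f"{int(e)}" for e in self.bin_left_edges],
        )
        return df


@dataclass(frozen=True)
class PairedWindowResult:
    """Paired pre/post window comparison for one behavior."""

    behavior: str
    measure: str
    window_min: float
    n_pairs: int
    statistic: Optional[float]  # signed-rank W+ (sum of positive-diff ranks)
    p_two_sided: Optional[float]
    direction: str  # pre_greater | post_greater | none
    stars: str
    insufficient_data: bool = False

    def to_dict(self) -> dict:
        return {
            "behavior": self.behavior,
            "measure": self.measure,
            "window_min": self.window_min,
            "n_pairs": self.n_pairs,
            "statistic": self.statistic,
            "p_two_sided": self.p_two_sided,
            "direction": self.direction,
            "stars": self.stars,
            "insufficient_data": self.insufficient_data,
        }


def _interval_overlap(start: float, end: float, lo: float, hi: float) -> float:
    return max(0.0, min(end, hi) - max(start, lo))


def _window_measure(
    df: pd.DataFrame, behavior: str, lo: float, hi: float
) -> float:
    """Aggregate one contest's events of ``behavior`` over [lo, hi)."""
    if behavior in POINT_BEHAVIORS:
        t = df["start_s"].to_numpy(float)
        return float(np.count_nonzero((t >= lo) & (t < hi)))
    total = 0.0
    for s, e in zip(df["start_s"].to_numpy(float), df["end_s"].to_numpy(float)):
        total += _interval_overlap(s, e, lo, hi)
    return total / (hi - lo)


def align_and_bin(
    events: EventTable,
    timelines: Sequence[DominanceTimeline],
    behavior: str,
    measure: Optional[str] = None,
    bin_s: float = 60.0,
) -> PeriEventMatrix:
    """Build the onset-aligned contest x bin matrix.

    All timelines must be established (run :func:`apply_exclusions`
    first).  Bin 0 starts at onset; bins are half-open ``[e, e+bin_s)``
    in onset-relative seconds.  A bin is valid for a contest only when
    fully covered by its recording.
    """
    measure = _check_measure(behavior, measure)
    for tl in timelines:
        if tl.classification != "established":
            raise ValueError(
                f"contest {tl.contest_id}: alignment requires established "
                f"timelines, got {tl.classification}"
            )
    if not timelines:
        raise ValueError("no timelines given")

    lo_bin = min(-math.ceil(tl.onset_s / bin_s) for tl in timelines)
    hi_bin = max(
        math.ceil((tl.duration_s - tl.onset_s) / bin_s) for tl in timelines
    )
    edges = np.arange(lo_bin, hi_bin + 1) * bin_s
    n_bins = len(edges) - 1
    values = np.full((len(timelines), n_bins), np.nan)
    ids: List[str] = []

    for row, tl in enumerate(timelines):
        ids.append(tl.contest_id)
        df = events.select(behavior=behavior, contest_id=tl.contest_id or None)
        starts = df["start_s"].to_numpy(float) - tl.onset_s
        ends = df["end_s"].to_numpy(float) - tl.onset_s
        cover_lo = -tl.onset_s
        cover_hi = tl.duration_s - tl.onset_s
        for j in range(n_bins):
            b0, b1 = edges[j], edges[j + 1]
            if b0 < cover_lo - 1e-9 or b1 > cover_hi + 1e-9:
                continue
            if behavior in POINT_BEHAVIORS:
                values[row, j] = np.count_nonzero((starts >= b0) & (starts < b1))
            else:
                occ = 0.0
                for s, e in zip(starts, ends):
                    occ += _interval_overlap(s, e, b0, b1)
                values[row, j] = occ / bin_s
    return PeriEventMatrix(
        behavior=behavior,
        measure=measure,
        bin_edges_s=edges.astype(float),
        values=values,
        contest_ids=ids,
    )


def summarize(matrix: PeriEventMatrix, min_n: int = 5) -> pd.DataFrame:
    """Per-bin median and IQR over contests with coverage.

    Quartiles use linear interpolation between order statistics.  Bins
    with fewer than ``min_n`` contributing contests are flagged.
    """
    if matrix.values.size == 0:
        raise ValueError("empty matrix")
    vals = matrix.values
    n = np.sum(~np.isnan(vals), axis=0)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # bins covered by no contest legitimately summarize to NaN
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(vals, axis=0)
        q25 = np.nanpercentile(vals, 25, axis=0)
        q75 = np.nanpercentile(vals, 75, axis=0)
    return pd.DataFrame(
        {
            "bin_left_s": matrix.bin_left_edges,
            "median": med,
            "q25": q25,
            "q75": q75,
            "n": n,
            "low_n": n < min_n,
        }
    )


def paired_window_test(
    events: EventTable,
    timelines: Sequence[DominanceTimeline],
    behavior: str,
    window_min: float,
    measure: Optional[str] = None,
) -> PairedWindowResult:
    """Two-sided signed-rank comparison of pre vs post onset windows.

    Contests lacking a full ``[-w, 0)`` or ``[0, w)`` window inside their
    recording are dropped from this test only.
    """
    measure = _check_measure(behavior, measure)
    w = window_min * 60.0
    diffs: List[float] = []
    for tl in timelines:
        if tl.classification != "established":
            continue
        if tl.onset_s - w < tl.observation_start_s - 1e-9:
            continue
        if tl.onset_s + w > tl.duration_s + 1e-9:
            continue
        df = events.select(behavior=behavior, contest_id=tl.contest_id or None)
        pre = _window_measure(df, behavior, tl.onset_s - w, tl.onset_s)
        post = _window_measure(df, behavior, tl.onset_s, tl.onset_s + w)
        diffs.append(post - pre)
    n_pairs = len(diffs)
    if n_pairs < 2:
        return PairedWindowResult(
            behavior=behavior,
            measure=measure,
            window_min=window_min,
            n_pairs=n_pairs,
            statistic=None,
            p_two_sided=None,
            direction="none",
            stars="n.s.",
            insufficient_data=True,
        )
    res: SignedRankResult = signed_rank_test(diffs)
    return PairedWindowResult(
        behavior=behavior,
        measure=measure,
        window_min=window_min,
        n_pairs=n_pairs,
        statistic=res.w_plus,
        p_two_sided=res.p_two_sided,
        direction=res.direction,
        stars=stars(res.p_two_sided),
    )


def raster_table(
    events: EventTable,
    timelines: Sequence[DominanceTimeline],
    behavior: str,
) -> pd.DataFrame:
    """Plot-ready raster rows: onset-relative event times per contest."""
    _check_measure(behavior, None)
    rows = []
    for tl in timelines:
        if tl.classification != "established":
            continue
        df = events.select(behavior=behavior, contest_id=tl.contest_id or None)
        for _, r in df.iterrows():
            rows.append(
                {
                    "contest_id": tl.contest_id,
                    "fly": r["fly"],
                    "t_rel_start_s": r["start_s"] - tl.onset_s,
                    "t_rel_end_s": r["end_s"] - tl.onset_s,
                }
            )
    return pd.DataFrame(rows, columns=["contest_id", "fly", "t_rel_start_s", "t_rel_end_s"])
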