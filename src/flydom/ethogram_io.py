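"""On-disk data model for dyadic contest recordings.

Two plain-text table formats carry everything the pipeline consumes:

* trajectory CSV — one row per frame per fly:
  ``frame,fly,x_mm,y_mm,heading_deg[,on_wall]``.  Coordinates are
  arena-centered millimetres, headings in degrees ``[0, 360)``, frames
  0-based at a fixed frame rate.
* events CSV — one row per behavioral act:
  ``contest_id,fly,behavior,start_s,end_s``.  State-like acts (fence,
  box_tussle, chase, pursuit, climb) occupy half-open intervals
  ``[start_s, end_s)``; point-like acts (lunge, wing_flick) may have
  ``start_s == end_s``.

The behavior vocabulary is fixed: fence, wing_flick, box_tussle (boxing
and tussling merged into one category, as is customary when they are hard
to tell apart), lunge, chase, pursuit and climb.  Fly identities are the
labels {A, B} carried by the files; ``both`` marks mutual acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

__all__ = [
    "BEHAVIORS",
    "POINT_BEHAVIORS",
    "STATE_BEHAVIORS",
    "FLY_IDS",
    "ArenaGeometry",
    "EthogramError",
    "TrajectoryError",
    "EventTableError",
    "Trajectory",
    "EventTable",
    "read_trajectory",
    "write_trajectory",
    "read_events",
    "write_events",
]

#: Point-like acts: instantaneous, counted per time bin.
POINT_BEHAVIORS = frozenset({"lunge", "wing_flick"})
#: State-like acts: extended bouts, measured as fraction of time.
STATE_BEHAVIORS = frozenset({"fence", "box_tussle", "chase", "pursuit", "climb"})
BEHAVIORS = POINT_BEHAVIORS | STATE_BEHAVIORS

FLY_IDS = ("A", "B")
_EVENT_FLY_VALUES = frozenset({"A", "B", "both"})

TRAJECTORY_COLUMNS = ["frame", "fly", "x_mm", "y_mm", "heading_deg"]
EVENT_COLUMNS = ["contest_id", "fly", "behavior", "start_s", "end_s"]

#: Slack, in mm, allowed beyond the nominal arena radius before a
#: coordinate is rejected as out-of-arena.
ARENA_TOLERANCE_MM = 0.5


class EthogramError(ValueError):
    """Base class for validation failures of the on-disk data model."""


class TrajectoryError(EthogramError):
    pass


class EventTableError(EthogramError):
    pass


class ArenaGeometry(BaseModel):
    """Circular arena geometry.

    ``wall_fraction`` is the radial fraction beyond which a fly is
    considered to have left the floor (the wall proxy used when no
    explicit ``on_wall`` flag is recorded).
    """

    radius_mm: float = 8.0
    wall_fraction: float = 0.95

    @model_validator(mode="after")
    def _check(self) -> "ArenaGeometry":
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not 0.0 < self.wall_fraction < 1.0:
            raise ValueError("wall_fraction must lie in (0, 1)")
        return self


@dataclass
class Trajectory:
    """Validated per-frame kinematic state of both flies.

    ``df`` is long format sorted by (frame, fly) with exactly the columns
    of the trajectory CSV.  Times are derived: ``t_s = frame / fps``.
    """

    df: pd.DataFrame
    fps: float
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_trajectory_frame(self.df, self.fps, self.geometry)

    @property
    def n_frames(self) -> int:
        return int(self.df["frame"].max()) + 1

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def has_on_wall(self) -> bool:
        return "on_wall" in self.df.columns

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def fly_frame(self, fly: str) -> pd.DataFrame:
        sub = self.df[self.df["fly"] == fly]
        return sub.reset_index(drop=True)

    def positions(self, fly: str) -> np.ndarray:
        sub = self.fly_frame(fly)
        return sub[["x_mm", "y_mm"]].to_numpy(dtype=float)

    def headings_deg(self, fly: str) -> np.ndarray:
        return self.fly_frame(fly)["heading_deg"].to_numpy(dtype=float)

    def on_wall(self, fly: str) -> Optional[np.ndarray]:
        if not self.has_on_wall:
            return None
        return self.fly_frame(fly)["on_wall"].to_numpy(dtype=bool)


def _validate_trajectory_frame(
    df: pd.DataFrame, fps: float, geometry: ArenaGeometry
) -> None:
    if fps <= 0:
        raise TrajectoryError("fps must be positive")
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"trajectory missing columns: {missing}")
    bad_fly = set(df["fly"].unique()) - set(FLY_IDS)
    if bad_fly:
        raise TrajectoryError(f"unknown fly ids: {sorted(bad_fly)} (expected {FLY_IDS})")
    frames = np.sort(df["frame"].unique())
    n = len(frames)
    if n == 0:
        raise TrajectoryError("trajectory is empty")
    if frames[0] != 0 or frames[-1] != n - 1:
        raise TrajectoryError("frame indices must be 0-based and contiguous")
    for fly in FLY_IDS:
        sub = df[df["fly"] == fly]
        if len(sub) != n:
            present = set(sub["frame"])
            absent = sorted(set(range(n)) - present)[:5]
            raise TrajectoryError(
                f"fly {fly} absent from frames {absent}"
                + ("..." if len(sub) < n - len(absent) else "")
            )
        fvals = sub["frame"].to_numpy()
        if not np.all(np.diff(fvals) > 0):
            raise TrajectoryError(f"fly {fly}: frames not strictly increasing")
    r = np.hypot(df["x_mm"].to_numpy(float), df["y_mm"].to_numpy(float))
    limit = geometry.radius_mm + ARENA_TOLERANCE_MM
    out = np.nonzero(r > limit)[0]
    if out.size:
        rows = out[:5].tolist()
        raise TrajectoryError(
            f"coordinates beyond arena radius (+{ARENA_TOLERANCE_MM} mm tolerance) "
            f"at rows {rows}"
        )
    h = df["heading_deg"].to_numpy(float)
    if np.any(~np.isfinite(h)) or np.any((h < 0) | (h >= 360.0)):
        raise TrajectoryError("heading_deg must be finite and in [0, 360)")


@dataclass
class EventTable:
    """Validated table of behavioral events (the ethogram)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate_event_frame(self.df)

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame(columns=EVENT_COLUMNS))

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "EventTable":
        df = pd.DataFrame(list(rows), columns=EVENT_COLUMNS)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def select(
        self,
        behavior: Optional[str] = None,
        fly: Optional[str] = None,
        contest_id: Optional[str] = None,
    ) -> pd.DataFrame:
        df = self.df
        if behavior is not None:
            if behavior not in BEHAVIORS:
                raise EventTableError(
                    f"unknown behavior {behavior!r}; allowed: {sorted(BEHAVIORS)}"
                )
            df = df[df["behavior"] == behavior]
        if fly is not None:
            df = df[df["fly"] == fly]
        if contest_id is not None:
            df = df[df["contest_id"] == contest_id]
        return df.reset_index(drop=True)

    def contest_ids(self) -> list:
        return list(dict.fromkeys(self.df["contest_id"]))

    def concat(self, other: "EventTable") -> "EventTable":
        frames = [df for df in (self.df, other.df) if len(df)]
        if not frames:
            return EventTable.empty()
        return EventTable(pd.concat(frames, ignore_index=True))

    def sorted(self) -> "EventTable":
        df = self.df.sort_values(
            ["contest_id", "start_s", "end_s", "behavior", "fly"], kind="mergesort"
        )
        return EventTable(df.reset_index(drop=True))


def _validate_event_frame(df: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventTableError(f"event table missing columns: {missing}")
    if len(df) == 0:
        return
    bad = df[~df["behavior"].isin(BEHAVIORS)]
    if len(bad):
        labels = sorted(set(bad["behavior"]))
        raise EventTableError(
            f"unknown behavior labels {labels}; allowed vocabulary: {sorted(BEHAVIORS)}"
        )
    bad_fly = set(df["fly"].unique()) - _EVENT_FLY_VALUES
    if bad_fly:
        raise EventTableError(
            f"unknown fly values {sorted(bad_fly)}; allowed: {sorted(_EVENT_FLY_VALUES)}"
        )
    start = df["start_s"].to_numpy(float)
    end = df["end_s"].to_numpy(float)
    if np.any(~np.isfinite(start)) or np.any(~np.isfinite(end)):
        raise EventTableError("event times must be finite")
    neg = np.nonzero(start < 0)[0]
    if neg.size:
        raise EventTableError(f"negative start_s at rows {neg[:5].tolist()}")
    is_state = df["behavior"].isin(STATE_BEHAVIORS).to_numpy()
    bad_state = np.nonzero(is_state & (start >= end))[0]
    if bad_state.size:
        raise EventTableError(
            "state-like behaviors require start_s < end_s; violated at rows "
            f"{bad_state[:5].tolist()}"
        )
    bad_point = np.nonzero(~is_state & (start > end))[0]
    if bad_point.size:
        raise EventTableError(
            f"start_s > end_s at rows {bad_point[:5].tolist()}"
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_trajectory(
    path: str | Path, fps: float, geometry: Optional[ArenaGeometry] = None
) -> Trajectory:
    """Read and validate a trajectory CSV.

    When the optional ``on_wall`` column is absent it is *not* synthesized
    here; downstream feature computation fills it from the radial
    threshold of ``geometry``.
    """
    geometry = geometry or ArenaGeometry()
    df = pd.read_csv(path)
    if "on_wall" in df.columns:
        df["on_wall"] = df["on_wall"].astype(int).astype(bool)
    df = df.sort_values(["frame", "fly"], kind="mergesort").reset_index(drop=True)
    return Trajectory(df, fps=fps, geometry=geometry)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    df = traj.df.copy()
    if "on_wall" in df.columns:
        df["on_wall"] = df["on_wall"].astype(int)
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> EventTable:
    df = pd.read_csv(path, dtype={"contest_id": str, "fly": str, "behavior": str})
    if len(df) == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
    return EventTable(df)


def write_events(table: EventTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
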