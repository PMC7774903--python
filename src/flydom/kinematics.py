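"""Per-frame kinematic features and bout segmentation.

The detectors here operationalize the trajectory-visible acts:

* **pursuit** — one fly trailing the other at close range with its
  heading aligned to the opponent; short bouts, restricted to the floor.
* **chase** — a pursuit-shaped bout that is long *and* fast; chases are
  re-labeled out of the pursuit set so the two classes partition the
  trailing bouts exhaustively and exclusively.
* **climb** — sustained occupancy of the arena wall (radial fraction at
  or beyond the wall threshold, or an explicit on-wall flag), the
  operational "leaves the floor".
* **lunge** — a point event: a rapid forward thrust towards a nearby
  opponent, detected as a displacement threshold over a short window.

All thresholds live in :class:`DetectorParams`; none of them comes from a
printed value, they are calibratable defaults at plausible fly scales.
Fence, box/tussle and wing flick have no trajectory signature a top-down
2-D track can resolve and are consumed from annotation files or simulator
truth instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from pydantic import BaseModel, model_validator

from .ethogram_io import (
    EventTable,
    FLY_IDS,
    ArenaGeometry,
    Trajectory,
)

__all__ = [
    "DetectorParams",
    "FeatureSeries",
    "Bout",
    "compute_features",
    "detect_pursuit",
    "detect_chase",
    "detect_climb",
    "detect_lunge",
    "detect_all",
    "bouts_to_events",
]


class DetectorParams(BaseModel):
    """Thresholds for the trajectory-based bout detectors (mm, s, deg)."""

    # pursuit
    pursuit_d_max_mm: float = 5.0
    pursuit_v_min_mm_s: float = 3.0
    pursuit_theta_max_deg: float = 45.0
    pursuit_t_min_s: float = 1.0
    pursuit_gap_max_s: float = 0.2
    # chase re-labeling
    chase_min_s: float = 5.0
    chase_v_min_mm_s: float = 10.0
    # climb
    climb_min_s: float = 0.5
    # lunge
    lunge_window_s: float = 0.1
    lunge_disp_min_mm: float = 1.5
    lunge_d_max_mm: float = 3.0
    lunge_theta_max_deg: float = 30.0
    lunge_refractory_s: float = 0.3
    # diagnostic linking (used by the dominance module)
    link_max_s: float = 2.0
    k_confirm: int = 1
    pre_established_tol_s: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "DetectorParams":
        positive = [
            self.pursuit_d_max_mm,
            self.pursuit_v_min_mm_s,
            self.pursuit_theta_max_deg,
            self.pursuit_t_min_s,
            self.chase_min_s,
            self.chase_v_min_mm_s,
            self.climb_min_s,
            self.lunge_window_s,
            self.lunge_disp_min_mm,
            self.lunge_d_max_mm,
            self.lunge_theta_max_deg,
            self.link_max_s,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("detector thresholds must be positive")
        if self.pursuit_gap_max_s < 0 or self.lunge_refractory_s < 0:
            raise ValueError("gap/refractory durations must be non-negative")
        if self.k_confirm < 1:
            raise ValueError("k_confirm must be >= 1")
        return self


@dataclass
class FeatureSeries:
    """Per-frame kinematic features for both flies of a dyad."""

    t_s: np.ndarray
    fps: float
    speed_mm_s: Dict[str, np.ndarray]
    radial_fraction: Dict[str, np.ndarray]
    bearing_error_deg: Dict[str, np.ndarray]
    on_wall: Dict[str, np.ndarray]
    inter_fly_distance_mm: np.ndarray
    positions: Dict[str, np.ndarray]

    @property
    def n_frames(self) -> int:
        return len(self.t_s)


@dataclass(frozen=True)
class Bout:
    """A detected behavioral bout (or point event, for lunges)."""

    fly: str
    kind: str
    start_s: float
    end_s: float
    mean_speed_mm_s: float
    target_fly: Optional[str] = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _other(fly: str) -> str:
    return "B" if fly == "A" else "A"


def compute_features(
    traj: Trajectory, geometry: Optional[ArenaGeometry] = None
) -> FeatureSeries:
    """Derive speeds, radial fractions, bearing errors and wall occupancy.

    Speed uses central differences with one-sided differences at the
    first/last frame.  ``on_wall`` is the trajectory's own flag when the
    column exists, else ``radial_fraction >= wall_fraction``.
    """
    geometry = geometry or traj.geometry
    fps = traj.fps
    t = traj.t_s
    pos = {fly: traj.positions(fly) for fly in FLY_IDS}
    n = len(t)

    speed: Dict[str, np.ndarray] = {}
    radial: Dict[str, np.ndarray] = {}
    bearing: Dict[str, np.ndarray] = {}
    wall: Dict[str, np.ndarray] = {}
    for fly in FLY_IDS:
        p = pos[fly]
        v = np.empty(n)
        if n == 1:
            v[:] = 0.0
        else:
            d = p[2:] - p[:-2]
            v[1:-1] = np.hypot(d[:, 0], d[:, 1]) * fps / 2.0
            v[0] = np.hypot(*(p[1] - p[0])) * fps
            v[-1] = np.hypot(*(p[-1] - p[-2])) * fps
        speed[fly] = v
        radial[fly] = np.hypot(p[:, 0], p[:, 1]) / geometry.radius_mm

        to_opp = pos[_other(fly)] - p
        ang_opp = np.degrees(np.arctan2(to_opp[:, 1], to_opp[:, 0]))
        diff = np.abs((traj.headings_deg(fly) - ang_opp + 180.0) % 360.0 - 180.0)
        bearing[fly] = diff

        flag = traj.on_wall(fly)
        if flag is None:
            wall[fly] = radial[fly] >= geometry.wall_fraction
        else:
            wall[fly] = flag.astype(bool)

    dvec = pos["A"] - pos["B"]
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    return FeatureSeries(
        t_s=t,
        fps=fps,
        speed_mm_s=speed,
        radial_fraction=radial,
        bearing_error_deg=bearing,
        on_wall=wall,
        inter_fly_distance_mm=dist,
        positions=pos,
    )


# ---------------------------------------------------------------------------
# mask → bout machinery (mask, merge gaps, drop short — fixed order)


def _runs(mask: np.ndarray) -> List[tuple]:
    """Maximal runs of True as (first_frame, last_frame_exclusive)."""
    if not mask.any():
        return []
    m = mask.astype(np.int8)
    edges = np.diff(np.concatenate(([0], m, [0])))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_gaps(runs: List[tuple], gap_max_frames: int) -> List[tuple]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= gap_max_frames:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def pursuit_frame_mask(
    features: FeatureSeries, actor: str, params: DetectorParams
) -> np.ndarray:
    """Frame mask of pursuit-compatible frames for ``actor`` (pre-filter)."""
    return (
        (features.inter_fly_distance_mm <= params.pursuit_d_max_mm)
        & (features.speed_mm_s[actor] >= params.pursuit_v_min_mm_s)
        & (features.bearing_error_deg[actor] <= params.pursuit_theta_max_deg)
        & ~features.on_wall[actor]
    )


def detect_pursuit(
    features: FeatureSeries, params: Optional[DetectorParams] = None
) -> List[Bout]:
    """Segment trailing bouts (pursuits, before chase re-labeling)."""
    params = params or DetectorParams()
    fps = features.fps
    gap_frames = int(round(params.pursuit_gap_max_s * fps))
    min_frames = int(round(params.pursuit_t_min_s * fps))
    bouts: List[Bout] = []
    for actor in FLY_IDS:
        mask = pursuit_frame_mask(features, actor, params)
        runs = _merge_gaps(_runs(mask), gap_frames)
        for s, e in runs:
            if e - s < min_frames:
                continue
            bouts.append(
                Bout(
                    fly=actor,
                    kind="pursuit",
                    start_s=s / fps,
                    end_s=e / fps,
                    mean_speed_mm_s=float(np.mean(features.speed_mm_s[actor][s:e])),
                    target_fly=_other(actor),
                )
            )
    bouts.sort(key=lambda b: (b.start_s, b.fly))
    return bouts


def detect_chase(
    pursuit_bouts: List[Bout], params: Optional[DetectorParams] = None
) -> List[Bout]:
    """Re-label long, high-speed trailing bouts as chases.

    The returned list contains every input bout exactly once, labeled
    either ``pursuit`` or ``chase``.
    """
    params = params or DetectorParams()
    out: List[Bout] = []
    for b in pursuit_bouts:
        is_chase = (
            b.duration_s >= params.chase_min_s
            and b.mean_speed_mm_s >= params.chase_v_min_mm_s
        )
        kind = "chase" if is_chase else "pursuit"
        out.append(
            Bout(
                fly=b.fly,
                kind=kind,
                start_s=b.start_s,
                end_s=b.end_s,
                mean_speed_mm_s=b.mean_speed_mm_s,
                target_fly=b.target_fly,
            )
        )
    return out


def detect_climb(
    features: FeatureSeries, params: Optional[DetectorParams] = None
) -> List[Bout]:
    """Segment wall excursions: maximal on-wall runs of sufficient length."""
    params = params or DetectorParams()
    fps = features.fps
    min_frames = int(round(params.climb_min_s * fps))
    bouts: List[Bout] = []
    for fly in FLY_IDS:
        for s, e in _runs(features.on_wall[fly]):
            if e - s < min_frames:
                continue
            bouts.append(
                Bout(
                    fly=fly,
                    kind="climb",
                    start_s=s / fps,
                    end_s=e / fps,
                    mean_speed_mm_s=float(np.mean(features.speed_mm_s[fly][s:e])),
                    target_fly=None,
                )
            )
    bouts.sort(key=lambda b: (b.start_s, b.fly))
    return bouts


def detect_lunge(
    features: FeatureSeries, params: Optional[DetectorParams] = None
) -> List[Bout]:
    """Detect lunges: forward thrusts at close range towards the opponent.

    A candidate frame ``i`` requires displacement ``|p[i+w] - p[i]|`` at
    least ``lunge_disp_min_mm`` over the window, opponent distance at the
    window start at most ``lunge_d_max_mm`` and bearing error at most
    ``lunge_theta_max_deg``.  Candidates closer than the refractory period
    merge into the first.
    """
    params = params or DetectorParams()
    fps = features.fps
    w = max(1, int(round(params.lunge_window_s * fps)))
    refractory = params.lunge_refractory_s
    n = features.n_frames
    events: List[Bout] = []
    for actor in FLY_IDS:
        p = features.positions[actor]
        if n <= w:
            continue
        disp = np.hypot(*(p[w:] - p[:-w]).T)
        mask = (
            (disp >= params.lunge_disp_min_mm)
            & (features.inter_fly_distance_mm[:-w] <= params.lunge_d_max_mm)
            & (features.bearing_error_deg[actor][:-w] <= params.lunge_theta_max_deg)
        )
        cand = np.nonzero(mask)[0]
        last_t = -np.inf
        for i in cand:
            t = i / fps
            if t - last_t < refractory:
                continue
            last_t = t
            events.append(
                Bout(
                    fly=actor,
                    kind="lunge",
                    start_s=t,
                    end_s=t,
                    mean_speed_mm_s=float(disp[i] / (w / fps)),
                    target_fly=_other(actor),
                )
            )
    events.sort(key=lambda b: (b.start_s, b.fly))
    return events


def detect_all(
    traj: Trajectory,
    params: Optional[DetectorParams] = None,
    geometry: Optional[ArenaGeometry] = None,
) -> List[Bout]:
    """Run every detector on a trajectory; returns all bouts sorted."""
    params = params or DetectorParams()
    features = compute_features(traj, geometry)
    trailing = detect_chase(detect_pursuit(features, params), params)
    climbs = detect_climb(features, params)
    lunges = detect_lunge(features, params)
    bouts = trailing + climbs + lunges
    bouts.sort(key=lambda b: (b.start_s, b.kind, b.fly))
    return bouts


def bouts_to_events(bouts: List[Bout], contest_id: str) -> EventTable:
    """Export detected bouts as ethogram event rows."""
    rows = [
        (contest_id, b.fly, b.kind, b.start_s, b.end_s)
        for b in bouts
    ]
    if not rows:
        return EventTable.empty()
    return EventTable.from_rows(rows)
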