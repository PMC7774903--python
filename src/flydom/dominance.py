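"""The pursue-to-climb criterion: dominance onset, reversals, exclusions.

A **diagnostic instance** occurs when a climb by fly X begins during, or
within a short linking window after, a pursuit bout whose actor is the
other fly Y.  The pursuer is classified dominant; the climb marks the
retreating fly leaving the floor.  The first instance sets dominance
onset; a later instance whose pursuer is the current subordinate is a
reversal that transfers dominant status.  Contests whose first diagnostic
pursuit was already in progress at the start of observation are
"pre-established"; contests with no instance never establish.  Both
classes are excluded from downstream analyses (with machine-readable
reasons), mirroring standard practice for peri-onset alignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from .kinematics import Bout, DetectorParams

__all__ = [
    "DiagnosticInstance",
    "DominanceTimeline",
    "find_diagnostic_instances",
    "build_timeline",
    "apply_exclusions",
    "write_timelines",
    "read_timelines",
]

logger = logging.getLogger(__name__)

UNESTABLISHED = "unestablished"


@dataclass(frozen=True)
class DiagnosticInstance:
    """One pursue-to-climb occurrence: climb time plus the roles."""

    time_s: float  # climb start
    pursuer: str
    climber: str
    pursuit_start_s: float
    pursuit_end_s: float


@dataclass
class DominanceTimeline:
    """Onset, ordered reversals and per-instant dominance status."""

    contest_id: str
    classification: str  # established | pre_established | never_established
    onset_s: Optional[float]
    dominant_at_onset: Optional[str]
    reversals: List[Tuple[float, str]] = field(default_factory=list)
    duration_s: float = 0.0
    observation_start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.classification not in (
            "established",
            "pre_established",
            "never_established",
        ):
            raise ValueError(f"bad classification {self.classification!r}")
        if self.classification == "never_established":
            if self.onset_s is not None or self.reversals:
                raise ValueError("never_established implies no onset and no reversals")
        else:
            if self.onset_s is None or self.dominant_at_onset is None:
                raise ValueError("established timelines need onset and dominant")
            times = [t for t, _ in self.reversals]
            if any(t <= self.onset_s for t in times):
                raise ValueError("reversals must fall strictly after onset")
            if any(b <= a for a, b in zip(times, times[1:])) :
                raise ValueError("reversal times must be strictly increasing")
            who = [self.dominant_at_onset] + [d for _, d in self.reversals]
            if any(a == b for a, b in zip(who, who[1:])):
                raise ValueError("consecutive reversals must alternate dominant")

    def status(self, t: float) -> str:
        """Dominance status at time ``t``: unestablished / A_dominant / B_dominant."""
        if self.onset_s is None or t < self.onset_s:
            return UNESTABLISHED
        dom = self.dominant_at_onset
        for rt, new_dom in self.reversals:
            if t >= rt:
                dom = new_dom
            else:
                break
        return f"{dom}_dominant"

    def dominant_at(self, t: float) -> Optional[str]:
        s = self.status(t)
        return None if s == UNESTABLISHED else s[0]

    def segments(self) -> List[Tuple[float, float, str]]:
        """Tile ``[observation_start_s, duration_s)`` with status segments."""
        t0, t1 = self.observation_start_s, self.duration_s
        if self.onset_s is None:
            return [(t0, t1, UNESTABLISHED)]
        edges = [t0]
        if self.onset_s > t0:
            edges.append(self.onset_s)
        edges.extend(rt for rt, _ in self.reversals if t0 < rt < t1)
        edges.append(t1)
        segs = []
        for a, b in zip(edges, edges[1:]):
            if b > a:
                segs.append((a, b, self.status(a)))
        return segs

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "contest_id": self.contest_id,
            "classification": self.classification,
            "onset_s": self.onset_s,
            "dominant_at_onset": self.dominant_at_onset,
            "reversals": [
                {"t_s": t, "new_dominant": d} for t, d in self.reversals
            ],
            "duration_s": self.duration_s,
            "observation_start_s": self.observation_start_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DominanceTimeline":
        return cls(
            contest_id=d["contest_id"],
            classification=d["classification"],
            onset_s=d["onset_s"],
            dominant_at_onset=d["dominant_at_onset"],
            reversals=[(r["t_s"], r["new_dominant"]) for r in d["reversals"]],
            duration_s=d.get("duration_s", 0.0),
            observation_start_s=d.get("observation_start_s", 0.0),
        )


def find_diagnostic_instances(
    pursuits: Sequence[Bout],
    climbs: Sequence[Bout],
    params: Optional[DetectorParams] = None,
) -> List[DiagnosticInstance]:
    """Link climbs to the pursuit bouts that culminate in them.

    A climb by X starting during, or within ``link_max_s`` after, a
    pursuit bout by Y (Y != X) yields an instance at the climb start.
    When several pursuits qualify, the most recent (latest start) is
    linked.  Candidate pairs where the pursuit actor equals the climber
    are rejected and logged.
    """
    params = params or DetectorParams()
    link = params.link_max_s
    instances: List[DiagnosticInstance] = []
    for climb in climbs:
        c = climb.start_s
        best: Optional[Bout] = None
        for p in pursuits:
            if p.kind not in ("pursuit", "chase"):
                continue
            if not (p.start_s <= c <= p.end_s + link):
                continue
            if p.fly == climb.fly:
                logger.info(
                    "rejected self-pair: %s pursues and climbs at t=%.2f s",
                    climb.fly,
                    c,
                )
                continue
            if best is None or p.start_s > best.start_s:
                best = p
        if best is not None:
            instances.append(
                DiagnosticInstance(
                    time_s=c,
                    pursuer=best.fly,
                    climber=climb.fly,
                    pursuit_start_s=best.start_s,
                    pursuit_end_s=best.end_s,
                )
            )
    instances.sort(key=lambda i: (i.time_s, i.pursuit_start_s))
    return instances


def _dedupe_simultaneous(
    instances: List[DiagnosticInstance],
) -> List[DiagnosticInstance]:
    """Resolve opposite-role instances at identical timestamps.

    Keeps the instance whose pursuit bout started earlier (deterministic
    tie-break); logs the drop.
    """
    out: List[DiagnosticInstance] = []
    i = 0
    while i < len(instances):
        group = [instances[i]]
        j = i + 1
        while j < len(instances) and instances[j].time_s == instances[i].time_s:
            group.append(instances[j])
            j += 1
        if len(group) > 1 and len({g.pursuer for g in group}) > 1:
            keep = min(group, key=lambda g: g.pursuit_start_s)
            logger.info(
                "simultaneous opposite-role instances at t=%.2f s; keeping "
                "pursuer %s (earlier pursuit start)",
                keep.time_s,
                keep.pursuer,
            )
            out.append(keep)
        else:
            out.extend(group)
        i = j
    return out


def build_timeline(
    instances: Sequence[DiagnosticInstance],
    duration_s: float,
    observation_start_s: float = 0.0,
    params: Optional[DetectorParams] = None,
    contest_id: str = "",
) -> DominanceTimeline:
    """Fold diagnostic instances into a dominance timeline.

    ``params.k_confirm`` instances by the same pursuer are required
    before onset is declared (default 1); the same count governs
    reversals.  Instances confirming the current dominant reset a
    challenger's count and change nothing else.
    """
    params = params or DetectorParams()
    k = params.k_confirm
    tol = params.pre_established_tol_s
    inst = _dedupe_simultaneous(sorted(instances, key=lambda i: i.time_s))

    onset: Optional[float] = None
    dominant: Optional[str] = None
    onset_pursuit_start: Optional[float] = None
    reversals: List[Tuple[float, str]] = []
    counts: dict = {}
    for it in inst:
        if onset is None:
            counts[it.pursuer] = counts.get(it.pursuer, 0) + 1
            if counts[it.pursuer] >= k:
                onset = it.time_s
                dominant = it.pursuer
                onset_pursuit_start = it.pursuit_start_s
                counts = {}
        else:
            if it.pursuer == dominant:
                counts = {}
                continue
            counts[it.pursuer] = counts.get(it.pursuer, 0) + 1
            if counts[it.pursuer] >= k:
                reversals.append((it.time_s, it.pursuer))
                dominant = it.pursuer
                counts = {}

    if onset is None:
        return DominanceTimeline(
            contest_id=contest_id,
            classification="never_established",
            onset_s=None,
            dominant_at_onset=None,
            reversals=[],
            duration_s=duration_s,
            observation_start_s=observation_start_s,
        )
    # first diagnostic pursuit already running at the start of observation?
    if onset_pursuit_start is not None and onset_pursuit_start <= observation_start_s + tol:
        return DominanceTimeline(
            contest_id=contest_id,
            classification="pre_established",
            onset_s=observation_start_s,
            dominant_at_onset=_first_dominant(inst, onset),
            reversals=reversals,
            duration_s=duration_s,
            observation_start_s=observation_start_s,
        )
    return DominanceTimeline(
        contest_id=contest_id,
        classification="established",
        onset_s=onset,
        dominant_at_onset=_first_dominant(inst, onset),
        reversals=reversals,
        duration_s=duration_s,
        observation_start_s=observation_start_s,
    )


def _first_dominant(
    instances: Sequence[DiagnosticInstance], onset: float
) -> str:
    for it in instances:
        if it.time_s == onset:
            return it.pursuer
    # onset always comes from an instance time
    raise RuntimeError("onset time not found among instances")


def apply_exclusions(
    timelines: Iterable[DominanceTimeline],
) -> Tuple[List[DominanceTimeline], List[Tuple[DominanceTimeline, str]]]:
    """Partition timelines into analyzable and excluded-with-reason.

    Pre-established and never-established contests are excluded; kept
    contests all have a finite onset strictly after observation start.
    """
    kept: List[DominanceTimeline] = []
    excluded: List[Tuple[DominanceTimeline, str]] = []
    for tl in timelines:
        if tl.classification == "established":
            kept.append(tl)
        else:
            excluded.append((tl, tl.classification))
    return kept, excluded


def write_timelines(timelines: Sequence[DominanceTimeline], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([tl.to_dict() for tl in timelines], fh, indent=1)
        fh.write("\n")


def read_timelines(path: str | Path) -> List[DominanceTimeline]:
    with open(path) as fh:
        data = json.load(fh)
    return [DominanceTimeline.from_dict(d) for d in data]
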