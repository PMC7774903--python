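"""Synthetic dyadic contests with known ground truth.

Generates 20-min, 30 frames/s contests in a 16-mm circular arena with
the canonical temporal structure of fly dominance fights: fencing is
prevalent before the onset of dominance; boxing/tussling ramps up and
peaks in the final pre-onset minute; wing flicks step up at onset;
lunges emerge at onset and increase thereafter; chases appear only well
after onset.  Dominance onset itself is scripted as the diagnostic
pursue-to-climb sequence — the eventual dominant pursues the retreating
fly until it leaves the floor by running up the arena wall — and
reversals are role-swapped repetitions of that sequence.

Two layers are exposed:

* :func:`simulate_truth` — timeline + true event streams only (fast;
  used for statistical calibration experiments).
* :func:`simulate_contest` — additionally renders a frame-by-frame
  trajectory (correlated random walks interleaved with the scripted
  pursuit / climb / chase / lunge motion) that the kinematic detectors
  can segment; the scripted acts are recovered by the detectors by
  construction.

Everything is reproducible from ``(config, seed)``; cohort members get
seeds derived deterministically from the cohort seed and index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .dominance import DominanceTimeline
from .ethogram_io import ArenaGeometry, EventTable, Trajectory

__all__ = [
    "RateProfile",
    "PursuitParams",
    "SimConfig",
    "GroundTruth",
    "SimulatedContest",
    "default_profiles",
    "null_profiles",
    "derived_seed",
    "simulate_truth",
    "simulate_contest",
    "simulate_cohort",
    "winner_rematch",
]


class RateProfile(BaseModel):
    """Piecewise-linear act rate as a function of time relative to onset.

    ``breakpoints`` are ``(t_rel_s, rate_per_min)`` pairs; the rate is
    linearly interpolated between them and held flat beyond the ends.
    ``kind`` separates point acts (counted) from state acts (bouts with
    gamma-distributed durations around ``bout_mean_s``).
    """

    breakpoints: List[Tuple[float, float]]
    kind: Literal["point", "state"]
    bout_mean_s: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "RateProfile":
        if not self.breakpoints:
            raise ValueError("profile needs at least one breakpoint")
        ts = [t for t, _ in self.breakpoints]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if any(r < 0 for _, r in self.breakpoints):
            raise ValueError("rates must be >= 0")
        if self.kind == "state" and self.bout_mean_s <= 0:
            raise ValueError("state profiles need bout_mean_s > 0")
        return self

    def rate_at(self, t_rel: np.ndarray | float) -> np.ndarray | float:
        xs = np.array([t for t, _ in self.breakpoints])
        ys = np.array([r for _, r in self.breakpoints])
        return np.interp(t_rel, xs, ys)

    @property
    def max_rate(self) -> float:
        return max(r for _, r in self.breakpoints)


def default_profiles() -> Dict[str, RateProfile]:
    """Phase-dependent act rates encoding the canonical contest structure."""
    return {
        "fence": RateProfile(
            breakpoints=[(-1e-6, 3.0), (0.0, 0.3)], kind="state", bout_mean_s=2.0
        ),
        "box_tussle": RateProfile(
            breakpoints=[(-240.0, 0.0), (0.0, 6.0), (1.0, 0.2)],
            kind="state",
            bout_mean_s=1.5,
        ),
        "wing_flick": RateProfile(
            breakpoints=[(-1e-6, 1.0), (0.0, 6.0)], kind="point"
        ),
        "lunge": RateProfile(
            breakpoints=[(0.0, 0.0), (300.0, 10.0)], kind="point"
        ),
        "chase": RateProfile(
            breakpoints=[(90.0, 0.0), (240.0, 1.2)], kind="state", bout_mean_s=7.0
        ),
    }


def null_profiles() -> Dict[str, RateProfile]:
    """Phase-independent rates: no structure around onset (null model)."""
    return {
        "fence": RateProfile(
            breakpoints=[(0.0, 1.5)], kind="state", bout_mean_s=2.0
        ),
        "box_tussle": RateProfile(
            breakpoints=[(0.0, 1.0)], kind="state", bout_mean_s=1.5
        ),
        "wing_flick": RateProfile(breakpoints=[(0.0, 3.0)], kind="point"),
        "lunge": RateProfile(breakpoints=[(0.0, 3.0)], kind="point"),
        "chase": RateProfile(
            breakpoints=[(0.0, 0.5)], kind="state", bout_mean_s=7.0
        ),
    }


class PursuitParams(BaseModel):
    """Scripted pursuit kinematics."""

    speed_mm_s: float = 10.0
    trigger_distance_mm: float = 5.0
    bout_duration_s: float = 2.0

    @model_validator(mode="after")
    def _check(self) -> "PursuitParams":
        if min(self.speed_mm_s, self.trigger_distance_mm, self.bout_duration_s) <= 0:
            raise ValueError("pursuit parameters must be positive")
        return self


class SimConfig(BaseModel):
    """Generative parameters of a synthetic contest cohort."""

    duration_s: float = 1200.0
    fps: float = 30.0
    arena: ArenaGeometry = Field(default_factory=ArenaGeometry)
    # onset latency: log-normal (median, shape), truncated
    onset_median_s: float = 420.0
    onset_sigma: float = 0.5
    onset_min_s: float = 120.0
    onset_max_s: float = 840.0
    # contest classes
    p_pre_established: float = 0.1
    p_never_established: float = 0.05
    # reversals
    p_reversal: float = 0.2
    n_reversals_geom_p: float = 0.6
    reversal_min_gap_s: float = 90.0
    # acts
    act_rate_profiles: Dict[str, RateProfile] = Field(default_factory=default_profiles)
    pursuit_params: PursuitParams = Field(default_factory=PursuitParams)
    pursuit_rate_per_min: float = 1.0
    climb_latency_s: float = 1.0
    climb_duration_s: float = 2.0
    lunge_dominant_fraction: float = 0.9
    naive_pre_lunge_prob: float = 0.1
    # winner-rematch contests
    rematch_win_prob: float = 0.75
    rematch_pre_lunge_prob: float = 0.7
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in (
            "p_pre_established",
            "p_never_established",
            "p_reversal",
            "n_reversals_geom_p",
            "lunge_dominant_fraction",
            "naive_pre_lunge_prob",
            "rematch_win_prob",
            "rematch_pre_lunge_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_pre_established + self.p_never_established > 1.0:
            raise ValueError("p_pre_established + p_never_established must be <= 1")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if self.n_reversals_geom_p == 0.0:
            raise ValueError("n_reversals_geom_p must be > 0")
        if not (0 < self.onset_min_s < self.onset_max_s < self.duration_s):
            raise ValueError("onset bounds must satisfy 0 < min < max < duration")
        if self.pursuit_params.trigger_distance_mm > 2 * self.arena.radius_mm:
            raise ValueError("pursuit trigger distance exceeds arena diameter")
        if self.pursuit_rate_per_min < 0:
            raise ValueError("rates must be >= 0")
        return self

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """A phase-independent configuration for calibration experiments."""
        base = dict(
            act_rate_profiles=null_profiles(),
            p_pre_established=0.0,
            p_never_established=0.0,
            p_reversal=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """The simulator's true timeline, event streams and parameters."""

    classification: str
    dominant_id: Optional[str]
    onset_s: Optional[float]
    reversal_times_s: List[float]
    events: EventTable
    params_used: SimConfig
    prior_dominant_id: Optional[str] = None

    def dominant_at(self, t: float) -> Optional[str]:
        if self.onset_s is None or t < self.onset_s:
            return None
        dom = self.dominant_id
        for rt in self.reversal_times_s:
            if t >= rt:
                dom = "B" if dom == "A" else "A"
            else:
                break
        return dom

    def to_timeline(self, contest_id: str = "") -> DominanceTimeline:
        """The true dominance timeline in the analysis representation."""
        if self.classification == "never_established":
            return DominanceTimeline(
                contest_id=contest_id,
                classification="never_established",
                onset_s=None,
                dominant_at_onset=None,
                reversals=[],
                duration_s=self.params_used.duration_s,
            )
        revs = []
        dom = self.dominant_id
        for rt in self.reversal_times_s:
            dom = "B" if dom == "A" else "A"
            revs.append((rt, dom))
        return DominanceTimeline(
            contest_id=contest_id,
            classification=self.classification,
            onset_s=self.onset_s,
            dominant_at_onset=self.dominant_id,
            reversals=revs,
            duration_s=self.params_used.duration_s,
        )

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "dominant_id": self.dominant_id,
            "onset_s": self.onset_s,
            "reversal_times_s": list(self.reversal_times_s),
            "prior_dominant_id": self.prior_dominant_id,
            "params_used": json.loads(self.params_used.model_dump_json()),
        }


@dataclass
class SimulatedContest:
    trajectory: Optional[Trajectory]
    truth: GroundTruth
    contest_id: str


# ---------------------------------------------------------------------------
# scripted blocks


@dataclass
class _Block:
    kind: str  # "diagnostic" | "pursuit" | "chase" | "lunge"
    actor: str
    target: str
    t0: float  # block start (approach onset)
    t1: float  # block end
    pursue_start: float = 0.0
    pursue_end: float = 0.0
    climb_start: float = 0.0
    climb_end: float = 0.0
    thrust_t: float = 0.0


@dataclass
class _Script:
    truth: GroundTruth
    blocks: List[_Block]


def derived_seed(seed: int, index: int) -> int:
    """Deterministic per-contest seed below 2**31.

    Uses SeedSequence spawn keys (the canonical independent-stream
    derivation); composing the index into the entropy words instead
    leaves measurable cross-stream structure.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def _other(fly: str) -> str:
    return "B" if fly == "A" else "A"


def _sample_point_times(
    profile: RateProfile,
    onset: Optional[float],
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson event times via thinning (rates per minute)."""
    rmax = profile.max_rate / 60.0
    if rmax <= 0:
        return np.array([])
    n = rng.poisson(rmax * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    t_rel = t - onset if onset is not None else np.full_like(t, -1e9)
    accept = rng.uniform(0.0, 1.0, size=n) * rmax <= profile.rate_at(t_rel) / 60.0
    return t[accept]


def _sample_state_bouts(
    profile: RateProfile,
    onset: Optional[float],
    duration: float,
    rng: np.random.Generator,
) -> List[Tuple[float, float]]:
    """Bout intervals: Poisson starts + gamma(2) durations, merged, clipped."""
    starts = _sample_point_times(profile, onset, duration, rng)
    bouts = []
    for s in starts:
        d = rng.gamma(2.0, profile.bout_mean_s / 2.0)
        d = max(d, 0.1)
        e = min(s + d, duration - 1e-9)
        if e > s:
            bouts.append((float(s), float(e)))
    bouts.sort()
    merged: List[Tuple[float, float]] = []
    for s, e in bouts:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class _Reservations:
    """Non-overlapping time reservations with margins."""

    def __init__(self) -> None:
        self.intervals: List[Tuple[float, float]] = []

    def try_add(self, t0: float, t1: float, margin: float) -> bool:
        for a, b in self.intervals:
            if t0 - margin < b and a < t1 + margin:
                return False
        self.intervals.append((t0, t1))
        self.intervals.sort()
        return True


def _draw_onset(cfg: SimConfig, rng: np.random.Generator) -> float:
    mu = math.log(cfg.onset_median_s)
    for _ in range(200):
        t = float(rng.lognormal(mu, cfg.onset_sigma))
        if cfg.onset_min_s <= t <= cfg.onset_max_s:
            return t
    return float(np.clip(cfg.onset_median_s, cfg.onset_min_s, cfg.onset_max_s))


def _draw_reversals(
    cfg: SimConfig, onset: float, rng: np.random.Generator
) -> List[float]:
    if rng.uniform() >= cfg.p_reversal:
        return []
    k = int(rng.geometric(cfg.n_reversals_geom_p))
    lo = onset + cfg.reversal_min_gap_s
    hi = cfg.duration_s - 60.0
    if hi <= lo:
        return []
    for _ in range(100):
        kk = min(k, max(1, int((hi - lo) / cfg.reversal_min_gap_s)))
        times = np.sort(rng.uniform(lo, hi, size=kk))
        if kk == 1 or np.min(np.diff(times)) >= cfg.reversal_min_gap_s:
            return [float(t) for t in times]
    return [float(rng.uniform(lo, hi))]


def _diagnostic_block(
    climb_t: float,
    pursuer: str,
    climber: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    approach_s: float = 3.0,
) -> _Block:
    dp = cfg.pursuit_params.bout_duration_s * rng.uniform(0.9, 1.3)
    gap = rng.uniform(0.15, 0.4) * cfg.climb_latency_s
    ps = climb_t - gap - dp
    return _Block(
        kind="diagnostic",
        actor=pursuer,
        target=climber,
        t0=ps - approach_s,
        t1=climb_t + cfg.climb_duration_s,
        pursue_start=ps,
        pursue_end=climb_t - gap,
        climb_start=climb_t,
        climb_end=climb_t + cfg.climb_duration_s,
    )


def _build_script(
    cfg: SimConfig,
    seed: int,
    contest_id: str,
    rematch_prior_dominant: Optional[str] = None,
) -> _Script:
    """Draw the ground-truth timeline, scripted blocks and event streams."""
    ss = np.random.SeedSequence(int(seed))
    rng_truth, _ = [np.random.default_rng(s) for s in ss.spawn(2)]
    rng = rng_truth
    duration = cfg.duration_s

    u = rng.uniform()
    if u < cfg.p_never_established:
        classification = "never_established"
    elif u < cfg.p_never_established + cfg.p_pre_established:
        classification = "pre_established"
    else:
        classification = "established"

    rows: List[tuple] = []
    blocks: List[_Block] = []
    reservations = _Reservations()

    dominant: Optional[str] = None
    onset: Optional[float] = None
    reversal_times: List[float] = []

    if classification != "never_established":
        if rematch_prior_dominant is not None:
            win = rng.uniform() < cfg.rematch_win_prob
            dominant = "A" if win else "B"  # prior dominant is fly A by convention
        else:
            dominant = "A" if rng.uniform() < 0.5 else "B"

    if classification == "established":
        onset = _draw_onset(cfg, rng)
        reversal_times = _draw_reversals(cfg, onset, rng)
        # diagnostic sequences: onset plus role-swapped repetitions
        dom_seq = dominant
        blk = _diagnostic_block(onset, dom_seq, _other(dom_seq), cfg, rng)
        blocks.append(blk)
        reservations.try_add(blk.t0, blk.t1, 0.0)
        for rt in reversal_times:
            new_dom = _other(dom_seq)
            blk = _diagnostic_block(rt, new_dom, dom_seq, cfg, rng)
            blocks.append(blk)
            reservations.try_add(blk.t0, blk.t1, 0.0)
            dom_seq = new_dom
    elif classification == "pre_established":
        onset = 0.0
        dp = cfg.pursuit_params.bout_duration_s * 0.75
        gap = 0.3 * cfg.climb_latency_s
        blk = _Block(
            kind="diagnostic",
            actor=dominant,
            target=_other(dominant),
            t0=0.0,
            t1=dp + gap + cfg.climb_duration_s,
            pursue_start=0.0,
            pursue_end=dp,
            climb_start=dp + gap,
            climb_end=dp + gap + cfg.climb_duration_s,
        )
        blocks.append(blk)
        reservations.try_add(blk.t0, blk.t1, 0.0)

    for blk in [b for b in blocks if b.kind == "diagnostic"]:
        rows.append(
            (contest_id, blk.actor, "pursuit", blk.pursue_start, blk.pursue_end)
        )
        rows.append(
            (contest_id, blk.target, "climb", blk.climb_start, blk.climb_end)
        )

    truth_for_status = GroundTruth(
        classification=classification,
        dominant_id=dominant,
        onset_s=onset,
        reversal_times_s=reversal_times,
        events=EventTable.empty(),
        params_used=cfg,
        prior_dominant_id="A" if rematch_prior_dominant is not None else None,
    )

    margin = 3.5  # keep scripted acts clear of diagnostic link windows

    # alternating pursuit bouts that do not culminate in climbs: before
    # onset in established contests, throughout never-established ones
    if classification in ("established", "never_established"):
        rate = cfg.pursuit_rate_per_min / 60.0
        window_end = (onset - 15.0) if onset is not None else duration - 15.0
        n = rng.poisson(max(0.0, rate * max(0.0, window_end - 30.0)))
        times = np.sort(rng.uniform(30.0, max(31.0, window_end), size=n))
        actor = "A" if rng.uniform() < 0.5 else "B"
        for t in times:
            dp = cfg.pursuit_params.bout_duration_s * rng.uniform(0.6, 1.25)
            t0, t1 = t - 3.0, t + dp + 2.0  # approach + bout + clear
            if t0 < 1.0 or not reservations.try_add(t0, t1, margin):
                continue
            blocks.append(
                _Block(
                    kind="pursuit",
                    actor=actor,
                    target=_other(actor),
                    t0=t0,
                    t1=t1,
                    pursue_start=t,
                    pursue_end=t + dp,
                )
            )
            rows.append((contest_id, actor, "pursuit", float(t), float(t + dp)))
            actor = _other(actor)

    # chases (trajectory-visible, post-onset ramp)
    chase_profile = cfg.act_rate_profiles.get("chase")
    if chase_profile is not None and classification != "never_established":
        for t in _sample_point_times(chase_profile, onset, duration - 14.0, rng):
            d = float(np.clip(rng.normal(chase_profile.bout_mean_s, 1.0), 5.5, 9.0))
            t0, t1 = t - 3.0, t + d + 1.0
            if t0 < 1.0 or not reservations.try_add(t0, t1, margin):
                continue
            actor = truth_for_status.dominant_at(t) or "A"
            blocks.append(
                _Block(
                    kind="chase",
                    actor=actor,
                    target=_other(actor),
                    t0=t0,
                    t1=t1,
                    pursue_start=t,
                    pursue_end=t + d,
                )
            )
            rows.append((contest_id, actor, "chase", float(t), float(t + d)))

    # lunges (trajectory-visible point events)
    lunge_profile = cfg.act_rate_profiles.get("lunge")
    lunge_times: List[Tuple[float, str]] = []
    if lunge_profile is not None and classification != "never_established":
        for t in _sample_point_times(lunge_profile, onset, duration - 4.0, rng):
            dom = truth_for_status.dominant_at(t)
            if dom is None:
                continue
            actor = dom if rng.uniform() < cfg.lunge_dominant_fraction else _other(dom)
            lunge_times.append((float(t), actor))
    # occasional pre-onset lunges
    if classification == "established" and onset is not None and onset > 90.0:
        if rematch_prior_dominant is not None:
            if rng.uniform() < cfg.rematch_pre_lunge_prob:
                for _ in range(1 + rng.poisson(1.0)):
                    lunge_times.append(
                        (float(rng.uniform(60.0, onset - 30.0)), "A")
                    )
            if rng.uniform() < cfg.naive_pre_lunge_prob:
                lunge_times.append((float(rng.uniform(60.0, onset - 30.0)), "B"))
        else:
            if rng.uniform() < cfg.naive_pre_lunge_prob:
                fly = "A" if rng.uniform() < 0.5 else "B"
                lunge_times.append((float(rng.uniform(60.0, onset - 30.0)), fly))
    for t, actor in sorted(lunge_times):
        t0, t1 = t - 2.5, t + 0.4
        if t0 < 1.0 or not reservations.try_add(t0, t1, margin):
            continue
        blocks.append(
            _Block(
                kind="lunge",
                actor=actor,
                target=_other(actor),
                t0=t0,
                t1=t1,
                thrust_t=t,
            )
        )
        rows.append((contest_id, actor, "lunge", float(t), float(t)))

    # annotation-only acts (no trajectory signature)
    for name in ("fence", "box_tussle"):
        profile = cfg.act_rate_profiles.get(name)
        if profile is None:
            continue
        for s, e in _sample_state_bouts(profile, onset, duration, rng):
            rows.append((contest_id, "both", name, s, e))
    wf = cfg.act_rate_profiles.get("wing_flick")
    if wf is not None:
        for t in _sample_point_times(wf, onset, duration, rng):
            fly = "A" if rng.uniform() < 0.5 else "B"
            rows.append((contest_id, fly, "wing_flick", float(t), float(t)))

    events = EventTable.from_rows(rows).sorted() if rows else EventTable.empty()
    truth = GroundTruth(
        classification=classification,
        dominant_id=dominant,
        onset_s=onset,
        reversal_times_s=reversal_times,
        events=events,
        params_used=cfg,
        prior_dominant_id="A" if rematch_prior_dominant is not None else None,
    )
    blocks.sort(key=lambda b: b.t0)
    return _Script(truth=truth, blocks=blocks)


def simulate_truth(
    cfg: SimConfig, seed: int, contest_id: str = "contest"
) -> GroundTruth:
    """Ground truth only (timeline + event streams), no trajectory."""
    return _build_script(cfg, seed, contest_id).truth


# ---------------------------------------------------------------------------
# trajectory rendering

# per-frame motion modes
_WALK, _APPROACH, _PURSUE, _RETREAT, _CLIMB, _SLOW, _THRUST, _INWARD = range(8)


def _fill_modes(
    blocks: List[_Block], n: int, fps: float, cfg: SimConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mode code and nominal speed per frame per fly (A=0, B=1)."""
    mode = np.zeros((2, n), dtype=np.int8)
    vnom = np.zeros((2, n), dtype=np.float64)
    gap = np.full((2, n), 1.8, dtype=np.float64)

    def fr(t: float) -> int:
        return int(np.clip(round(t * fps), 0, n))

    idx = {"A": 0, "B": 1}
    v_pursuit = cfg.pursuit_params.speed_mm_s
    for b in blocks:
        a, tg = idx[b.actor], idx[b.target]
        if b.kind in ("diagnostic", "pursuit", "chase"):
            v = 12.5 if b.kind == "chase" else v_pursuit
            f0, f1 = fr(b.t0), fr(b.pursue_start)
            mode[a, f0:f1] = _APPROACH
            vnom[a, f0:f1] = 13.0
            f1p = fr(b.pursue_end)
            mode[a, fr(b.pursue_start):f1p] = _PURSUE
            vnom[a, fr(b.pursue_start):f1p] = v
            mode[tg, fr(b.pursue_start):f1p] = _RETREAT
            vnom[tg, fr(b.pursue_start):f1p] = v
            if b.kind == "diagnostic":
                fg0, fg1 = f1p, fr(b.climb_start)
                mode[tg, fg0:fg1] = _RETREAT  # linking gap: keep fleeing
                vnom[tg, fg0:fg1] = v
                fc0, fc1 = fr(b.climb_start), fr(b.climb_end)
                mode[tg, fc0:fc1] = _CLIMB
            else:
                fe = fr(b.t1)
                mode[tg, f1p:fe] = _INWARD
                vnom[tg, f1p:fe] = 6.0
        elif b.kind == "lunge":
            f0, fth = fr(b.t0), fr(b.thrust_t)
            fend = fr(b.thrust_t + 0.1)
            fclear = fr(b.t1)
            mode[a, f0:fth] = _APPROACH
            vnom[a, f0:fth] = 12.0
            gap[a, f0:fth] = 2.3
            mode[a, fth:fend] = _THRUST
            mode[a, fend:fclear] = _INWARD
            vnom[a, fend:fclear] = 4.0
            mode[tg, f0:fclear] = _SLOW
    return mode, vnom, gap


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _render_trajectory(
    cfg: SimConfig, script: _Script, rng: np.random.Generator
) -> Trajectory:
    import pandas as pd

    fps = cfg.fps
    n = int(round(cfg.duration_s * fps))
    R = cfg.arena.radius_mm
    wall_r = cfg.arena.wall_fraction * R
    dt = 1.0 / fps

    mode, vnom, gapv = _fill_modes(script.blocks, n, fps, cfg)
    turn_noise = rng.normal(0.0, 0.30, size=(2, n))
    spd_noise = rng.normal(0.0, 0.8, size=(2, n))
    small_noise = rng.normal(0.0, 0.10, size=(2, n))

    xs = np.empty((2, n))
    ys = np.empty((2, n))
    hds = np.empty((2, n))
    wall_flag = np.zeros((2, n), dtype=bool)

    # initial placement
    if script.truth.classification == "pre_established":
        pursuer = 0 if script.truth.dominant_id == "A" else 1
        target = 1 - pursuer
        ang = rng.uniform(0, 2 * math.pi)
        xs[target, 0], ys[target, 0] = 2.0 * math.cos(ang), 2.0 * math.sin(ang)
        xs[pursuer, 0] = xs[target, 0] - 1.8 * math.cos(ang)
        ys[pursuer, 0] = ys[target, 0] - 1.8 * math.sin(ang)
        hds[:, 0] = ang
    else:
        for k in range(2):
            rr = rng.uniform(1.0, 0.6 * R)
            aa = rng.uniform(0, 2 * math.pi)
            xs[k, 0], ys[k, 0] = rr * math.cos(aa), rr * math.sin(aa)
            hds[k, 0] = rng.uniform(0, 2 * math.pi)
    spd = [4.0, 4.0]

    for i in range(1, n):
        for k in range(2):
            o = 1 - k
            x, y, hd = xs[k, i - 1], ys[k, i - 1], hds[k, i - 1]
            ox, oy = xs[o, i - 1], ys[o, i - 1]
            m = mode[k, i]
            dx, dy = ox - x, oy - y
            dist = math.hypot(dx, dy)
            r = math.hypot(x, y)

            if m == _WALK:
                hd += turn_noise[k, i]
                if r > 0.75 * R:
                    ang_c = math.atan2(-y, -x)
                    w = min(1.0, (r / R - 0.75) * 3.0)
                    hd += _wrap_angle(ang_c - hd) * w
                v = spd[k] + spd_noise[k, i]
                v = min(max(v, 0.4), 7.0)
                spd[k] = v
            elif m == _APPROACH:
                hd = math.atan2(dy, dx)
                v = min(vnom[k, i], max(0.0, (dist - gapv[k, i]) * fps))
            elif m == _PURSUE:
                hd = math.atan2(dy, dx)
                cap = 14.0 if vnom[k, i] > 11.0 else 13.0
                v = vnom[k, i] + 3.0 * (dist - 1.8)
                v = min(max(v, 3.5), cap)
            elif m == _RETREAT:
                ang_away = math.atan2(y - oy, x - ox)
                ang_c = math.atan2(-y, -x)
                w = min(0.85, max(0.0, (r / R - 0.55) * 2.2))
                hd = ang_away + _wrap_angle(ang_c - ang_away) * w
                hd += small_noise[k, i]
                v = vnom[k, i]
            elif m == _CLIMB:
                if r < 0.965 * R:
                    hd = math.atan2(y, x)
                    v = 16.0
                else:
                    ang = math.atan2(y, x) + 0.015 * small_noise[k, i] * 10.0
                    x, y = 0.98 * R * math.cos(ang), 0.98 * R * math.sin(ang)
                    hds[k, i] = hd
                    xs[k, i], ys[k, i] = x, y
                    wall_flag[k, i] = True
                    continue
            elif m == _SLOW:
                # lunge target: drift slowly away so the gap is kept
                hd = math.atan2(y - oy, x - ox) + small_noise[k, i]
                v = 1.0
            elif m == _THRUST:
                if dist > 0.5:
                    hd = math.atan2(dy, dx)
                v = 24.0
            else:  # _INWARD
                ang_c = math.atan2(-y, -x)
                hd = ang_c + small_noise[k, i] * 3.0
                v = vnom[k, i] if vnom[k, i] > 0 else 6.0

            x += v * dt * math.cos(hd)
            y += v * dt * math.sin(hd)
            r2 = math.hypot(x, y)
            if m == _CLIMB:
                if r2 >= 0.965 * R:
                    x, y = x / r2 * 0.98 * R, y / r2 * 0.98 * R
                    wall_flag[k, i] = True
                elif r2 >= wall_r:
                    wall_flag[k, i] = True
            elif m == _RETREAT:
                if r2 > 0.90 * R:
                    x, y = x / r2 * 0.88 * R, y / r2 * 0.88 * R
            else:
                if r2 >= 0.949 * R:
                    x, y = x / r2 * 0.93 * R, y / r2 * 0.93 * R
                    hd = math.atan2(-y, -x) + 0.4 * small_noise[k, i] * 4.0
                    spd[k] = 3.0
            xs[k, i], ys[k, i] = x, y
            hds[k, i] = hd

    frames = np.repeat(np.arange(n), 2)
    fly_col = np.tile(np.array(["A", "B"]), n)
    x_col = np.empty(2 * n)
    y_col = np.empty(2 * n)
    h_col = np.empty(2 * n)
    w_col = np.empty(2 * n, dtype=bool)
    for k in range(2):
        x_col[k::2] = xs[k]
        y_col[k::2] = ys[k]
        h_col[k::2] = np.round(np.degrees(hds[k]) % 360.0, 4) % 360.0
        w_col[k::2] = wall_flag[k]
    df = pd.DataFrame(
        {
            "frame": frames,
            "fly": fly_col,
            "x_mm": np.round(x_col, 6),
            "y_mm": np.round(y_col, 6),
            "heading_deg": h_col,
            "on_wall": w_col,
        }
    )
    return Trajectory(df, fps=fps, geometry=cfg.arena)


def simulate_contest(
    cfg: SimConfig,
    contest_seed: int,
    contest_id: Optional[str] = None,
    _rematch_prior_dominant: Optional[str] = None,
) -> SimulatedContest:
    """One fully reproducible contest: trajectory + ground truth."""
    cid = contest_id if contest_id is not None else f"contest_{contest_seed}"
    script = _build_script(cfg, contest_seed, cid, _rematch_prior_dominant)
    ss = np.random.SeedSequence(int(contest_seed))
    _, rng_traj = [np.random.default_rng(s) for s in ss.spawn(2)]
    traj = _render_trajectory(cfg, script, rng_traj)
    return SimulatedContest(trajectory=traj, truth=script.truth, contest_id=cid)


def simulate_cohort(cfg: SimConfig, n: int) -> List[SimulatedContest]:
    """n contests with per-contest seeds derived from ``cfg.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        simulate_contest(cfg, derived_seed(cfg.seed, i), contest_id=f"contest_{i:03d}")
        for i in range(n)
    ]


def winner_rematch(
    cfg: SimConfig,
    first: SimulatedContest,
    seed: int,
    events_only: bool = False,
) -> SimulatedContest:
    """Pair the prior dominant (relabeled fly A) with a naive opponent.

    The prior dominant lunges before onset with elevated probability and
    wins with probability ``cfg.rematch_win_prob``; ground truth marks
    it via ``prior_dominant_id``.  With ``events_only`` no trajectory is
    rendered (fast path for event-level experiments).
    """
    if first.truth.classification != "established":
        raise ValueError("rematch requires an established first contest")
    rematch_cfg = cfg.model_copy(
        update={"p_pre_established": 0.0, "p_never_established": 0.0}
    )
    cid = f"{first.contest_id}_rematch"
    if events_only:
        script = _build_script(
            rematch_cfg, seed, cid, rematch_prior_dominant=first.truth.dominant_id
        )
        return SimulatedContest(trajectory=None, truth=script.truth, contest_id=cid)
    return simulate_contest(
        rematch_cfg,
        seed,
        contest_id=cid,
        _rematch_prior_dominant=first.truth.dominant_id,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
        fh.write("\n")
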