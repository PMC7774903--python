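"""Status-conditioned attribution, outcome tests and the full pipeline.

* :func:`attribute_by_phase` tallies each fly's acts within the phases
  of the dominance timeline (unestablished, A-dominant, B-dominant
  segments), with derived summaries: fraction of acts post-onset,
  fraction of post-onset lunges by the instantaneous dominant, and
  counts around each reversal.
* :func:`dominance_outcome_test` asks whether focal males win more often
  than chance (exact binomial against 0.5) and compares two pairings'
  win counts with Fisher's exact test.
* :func:`lunge_count_comparisons` compares dominant-male lunge counts
  across groups (Kruskal–Wallis for 3+, rank-sum for 2 independent,
  sign test for paired designs).
* :func:`precocious_lunge_analysis` compares pre-onset-lunge proportions
  between a naive cohort and a winner-rematch cohort (chi-square, df=1),
  plus the within-rematch won-vs-lost comparison among early lungers.
* :func:`run_pipeline` chains simulate/read -> detect -> timelines ->
  exclusions -> peri-event -> outcomes and writes a report bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats as sps

from .contest_sim import SimConfig, SimulatedContest, simulate_cohort
from .dominance import (
    DominanceTimeline,
    apply_exclusions,
    build_timeline,
    find_diagnostic_instances,
    write_timelines,
)
from .ethogram_io import EventTable, EventTableError, write_events
from .kinematics import DetectorParams, bouts_to_events, detect_all
from .perievent import align_and_bin, paired_window_test, summarize
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "PhasePartition",
    "PhaseAttribution",
    "OutcomeTable",
    "OutcomeTestResult",
    "GroupComparisonResult",
    "PrecociousLungeResult",
    "PipelineConfig",
    "PipelineReport",
    "attribute_by_phase",
    "dominance_outcome_test",
    "lunge_count_comparisons",
    "precocious_lunge_analysis",
    "outcome_table_from_contests",
    "run_pipeline",
]


@dataclass
class PhasePartition:
    """Status segments tiling a contest's observation period."""

    contest_id: str
    segments: List[Tuple[float, float, str]]

    @classmethod
    def from_timeline(cls, tl: DominanceTimeline) -> "PhasePartition":
        return cls(contest_id=tl.contest_id, segments=tl.segments())


@dataclass
class PhaseAttribution:
    """Per-fly, per-phase tallies and derived summaries for one contest."""

    contest_id: str
    partition: PhasePartition
    counts: pd.DataFrame  # fly, behavior, segment_index, status, count
    fraction_post_onset: Dict[str, float]
    fraction_lunges_by_dominant: Optional[float]
    reversal_window_counts: List[Dict[str, int]]


def attribute_by_phase(
    events: EventTable,
    timeline: DominanceTimeline,
    reversal_window_s: float = 30.0,
) -> PhaseAttribution:
    """Tally events by actor within each dominance-status segment.

    Events are assigned to the segment containing their start time.
    ``fraction_lunges_by_dominant`` is computed over post-onset lunges
    with a single identified actor.
    """
    if timeline.classification == "never_established":
        raise ValueError("attribution requires an (eventually) established timeline")
    df = events.select(contest_id=timeline.contest_id or None)
    bad = set(df["fly"]) - {"A", "B", "both"}
    if bad:
        raise EventTableError(f"events by unknown fly ids {sorted(bad)}")

    partition = PhasePartition.from_timeline(timeline)
    rows = []
    for i, (s0, s1, status) in enumerate(partition.segments):
        in_seg = df[(df["start_s"] >= s0) & (df["start_s"] < s1)]
        for (fly, behavior), grp in in_seg.groupby(["fly", "behavior"]):
            rows.append(
                {
                    "fly": fly,
                    "behavior": behavior,
                    "segment_index": i,
                    "status": status,
                    "count": len(grp),
                }
            )
    counts = pd.DataFrame(
        rows, columns=["fly", "behavior", "segment_index", "status", "count"]
    )

    onset = timeline.onset_s
    frac_post: Dict[str, float] = {}
    for behavior in sorted(set(df["behavior"])):
        sub = df[df["behavior"] == behavior]
        n = len(sub)
        frac_post[behavior] = (
            float(np.count_nonzero(sub["start_s"] >= onset) / n) if n else float("nan")
        )

    lunges = df[(df["behavior"] == "lunge") & (df["fly"].isin(["A", "B"]))]
    post = lunges[lunges["start_s"] >= onset]
    if len(post):
        by_dom = sum(
            1
            for _, r in post.iterrows()
            if timeline.dominant_at(r["start_s"]) == r["fly"]
        )
        frac_by_dom: Optional[float] = by_dom / len(post)
    else:
        frac_by_dom = None

    rev_counts: List[Dict[str, int]] = []
    for rt, _ in timeline.reversals:
        lo, hi = rt - reversal_window_s, rt + reversal_window_s
        win = df[(df["start_s"] >= lo) & (df["start_s"] < hi)]
        rev_counts.append(win.groupby("behavior").size().to_dict())

    return PhaseAttribution(
        contest_id=timeline.contest_id,
        partition=partition,
        counts=counts,
        fraction_post_onset=frac_post,
        fraction_lunges_by_dominant=frac_by_dom,
        reversal_window_counts=rev_counts,
    )


# ---------------------------------------------------------------------------
# outcome tables and tests


OUTCOME_COLUMNS = [
    "pairing_label",
    "focal_genotype",
    "opponent_genotype",
    "focal_dominant",
    "focal_lunges",
    "opponent_lunges",
    "focal_lunged_pre_onset",
]


@dataclass
class OutcomeTable:
    """Per-contest outcome bookkeeping ('focal' is a label, not biology)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OUTCOME_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"outcome table missing columns: {missing}")
        if (self.df["focal_lunges"] < 0).any() or (self.df["opponent_lunges"] < 0).any():
            raise ValueError("lunge counts must be >= 0")

    def pairing(self, label: str) -> pd.DataFrame:
        return self.df[self.df["pairing_label"] == label].reset_index(drop=True)


def outcome_table_from_contests(
    contests: Sequence[SimulatedContest],
    timelines: Optional[Sequence[DominanceTimeline]] = None,
    pairing_label: str = "pairing",
    focal_fly: str = "A",
    focal_genotype: str = "focal",
    opponent_genotype: str = "opponent",
) -> OutcomeTable:
    """Build an outcome table from contests (truth or analyzed timelines).

    Only contests whose timeline is established contribute rows.
    """
    other = "B" if focal_fly == "A" else "A"
    rows = []
    tls = (
        list(timelines)
        if timelines is not None
        else [c.truth.to_timeline(c.contest_id) for c in contests]
    )
    for contest, tl in zip(contests, tls):
        if tl.classification != "established":
            continue
        ev = contest.truth.events
        lunges = ev.select(behavior="lunge")
        focal_lunges = int((lunges["fly"] == focal_fly).sum())
        opp_lunges = int((lunges["fly"] == other).sum())
        pre = lunges[lunges["start_s"] < tl.onset_s]
        rows.append(
            {
                "pairing_label": pairing_label,
                "focal_genotype": focal_genotype,
                "opponent_genotype": opponent_genotype,
                "focal_dominant": tl.dominant_at_onset == focal_fly
                if not tl.reversals
                else tl.reversals[-1][1] == focal_fly,
                "focal_lunges": focal_lunges,
                "opponent_lunges": opp_lunges,
                "focal_lunged_pre_onset": bool((pre["fly"] == focal_fly).any()),
            }
        )
    return OutcomeTable(pd.DataFrame(rows, columns=OUTCOME_COLUMNS))


@dataclass(frozen=True)
class OutcomeTestResult:
    pairing_label: str
    n_contests: int
    n_focal_dominant: int
    proportion: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_binomial: Optional[float]
    fisher_vs: Optional[str] = None
    p_fisher: Optional[float] = None
    insufficient_data: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def dominance_outcome_test(
    table: OutcomeTable,
    pairing_label: str,
    compare_with: Optional[str] = None,
) -> OutcomeTestResult:
    """Exact binomial test of focal wins against chance (0.5), optionally
    plus Fisher's exact comparison of two pairings' win counts."""
    sub = table.pairing(pairing_label)
    n = len(sub)
    if n == 0:
        return OutcomeTestResult(
            pairing_label=pairing_label,
            n_contests=0,
            n_focal_dominant=0,
            proportion=None,
            ci_low=None,
            ci_high=None,
            p_binomial=None,
            insufficient_data=True,
        )
    k = int(sub["focal_dominant"].sum())
    bt = sps.binomtest(k, n, 0.5, alternative="two-sided")
    ci = bt.proportion_ci(confidence_level=0.95, method="exact")
    p_fisher = None
    if compare_with is not None:
        other = table.pairing(compare_with)
        if len(other):
            k2 = int(other["focal_dominant"].sum())
            tab = [[k, n - k], [k2, len(other) - k2]]
            _, p_fisher = sps.fisher_exact(tab, alternative="two-sided")
            p_fisher = float(p_fisher)
    return OutcomeTestResult(
        pairing_label=pairing_label,
        n_contests=n,
        n_focal_dominant=k,
        proportion=k / n,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_binomial=float(bt.pvalue),
        fisher_vs=compare_with,
        p_fisher=p_fisher,
    )


@dataclass(frozen=True)
class GroupComparisonResult:
    test: str  # kruskal_wallis | rank_sum | sign_test
    statistic: Optional[float]
    p_value: Optional[float]
    group_medians: Dict[str, float]
    group_iqrs: Dict[str, Tuple[float, float]]
    insufficient_data: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_medians": self.group_medians,
            "group_iqrs": {k: list(v) for k, v in self.group_iqrs.items()},
            "insufficient_data": self.insufficient_data,
        }


def lunge_count_comparisons(
    groups: Dict[str, Sequence[float]],
    design: str = "independent",
) -> GroupComparisonResult:
    """Compare dominant-male lunge counts between groups.

    Two independent groups -> rank-sum; three or more -> tie-corrected
    Kruskal–Wallis; ``design='paired'`` (two equal-length groups) ->
    sign test on the paired differences.
    """
    medians = {}
    iqrs = {}
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size == 0:
            return GroupComparisonResult(
                test="none",
                statistic=None,
                p_value=None,
                group_medians={},
                group_iqrs={},
                insufficient_data=True,
            )
        medians[name] = float(np.median(arr))
        iqrs[name] = (float(np.percentile(arr, 25)), float(np.percentile(arr, 75)))
    arrays = [np.asarray(list(v), dtype=float) for v in groups.values()]
    if design == "paired":
        if len(arrays) != 2 or len(arrays[0]) != len(arrays[1]):
            raise ValueError("paired design needs two equal-length groups")
        d = arrays[0] - arrays[1]
        pos = int(np.sum(d > 0))
        neg = int(np.sum(d < 0))
        if pos + neg == 0:
            return GroupComparisonResult(
                "sign_test", 0.0, 1.0, medians, iqrs
            )
        bt = sps.binomtest(pos, pos + neg, 0.5, alternative="two-sided")
        return GroupComparisonResult(
            "sign_test", float(pos), float(bt.pvalue), medians, iqrs
        )
    if len(arrays) == 2:
        res: RankSumResult = rank_sum_test(arrays[0], arrays[1], "two-sided")
        return GroupComparisonResult(
            "rank_sum", res.rank_sum_x, res.p_value, medians, iqrs
        )
    if len(arrays) >= 3:
        if np.ptp(np.concatenate(arrays)) == 0:
            # identical values across all groups: H = 0 by definition
            return GroupComparisonResult("kruskal_wallis", 0.0, 1.0, medians, iqrs)
        h, p = sps.kruskal(*arrays)
        return GroupComparisonResult(
            "kruskal_wallis", float(h), float(p), medians, iqrs
        )
    raise ValueError("need at least two groups")


@dataclass(frozen=True)
class PrecociousLungeResult:
    """Cohort comparison of pre-onset lunging (naive vs winner-rematch)."""

    n_first: int
    n_rematch: int
    prop_first: float
    prop_rematch: float
    chi2: float
    p_chi2: float
    p_fisher: float
    low_expected_warning: bool
    # within-rematch: early lungers who won vs lost
    n_lunged_won: int
    n_lunged_lost: int
    chi2_within: Optional[float]
    p_within: Optional[float]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def precocious_lunge_analysis(
    first: OutcomeTable,
    rematch: OutcomeTable,
    yates: bool = False,
) -> PrecociousLungeResult:
    """Chi-square (df=1, no Yates correction by default) comparison of
    pre-onset-lunge proportions, with Fisher's exact alongside; plus the
    within-rematch won-vs-lost comparison among early-lunging focals."""
    a = int(first.df["focal_lunged_pre_onset"].sum())
    n1 = len(first.df)
    b = int(rematch.df["focal_lunged_pre_onset"].sum())
    n2 = len(rematch.df)
    tab = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if tab.sum() == 0 or n1 == 0 or n2 == 0:
        raise ValueError("both cohorts must be non-empty")
    expected = sps.contingency.expected_freq(tab)
    low = bool((expected < 1.0).any())
    if low:
        warnings.warn(
            "expected cell count below 1; prefer the Fisher exact p-value",
            stacklevel=2,
        )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        chi2, p_chi2 = 0.0, 1.0
    else:
        chi2, p_chi2, _, _ = sps.chi2_contingency(tab, correction=yates)
    _, p_fisher = sps.fisher_exact(tab.astype(int), alternative="two-sided")

    lunged = rematch.df[rematch.df["focal_lunged_pre_onset"]]
    won = int(lunged["focal_dominant"].sum())
    lost = len(lunged) - won
    if won + lost > 0:
        chi2_w = (won - lost) ** 2 / (won + lost)
        p_w = float(sps.chi2.sf(chi2_w, df=1))
    else:
        chi2_w, p_w = None, None
    return PrecociousLungeResult(
        n_first=n1,
        n_rematch=n2,
        prop_first=a / n1,
        prop_rematch=b / n2,
        chi2=float(chi2),
        p_chi2=float(p_chi2),
        p_fisher=float(p_fisher),
        low_expected_warning=low,
        n_lunged_won=won,
        n_lunged_lost=lost,
        chi2_within=chi2_w,
        p_within=p_w,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


class PipelineConfig(BaseModel):
    """Configuration of a full simulate/read -> analyze run."""

    sim: SimConfig = Field(default_factory=SimConfig)
    n_contests: int = 10
    event_source: str = "detectors"  # "detectors" | "truth"
    detector_params: DetectorParams = Field(default_factory=DetectorParams)
    behaviors: List[str] = Field(
        default_factory=lambda: ["fence", "box_tussle", "wing_flick", "lunge", "chase"]
    )
    windows_min: List[float] = Field(default_factory=lambda: [1.0, 5.0])
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineReport:
    config: PipelineConfig
    contests: List[SimulatedContest]
    events: EventTable
    timelines: List[DominanceTimeline]
    kept: List[DominanceTimeline]
    excluded: List[Tuple[DominanceTimeline, str]]
    paired_results: List[dict]
    attribution_summary: dict
    out_dir: Optional[Path] = None


def timeline_from_contest(
    contest: SimulatedContest,
    params: Optional[DetectorParams] = None,
    event_source: str = "detectors",
) -> Tuple[DominanceTimeline, EventTable]:
    """Events + dominance timeline for one contest.

    ``event_source='detectors'`` segments pursuit/chase/climb/lunge from
    the trajectory and takes the annotation-only acts (fence, box/tussle,
    wing flick) from the contest's event stream; ``'truth'`` uses the
    event stream for everything.
    """
    params = params or DetectorParams()
    truth_events = contest.truth.events
    duration = contest.trajectory.duration_s if contest.trajectory else (
        contest.truth.params_used.duration_s
    )
    if event_source == "detectors":
        bouts = detect_all(contest.trajectory, params)
        detected = bouts_to_events(bouts, contest.contest_id)
        manual = EventTable(
            truth_events.df[
                truth_events.df["behavior"].isin(["fence", "box_tussle", "wing_flick"])
            ]
        )
        events = detected.concat(manual).sorted()
    elif event_source == "truth":
        events = truth_events
    else:
        raise ValueError(f"unknown event_source {event_source!r}")

    pursuit_df = events.df[events.df["behavior"].isin(["pursuit", "chase"])]
    climb_df = events.df[events.df["behavior"] == "climb"]
    from .kinematics import Bout

    pursuits = [
        Bout(r["fly"], r["behavior"], r["start_s"], r["end_s"], 0.0,
             "B" if r["fly"] == "A" else "A")
        for _, r in pursuit_df.iterrows()
    ]
    climbs = [
        Bout(r["fly"], "climb", r["start_s"], r["end_s"], 0.0)
        for _, r in climb_df.iterrows()
    ]
    instances = find_diagnostic_instances(pursuits, climbs, params)
    tl = build_timeline(
        instances,
        duration_s=duration,
        params=params,
        contest_id=contest.contest_id,
    )
    return tl, events


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Simulate -> detect -> timelines -> exclusions -> peri-event -> outcomes."""
    contests = simulate_cohort(config.sim, config.n_contests)
    timelines: List[DominanceTimeline] = []
    all_events = EventTable.empty()
    for c in contests:
        tl, ev = timeline_from_contest(
            c, config.detector_params, config.event_source
        )
        timelines.append(tl)
        all_events = all_events.concat(ev)
    all_events = all_events.sorted()
    kept, excluded = apply_exclusions(timelines)

    paired_results = []
    for behavior in config.behaviors:
        for w in config.windows_min:
            res = paired_window_test(all_events, kept, behavior, w)
            paired_results.append(res.to_dict())

    attrib = {
        "fraction_lunges_post_onset": [],
        "fraction_lunges_by_dominant": [],
    }
    for tl in kept:
        at = attribute_by_phase(all_events, tl)
        fp = at.fraction_post_onset.get("lunge")
        if fp is not None and not np.isnan(fp):
            attrib["fraction_lunges_post_onset"].append(fp)
        if at.fraction_lunges_by_dominant is not None:
            attrib["fraction_lunges_by_dominant"].append(
                at.fraction_lunges_by_dominant
            )
    attribution_summary = {
        k: (float(np.mean(v)) if v else None) for k, v in attrib.items()
    }

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_events(all_events, out_dir / "events.csv")
        write_timelines(timelines, out_dir / "timelines.json")
        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump(
                [
                    {"contest_id": tl.contest_id, "reason": reason}
                    for tl, reason in excluded
                ],
                fh,
                indent=1,
            )
            fh.write("\n")
        for behavior in config.behaviors:
            if not kept:
                break
            m = align_and_bin(all_events, kept, behavior)
            m.to_frame().to_csv(out_dir / f"perievent_{behavior}.tsv", sep="\t")
            summarize(m).to_csv(
                out_dir / f"perievent_{behavior}_summary.tsv", sep="\t", index=False
            )
        with open(out_dir / "paired_tests.json", "w") as fh:
            json.dump(paired_results, fh, indent=1)
            fh.write("\n")
        with open(out_dir / "outcomes.json", "w") as fh:
            json.dump(attribution_summary, fh, indent=1)
            fh.write("\n")
        with open(out_dir / "run_log.jsonl", "w") as fh:
            log = {
                "n_contests": config.n_contests,
                "seed": config.sim.seed,
                "event_source": config.event_source,
                "n_kept": len(kept),
                "n_excluded": len(excluded),
                "exclusion_reasons": [r for _, r in excluded],
            }
            fh.write(json.dumps(log) + "\n")
    return PipelineReport(
        config=config,
        contests=contests,
        events=all_events,
        timelines=timelines,
        kept=kept,
        excluded=excluded,
        paired_results=paired_results,
        attribution_summary=attribution_summary,
        out_dir=out_dir,
    )
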