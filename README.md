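# flydom

Dominance-onset detection and peri-event analysis for dyadic contests
between male flies.

## What it does

In a small circular arena, pairs of male *Drosophila* escalate through a
stereotyped sequence of aggressive acts — fencing, boxing/tussling, wing
flicks, lunges, chases — until one male becomes dominant. Scoring any
one act as "aggression" conflates the acts that establish a hierarchy
with the acts that merely express it. `flydom` implements an onset
criterion that is independent of the scored acts: the **pursue-to-climb
sequence**, in which one male consistently pursues the other until the
retreating male leaves the floor by climbing the arena wall. The
pursuing male is classified dominant; later occurrences of the sequence
with roles swapped are reversals in status.

With onset (t = 0) defined, the package aligns each contest's ethogram
to it and provides the standard peri-event toolkit:

* per-frame kinematics and bout detectors (pursuit, chase, climb, lunge)
  from trajectory CSVs;
* dominance timelines — onset, reversals, per-instant status — with the
  standard exclusions (hierarchies formed before observation, or never);
* contest × 1-min-bin peri-event matrices (counts for point acts,
  fraction-of-time for state acts), median/IQR summaries, rasters;
* paired pre/post window comparisons by the two-sided Wilcoxon
  signed-rank test with an exact, tie-aware small-sample null
  (`min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))`, zeros dropped, mid-ranks);
* outcome statistics: status-conditioned lunge attribution, exact
  binomial tests of dominance against chance, Fisher/Kruskal–Wallis/
  rank-sum/sign comparisons of lunge counts, and chi-square analyses of
  precocious (pre-onset) lunging in winner-rematch designs;
* a ground-truth contest simulator (trajectories + event streams +
  true timelines) so every stage is testable without video data.

It is aimed at researchers quantifying social dominance in fly (or
other dyadic) contests who have tracking output and/or behavioral
annotations and want an explicit, falsifiable hierarchy criterion
rather than a proxy act.

## Worked example

Simulate a cohort, build timelines through the detectors, and run the
5-minute paired comparison for two acts:

```python
from flydom import (SimConfig, simulate_cohort, timeline_from_contest,
                    apply_exclusions, paired_window_test)
from flydom.ethogram_io import EventTable

cfg = SimConfig(seed=5)            # 20-min contests, 30 fps, 16-mm arena
contests = simulate_cohort(cfg, 20)

timelines, events = [], EventTable.empty()
for c in contests:
    tl, ev = timeline_from_contest(c)   # detect bouts -> pursue-to-climb
    timelines.append(tl)
    events = events.concat(ev)

kept, excluded = apply_exclusions(timelines)
print(f"{len(kept)} established, {len(excluded)} excluded")
for behavior in ("fence", "lunge"):
    r = paired_window_test(events, kept, behavior, window_min=5.0)
    print(f"{behavior:6s} n={r.n_pairs} p={r.p_two_sided:.2e} "
          f"{r.direction} {r.stars}")
```

Output:

```
18 established, 2 excluded
fence  n=14 p=1.22e-04 pre_greater ***
lunge  n=14 p=1.22e-04 post_greater ***
```

Two of the twenty contests are excluded (here: one hierarchy never
formed, one was already formed when observation started). Among the
established contests with full ±5-min windows (n = 14), fencing
occupies significantly more time before onset than after
(`pre_greater`), while lunging is essentially confined to the
post-onset period (`post_greater`) — the signature that motivates
treating lunges as an expression of dominance rather than its cause.

The same stages are available from the shell:

```bash
flydom sim --n 50 --seed 7 --out runs/sim
flydom detect --traj runs/sim/contest_000_traj.csv --out events.csv
flydom dominance --events events.csv --out timeline.json
flydom perievent --events events.csv --timelines timeline.json \
    --behavior lunge --window 5 --out runs/peri
flydom pipeline --config run.yaml
```

## File formats

* trajectory CSV: `frame,fly,x_mm,y_mm,heading_deg[,on_wall]` —
  arena-centered mm, 0-based frames, fly ∈ {A, B};
* events CSV: `contest_id,fly,behavior,start_s,end_s` — behaviors from
  {fence, wing_flick, box_tussle, lunge, chase, pursuit, climb},
  half-open intervals, point acts may have `start_s == end_s`;
* timelines: JSON (`contest_id, classification, onset_s,
  dominant_at_onset, reversals`).

Fence, box/tussle and wing flick have no 2-D trajectory signature and
are consumed from annotation files (or simulator truth); the detectors
cover pursuit, chase, climb and lunge. See `docs/methods.md` for every
definition, threshold and design choice.

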