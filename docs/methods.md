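# Methods

## The problem

When two male flies are confined in a small circular arena over food,
they escalate through a reproducible sequence of aggressive acts until
one of them becomes socially dominant. Most aggression assays score a
single act (usually the lunge) as a proxy for dominance, which conflates
the acts that *establish* a hierarchy with the acts that *express* it.
`flydom` implements an onset criterion that is independent of the scored
acts — the pursue-to-climb sequence — and the peri-onset analyses that
this independence makes possible.

## The pursue-to-climb criterion

Operational definitions, all on 2-D top-down trajectories:

* **pursuit** — a maximal run of frames in which one fly (the actor) is
  within `pursuit_d_max_mm` (5 mm) of the other, moving at
  `pursuit_v_min_mm_s` (3 mm/s) or faster, with its heading within
  `pursuit_theta_max_deg` (45°) of the direction to the opponent, and not
  on the wall. Gaps up to `pursuit_gap_max_s` (0.2 s) are merged, runs
  shorter than `pursuit_t_min_s` (1 s) are dropped. The order
  mask → merge → duration-filter is fixed so the segmentation is
  deterministic and oracle-checkable.
* **chase** — a pursuit-shaped bout at least `chase_min_s` (5 s) long
  with mean speed at least `chase_v_min_mm_s` (10 mm/s). Chases are
  re-labeled out of the pursuit list, so the two classes partition the
  trailing bouts.
* **climb** — a maximal run of wall occupancy lasting at least
  `climb_min_s` (0.5 s). Because top-down video cannot see height,
  "leaves the floor" is encoded as radial position at or beyond
  `wall_fraction` (0.95) of the arena radius; an explicit `on_wall`
  column in the trajectory file overrides the radial proxy.
* **diagnostic instance** — a climb by fly X starting during, or within
  `link_max_s` (2 s) after, a pursuit whose actor is the other fly Y.
  The instance is stamped at the climb start; Y is the pursuer.

The first instance marks dominance onset (pursuer = dominant). A later
instance whose pursuer is the current subordinate is a reversal that
transfers status; instances confirming the current dominant change
nothing. Contests with no instance are `never_established`; contests
whose first diagnostic pursuit was already running at the first observed
frame are `pre_established`. Both classes are excluded from peri-onset
analyses with machine-readable reasons. "Consistently pursues" is
operationalized as one duration-filtered pursuit bout linked to a climb;
a `k_confirm` knob can require k instances by the same pursuer before
onset (default 1, keeping the criterion explicit and falsifiable).
Because detected bout starts are quantized to the frame grid, a pursuit
starting within `pre_established_tol_s` (0.1 s) of observation start
counts as "in progress at start". Simultaneous opposite-role instances
at the same timestamp are resolved in favor of the earlier-starting
pursuit and logged.

None of these thresholds comes from a printed value; the acts are
defined verbally in the literature and scored by hand or by machine
vision. The defaults are plausible fly scales (walking below ~8 mm/s,
pursuit around 10 mm/s, chases faster and longer than pursuits) and all
of them are configuration.

## Lunge detection

A lunge is a point event: forward displacement of at least
`lunge_disp_min_mm` (1.5 mm) within `lunge_window_s` (0.1 s), starting
within `lunge_d_max_mm` (3 mm) of the opponent and aimed within 30° of
it; candidates within `lunge_refractory_s` (0.3 s) merge into the first.
Fence, box/tussle and wing flick have no signature a 2-D track resolves;
the pipeline consumes them from annotation files (or simulator truth),
mirroring how such acts are manually scored in practice.

## Peri-event analysis

Events are aligned to the initial onset (time 0) and binned into 60-s
half-open bins. Point acts (lunge, wing flick) are counted per bin;
state acts (fence, box/tussle, chase, pursuit, climb) contribute the
fraction of bin time occupied. A bin counts for a contest only when the
recording fully covers it. Cohort summaries are per-bin medians with
interquartile ranges; quartiles use linear interpolation between order
statistics (a convention had to be fixed for testability). Bins with
fewer than `min_n` (5) contests are flagged. Post-reversal periods are
not re-aligned; status-conditioned attribution lives in the outcomes
module.

Paired pre/post comparisons aggregate the same measure over `[-w, 0)`
and `[0, w)` (w = 1 or 5 min) and apply the two-sided Wilcoxon
signed-rank test. Zero differences are dropped before ranking, ties get
mid-ranks, and the null distribution is computed exactly (dynamic
programming over doubled mid-ranks) for up to 25 pairs, switching to a
normal approximation with tie correction and 0.5 continuity correction
above. The two-sided p is `min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))`. Contests
lacking a full window are dropped from that test only, with the per-test
n reported. No multiple-testing correction is applied across behaviors
(the per-behavior stars convention); this is flagged in the result
metadata by reporting each behavior separately.

The rank-sum test for two independent groups uses the analogous exact
subset-enumeration null (DP) for combined n up to 30. Exact binomial,
Fisher's exact, Kruskal–Wallis (tie-corrected) and chi-square tests are
delegated to scipy. Tests degrade to explicit insufficient-data results,
not exceptions, when groups are empty or pairs are fewer than two.

## Outcome analyses

* **Phase attribution**: the dominance timeline tiles the contest into
  unestablished / A-dominant / B-dominant segments; events are assigned
  to segments by start time. Derived summaries: fraction of each act
  post-onset, fraction of post-onset lunges by the instantaneous
  dominant, and counts in ±30 s windows around each reversal (the
  window is configuration; "near each reversal" has no printed width).
* **Dominance outcomes**: the chance-level test is the exact binomial
  against 0.5 (chosen over an unstated approximation), with a
  Clopper–Pearson interval; two pairings are compared by Fisher's exact
  test on the 2×2 win table.
* **Precocious lunging**: pre-onset-lunge proportions of a naive cohort
  and a winner-rematch cohort are compared by chi-square (df = 1, no
  Yates correction by default; a flag enables it), with Fisher's exact
  p reported alongside and a warning when an expected cell drops below
  1. The within-rematch comparison (early lungers who won vs lost) is a
  df-1 goodness-of-fit chi-square against an even split.

## The contest simulator

The simulator exists so that every stage is testable against known
ground truth; no public data accompany the observations it emulates.
It generates 20-min, 30 frames/s contests in a 16-mm-diameter arena.

**Timeline.** A contest is `never_established` (p = 0.05),
`pre_established` (p = 0.1) or `established`. Onset latency is
log-normal (median 420 s, shape 0.5), truncated to [120, 840] s so that
peri-onset windows of up to 5 min exist inside the recording for most
contests; the observed latencies span the recording without a printed
distribution, so these are package choices. Reversals occur in 20% of
established contests ("one in five"); given reversals, their number is
geometric (p = 0.6) and times are spaced at least 90 s apart.

**Acts.** Per-behavior rates are piecewise-linear functions of time
relative to onset, chosen to encode the qualitative temporal structure
and nothing more (no rates are printed anywhere): fence is a pre-onset
plateau (3 bouts/min) dropping at onset; box/tussle ramps from zero 240 s
before onset to a peak at onset (6/min) then collapses; wing flick steps
from 1/min to 6/min at onset; lunge ramps from zero at onset to 10/min
by +300 s, with each lunge executed by the instantaneous dominant with
probability `lunge_dominant_fraction` (0.9); chase is absent before
onset + 90 s and ramps to 1.2/min. State-act bout durations are
gamma(2)-distributed around their means, which keeps occupied-time
fractions continuous (this matters for the exactness of the signed-rank
calibration). A `SimConfig.null()` factory holds every rate constant in
time — the phase-independent null used for type-I calibration.

**Trajectories.** Base motion is a correlated random walk per fly with a
soft pull toward the center near the boundary and reflection at 0.95 of
the arena radius. Scripted blocks overlay the walk: pre-onset
alternating pursuit bouts (which never culminate in climbs — the target
is steered inward afterwards), the diagnostic pursue-to-climb sequence at
onset and at each reversal (pursuer trails at ~10 mm/s; the target flees
and then dashes to the wall, reaching it within `climb_latency_s` of the
pursuit end, and holds the wall with `on_wall` set), post-onset chases
(~12.5 mm/s, 5.5–9 s) and lunges (a 2.5-s approach to ~2.3 mm followed by
a 3-frame 24 mm/s thrust). Scripted blocks are scheduled with a 3.5-s
margin around diagnostic sequences so that only diagnostic pursuits can
link to climbs. Walk and controller speeds are capped so that no
non-lunge motion crosses the lunge displacement threshold.

Everything is reproducible from `(config, seed)`; cohort members use
seeds derived via `SeedSequence(seed, spawn_key=(index,))` — the
canonical independent-stream derivation (hashing the index into the
entropy words instead leaves measurable cross-stream structure that
distorts calibration experiments).

**What the simulator does not emulate.** Real tracking noise, identity
swaps, occlusions during tussles, wall-hugging exploration, genuine
behavioral variability in act shapes, or any physiological state beyond
rate parameters. Passing recovery tests therefore shows that the
pipeline's logic is correct under the stated generative assumptions —
not that the default thresholds are well calibrated for any particular
real tracking setup, which is why every threshold is exposed in
configuration.

## Problem sizes and numerical choices

The recovery experiments use cohorts of 30–100 full contests and the
calibration experiment 500 events-only cohorts of 20 contests; these
sizes give binomial confidence bands tight enough to be informative
while keeping a complete run of the suite and the acceptance script in
the minutes range on one core. Exact-test enumeration oracles sweep all
inputs up to n = 10. Floating-point output is rounded to 1 µm / 10⁻⁴
degree in trajectory files, which round-trips exactly through CSV.
Half-open intervals `[start, end)` and 0-based frames make bin and
segment assignment unambiguous at boundaries.

## Known limitations

* The pursuit/chase boundary (5 s, 10 mm/s) is a declared convention;
  the literature says only "longer" and "high-speed".
* Fence, box/tussle and wing flick cannot be detected from trajectories
  here; analyses involving them require annotation files.
* The pre-established class is identified from a pursuit in progress at
  the first observed frame; hierarchies formed entirely before recording
  with no residual pursuit are indistinguishable from established-late
  contests.
* Group (>2 fly) hierarchies and escalation dynamics through repeated
  reversals are out of scope.
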