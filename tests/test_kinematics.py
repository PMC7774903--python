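import math

import numpy as np
import pandas as pd
import pytest

from flydom.ethogram_io import ArenaGeometry, Trajectory
from flydom.kinematics import (
    Bout,
    DetectorParams,
    compute_features,
    detect_all,
    detect_chase,
    detect_climb,
    detect_lunge,
    detect_pursuit,
    pursuit_frame_mask,
)

FPS = 30.0


def make_traj(pos_a, pos_b, head_a=None, head_b=None, on_wall=None):
    """Build a trajectory from per-frame position arrays (n, 2)."""
    pos_a = np.asarray(pos_a, float)
    pos_b = np.asarray(pos_b, float)
    n = len(pos_a)

    def headings(p, given):
        if given is not None:
            return np.asarray(given, float) % 360.0
        d = np.diff(p, axis=0, append=p[-1:] + (p[-1:] - p[-2:-1]))
        return np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0

    ha, hb = headings(pos_a, head_a), headings(pos_b, head_b)
    rows = []
    for f in range(n):
        rows.append(
            {"frame": f, "fly": "A", "x_mm": pos_a[f, 0], "y_mm": pos_a[f, 1],
             "heading_deg": ha[f]}
        )
        rows.append(
            {"frame": f, "fly": "B", "x_mm": pos_b[f, 0], "y_mm": pos_b[f, 1],
             "heading_deg": hb[f]}
        )
    df = pd.DataFrame(rows)
    if on_wall is not None:
        df["on_wall"] = [on_wall[r["fly"]][r["frame"]] for _, r in df.iterrows()]
    return Trajectory(df, fps=FPS)


def circular_follow(duration_s=3.0, speed=10.0, gap=2.0, lead_s=1.0, r=5.0):
    """B walks a circle of radius ``r``; A trails ``gap`` mm behind on it.

    A stationary, far-apart lead-in/out bounds the bout.  On the circle
    the pursuer's bearing error is ~half the chord angle (about 12 deg
    here), well inside the detector's cone.
    """
    n_follow = int(duration_s * FPS)
    n_pad = int(lead_s * FPS)
    omega = speed / r  # rad/s
    lag = gap / r

    def on_circle(theta):
        return (r * math.cos(theta), r * math.sin(theta))

    thetas_b = [omega * i / FPS for i in range(n_follow)]
    pos_b = [on_circle(t) for t in thetas_b]
    pos_a = [on_circle(t - lag) for t in thetas_b]
    head_b = [math.degrees(t + math.pi / 2) for t in thetas_b]
    head_a = [math.degrees(t - lag + math.pi / 2) for t in thetas_b]
    # stationary pads at the endpoints: the speed criterion bounds the
    # bout without position jumps that would contaminate speed estimates
    pre_b = [pos_b[0]] * n_pad
    pre_a = [pos_a[0]] * n_pad
    post_b = [pos_b[-1]] * n_pad
    post_a = [pos_a[-1]] * n_pad
    heads_a = [0.0] * n_pad + head_a + [0.0] * n_pad
    heads_b = [0.0] * n_pad + head_b + [0.0] * n_pad
    return (
        make_traj(
            pre_a + pos_a + post_a,
            pre_b + pos_b + post_b,
            head_a=heads_a,
            head_b=heads_b,
        ),
        n_pad / FPS,
        (n_pad + n_follow) / FPS,
    )


class TestFeatures:
    def test_stationary_fly_at_center_has_zero_speed_and_radius(self):
        n = 10
        traj = make_traj([(0.0, 0.0)] * n, [(3.0, 0.0)] * n)
        f = compute_features(traj)
        assert np.allclose(f.speed_mm_s["A"], 0.0)
        assert np.allclose(f.radial_fraction["A"], 0.0)

    def test_wall_threshold_arithmetic(self):
        n = 20
        traj = make_traj([(7.8, 0.0)] * n, [(0.0, 0.0)] * n)
        f = compute_features(traj, ArenaGeometry(radius_mm=8.0, wall_fraction=0.95))
        assert f.on_wall["A"].all()  # 7.8/8 = 0.975 >= 0.95
        assert not f.on_wall["B"].any()

    def test_explicit_on_wall_flag_overrides_radial_proxy(self):
        n = 20
        flags = {"A": [False] * n, "B": [False] * n}
        traj = make_traj([(7.8, 0.0)] * n, [(0.0, 0.0)] * n, on_wall=flags)
        f = compute_features(traj)
        assert not f.on_wall["A"].any()

    def test_bearing_error_range(self, sim_contest):
        f = compute_features(sim_contest.trajectory)
        for fly in ("A", "B"):
            assert (f.bearing_error_deg[fly] >= 0).all()
            assert (f.bearing_error_deg[fly] <= 180).all()


class TestPursuitDetector:
    def test_far_apart_flies_yield_nothing(self):
        n = 60
        pos_a = [(-6.0 + 0.1 * i / FPS, 0.0) for i in range(n)]
        pos_b = [(6.0, 0.0)] * n
        assert detect_pursuit(compute_features(make_traj(pos_a, pos_b))) == []

    def test_circular_follow_yields_one_spanning_bout(self):
        traj, t0, t1 = circular_follow()
        bouts = detect_pursuit(compute_features(traj))
        assert len(bouts) == 1
        b = bouts[0]
        assert b.fly == "A" and b.target_fly == "B"
        assert b.start_s == pytest.approx(t0, abs=0.1)
        assert b.end_s == pytest.approx(t1, abs=0.1)
        assert b.mean_speed_mm_s == pytest.approx(10.0, rel=0.1)

    def test_short_run_discarded_by_min_duration(self):
        traj, _, _ = circular_follow(duration_s=0.5)
        assert detect_pursuit(compute_features(traj)) == []

    def test_mask_monotone_in_distance_and_speed_thresholds(self, sim_contest):
        f = compute_features(sim_contest.trajectory)
        base = DetectorParams()
        wide = DetectorParams(pursuit_d_max_mm=7.0, pursuit_v_min_mm_s=2.0)
        for fly in ("A", "B"):
            m0 = pursuit_frame_mask(f, fly, base)
            m1 = pursuit_frame_mask(f, fly, wide)
            assert not np.any(m0 & ~m1)  # widened thresholds give a superset


class TestChaseRelabeling:
    def _bout(self, dur, speed):
        return Bout("A", "pursuit", 10.0, 10.0 + dur, speed, "B")

    @pytest.mark.parametrize(
        "dur,speed,expected",
        [
            (3.0, 20.0, "pursuit"),  # fails duration
            (8.0, 12.0, "chase"),
            (8.0, 5.0, "pursuit"),  # fails speed
            (5.0, 10.0, "chase"),  # thresholds are inclusive
        ],
    )
    def test_threshold_logic(self, dur, speed, expected):
        out = detect_chase([self._bout(dur, speed)])
        assert [b.kind for b in out] == [expected]

    def test_partition_is_exhaustive_and_exclusive(self, sim_contest):
        f = compute_features(sim_contest.trajectory)
        pursuits = detect_pursuit(f)
        relabeled = detect_chase(pursuits)
        assert len(relabeled) == len(pursuits)
        assert {(b.start_s, b.fly) for b in relabeled} == {
            (b.start_s, b.fly) for b in pursuits
        }

    def test_empty_input(self):
        assert detect_chase([]) == []


class TestClimbDetector:
    def test_fly_never_on_wall_yields_nothing(self):
        n = 60
        traj = make_traj([(0.0, 0.0)] * n, [(3.0, 0.0)] * n)
        assert detect_climb(compute_features(traj)) == []

    def test_single_frame_touch_rejected(self):
        n = 60
        pos_a = [(0.0, 0.0)] * n
        pos_a[30] = (7.9, 0.0)
        traj = make_traj(pos_a, [(3.0, 0.0)] * n)
        assert detect_climb(compute_features(traj)) == []

    def test_scripted_climbs_matched_one_to_one(self, sim_contest):
        bouts = detect_climb(compute_features(sim_contest.trajectory))
        true_climbs = sim_contest.truth.events.select(behavior="climb")
        assert len(bouts) == len(true_climbs)
        for (_, r), b in zip(true_climbs.iterrows(), bouts):
            assert b.fly == r["fly"]
            assert b.start_s == pytest.approx(r["start_s"], abs=0.5)


class TestLungeDetector:
    def test_stationary_pair_yields_nothing(self):
        n = 60
        traj = make_traj([(0.0, 0.0)] * n, [(2.0, 0.0)] * n)
        assert detect_lunge(compute_features(traj)) == []

    def test_two_crossings_within_refractory_merge(self):
        # A thrusts at B twice, 0.1 s apart: one event reported
        n = 90
        pos_a = [(0.0, 0.0)] * n
        pos_b = [(2.5, 0.0)] * n
        for j, f0 in enumerate([30, 33]):
            for i in range(3):
                pos_a[f0 + i] = (pos_a[f0 - 1][0] + 0.8 * (i + 1), 0.0)
            for i in range(f0 + 3, n):
                pos_a[i] = pos_a[f0 + 2]
            pos_b = [(pos_a[i][0] + 2.5, 0.0) for i in range(n)]
        traj = make_traj(pos_a, pos_b, head_a=[0.0] * n, head_b=[0.0] * n)
        events = detect_lunge(compute_features(traj))
        assert len([e for e in events if e.fly == "A"]) == 1

    def test_scripted_lunges_recovered_with_high_precision_and_recall(
        self, established_config
    ):
        from flydom import derived_seed, simulate_contest

        tp = fp = fn = 0
        for i in range(2):
            c = simulate_contest(established_config, derived_seed(555, i))
            det = sorted(
                b.start_s for b in detect_all(c.trajectory) if b.kind == "lunge"
            )
            true = sorted(c.truth.events.select(behavior="lunge")["start_s"])
            used = set()
            for t in true:
                hit = [
                    j for j, d in enumerate(det) if abs(d - t) <= 0.2 and j not in used
                ]
                if hit:
                    used.add(hit[0])
                    tp += 1
                else:
                    fn += 1
            fp += len(det) - len(used)
        assert tp / (tp + fn) >= 0.9
        assert tp / (tp + fp) >= 0.9


@pytest.fixture(scope="module")
def short_contest():
    from flydom import SimConfig, simulate_contest

    cfg = SimConfig(
        duration_s=300.0,
        onset_median_s=120.0,
        onset_min_s=60.0,
        onset_max_s=200.0,
        p_pre_established=0.0,
        p_never_established=0.0,
        seed=91,
    )
    return simulate_contest(cfg, 91)


class TestGeometricInvariance:
    def _signature(self, bouts):
        return sorted((b.kind, b.fly, round(b.start_s, 4), round(b.end_s, 4))
                      for b in bouts)

    def test_rotation_invariance(self, short_contest):
        traj = short_contest.trajectory
        theta = 73.0
        rad = math.radians(theta)
        df = traj.df.copy()
        x, y = df["x_mm"].to_numpy(), df["y_mm"].to_numpy()
        df["x_mm"] = x * math.cos(rad) - y * math.sin(rad)
        df["y_mm"] = x * math.sin(rad) + y * math.cos(rad)
        df["heading_deg"] = (df["heading_deg"] + theta) % 360.0
        rotated = Trajectory(df, fps=traj.fps, geometry=traj.geometry)
        assert self._signature(detect_all(rotated)) == self._signature(
            detect_all(traj)
        )

    def test_fly_label_swap_swaps_actors(self, short_contest):
        traj = short_contest.trajectory
        df = traj.df.copy()
        df["fly"] = df["fly"].map({"A": "B", "B": "A"})
        df = df.sort_values(["frame", "fly"], kind="mergesort")
        swapped = Trajectory(df, fps=traj.fps, geometry=traj.geometry)
        orig = self._signature(detect_all(traj))
        swap = {"A": "B", "B": "A"}
        expected = sorted((k, swap[f], s, e) for k, f, s, e in orig)
        assert self._signature(detect_all(swapped)) == expected


def test_scripted_pursuits_overlap_detected_bouts(sim_contest):
    # every scripted pursuit bout is covered >= 80% by exactly one
    # detected trailing bout by the same actor
    det = [
        b for b in detect_all(sim_contest.trajectory) if b.kind in ("pursuit", "chase")
    ]
    true = sim_contest.truth.events.select(behavior="pursuit")
    assert len(true) > 0
    for _, r in true.iterrows():
        dur = r["end_s"] - r["start_s"]
        n_cover = sum(
            1
            for b in det
            if b.fly == r["fly"]
            and min(b.end_s, r["end_s"]) - max(b.start_s, r["start_s"]) >= 0.8 * dur
        )
        assert n_cover == 1


def test_pursuer_bearing_error_low_during_scripted_bouts(sim_contest):
    f = compute_features(sim_contest.trajectory)
    true = sim_contest.truth.events.select(behavior="pursuit")
    for _, r in true.iterrows():
        i0 = int(r["start_s"] * FPS)
        i1 = int(r["end_s"] * FPS)
        med = np.median(f.bearing_error_deg[r["fly"]][i0:i1])
        assert med < 45.0


def test_detector_params_reject_nonpositive_thresholds():
    with pytest.raises(ValueError):
        DetectorParams(pursuit_d_max_mm=0.0)
    with pytest.raises(ValueError):
        DetectorParams(chase_min_s=-1.0)
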