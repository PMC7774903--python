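import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flydom import (
    SimConfig,
    derived_seed,
    simulate_contest,
    simulate_truth,
    winner_rematch,
)
from flydom.dominance import DominanceTimeline
from flydom.ethogram_io import EventTable
from flydom.outcomes import (
    OutcomeTable,
    PhasePartition,
    attribute_by_phase,
    dominance_outcome_test,
    lunge_count_comparisons,
    outcome_table_from_contests,
    precocious_lunge_analysis,
)


def make_timeline(cid="c0", onset=300.0, duration=1200.0, reversals=()):
    return DominanceTimeline(
        contest_id=cid,
        classification="established",
        onset_s=onset,
        dominant_at_onset="A",
        reversals=list(reversals),
        duration_s=duration,
    )


def outcome_df(rows):
    return OutcomeTable(
        pd.DataFrame(
            rows,
            columns=[
                "pairing_label",
                "focal_genotype",
                "opponent_genotype",
                "focal_dominant",
                "focal_lunges",
                "opponent_lunges",
                "focal_lunged_pre_onset",
            ],
        )
    )


class TestPhaseAttribution:
    def test_partition_tiles_contest(self):
        tl = make_timeline(reversals=[(600.0, "B"), (900.0, "A")])
        part = PhasePartition.from_timeline(tl)
        assert part.segments[0][0] == 0.0
        assert part.segments[-1][1] == 1200.0
        for (_, a1, s0), (b0, _, s1) in zip(part.segments, part.segments[1:]):
            assert a1 == b0 and s0 != s1

    def test_all_post_onset_lunges_by_sole_dominant(self):
        tl = make_timeline()
        ev = EventTable.from_rows(
            [("c0", "A", "lunge", 400.0 + 10 * k, 400.0 + 10 * k) for k in range(5)]
        )
        at = attribute_by_phase(ev, tl)
        assert at.fraction_lunges_by_dominant == 1.0
        assert at.fraction_post_onset["lunge"] == 1.0

    def test_segment_counts_sum_to_contest_totals(self):
        tl = make_timeline(reversals=[(600.0, "B")])
        rows = [
            ("c0", "A", "lunge", t, t)
            for t in (100.0, 350.0, 650.0, 700.0, 1100.0)
        ] + [("c0", "both", "fence", 50.0, 55.0), ("c0", "B", "lunge", 800.0, 800.0)]
        at = attribute_by_phase(EventTable.from_rows(rows), tl)
        totals = at.counts.groupby("behavior")["count"].sum()
        assert totals["lunge"] == 6
        assert totals["fence"] == 1

    def test_reversal_window_counts(self):
        tl = make_timeline(reversals=[(600.0, "B")])
        rows = [
            ("c0", "A", "lunge", 580.0, 580.0),
            ("c0", "B", "lunge", 615.0, 615.0),
            ("c0", "A", "lunge", 700.0, 700.0),  # outside the +/-30 s window
        ]
        at = attribute_by_phase(EventTable.from_rows(rows), tl)
        assert at.reversal_window_counts == [{"lunge": 2}]

    def test_pooled_dominant_fraction_tracks_generative_parameter(self):
        # lunge_dominant_fraction=0.9: pooled fraction of post-onset
        # lunges executed by the instantaneous dominant within the
        # binomial band around 0.9
        cfg = SimConfig(
            p_pre_established=0.0, p_never_established=0.0, seed=31,
            lunge_dominant_fraction=0.9,
        )
        by_dom = total = 0
        for i in range(30):
            t = simulate_truth(cfg, derived_seed(31, i), f"c{i}")
            tl = t.to_timeline(f"c{i}")
            at = attribute_by_phase(t.events, tl)
            lunges = t.events.select(behavior="lunge")
            post = lunges[lunges["start_s"] >= t.onset_s]
            total += len(post)
            if at.fraction_lunges_by_dominant is not None:
                by_dom += round(at.fraction_lunges_by_dominant * len(post))
        lo = sps.binom.ppf(0.025, total, 0.9)
        hi = sps.binom.ppf(0.975, total, 0.9)
        assert lo <= by_dom <= hi


class TestDominanceOutcomeTest:
    def test_even_split_gives_p_one(self):
        rows = [("p", "g", "g", i < 5, 0, 0, False) for i in range(10)]
        res = dominance_outcome_test(outcome_df(rows), "p")
        assert res.p_binomial == 1.0
        assert res.proportion == 0.5

    def test_fisher_matches_hypergeometric_enumeration(self):
        # [[10,0],[5,5]]: enumerate all tables with the same margins
        rows = [("a", "g", "g", True, 0, 0, False) for _ in range(10)]
        rows += [("b", "g", "g", i < 5, 0, 0, False) for i in range(10)]
        res = dominance_outcome_test(outcome_df(rows), "a", compare_with="b")

        def hypergeom_p(table):
            (a, b), (c, d) = table
            n = a + b + c + d
            p_obs = (
                math.comb(a + b, a) * math.comb(c + d, c) / math.comb(n, a + c)
            )
            total = 0.0
            for aa in range(0, min(a + b, a + c) + 1):
                cc = a + c - aa
                if cc < 0 or cc > c + d:
                    continue
                p = (
                    math.comb(a + b, aa)
                    * math.comb(c + d, cc)
                    / math.comb(n, a + c)
                )
                if p <= p_obs * (1 + 1e-9):
                    total += p
            return total

        assert res.p_fisher == pytest.approx(hypergeom_p([[10, 0], [5, 5]]))

    def test_empty_pairing_reports_insufficient_data(self):
        res = dominance_outcome_test(outcome_df([]), "missing")
        assert res.insufficient_data

    def test_coin_flip_calibration(self):
        # fair-coin dominance: the exact binomial test at alpha=0.05 with
        # n=20 rejects at its achievable level (2*P(X<=5) ~ 0.041);
        # observed rejection rate must sit in that level's binomial band
        rng = np.random.default_rng(77)
        n_pairings, n_contests = 200, 20
        rejections = 0
        for _ in range(n_pairings):
            wins = rng.integers(0, 2, size=n_contests).sum()
            p = sps.binomtest(int(wins), n_contests, 0.5).pvalue
            if p <= 0.05:
                rejections += 1
        level = 2 * sps.binom.cdf(5, 20, 0.5)
        lo = sps.binom.ppf(0.025, n_pairings, level)
        hi = sps.binom.ppf(0.975, n_pairings, level)
        assert lo <= rejections <= hi


class TestLungeCountComparisons:
    def test_identical_groups_give_zero_kruskal_statistic(self):
        res = lunge_count_comparisons(
            {"a": [3, 3, 3], "b": [3, 3, 3], "c": [3, 3, 3]}
        )
        assert res.test == "kruskal_wallis"
        assert res.statistic == 0.0

    def test_two_groups_use_exact_rank_sum(self):
        res = lunge_count_comparisons({"lo": [1, 2, 3], "hi": [4, 5, 6]})
        assert res.test == "rank_sum"
        assert res.p_value == pytest.approx(2 / 20)  # two-sided of 1/20

    def test_paired_design_uses_sign_test(self):
        res = lunge_count_comparisons(
            {"first": [5, 6, 7, 8], "second": [1, 2, 3, 4]}, design="paired"
        )
        assert res.test == "sign_test"
        assert res.p_value == pytest.approx(2 / 16)

    def test_empty_group_reports_insufficient_data(self):
        res = lunge_count_comparisons({"a": [1.0], "b": []})
        assert res.insufficient_data

    def test_simulated_genotype_rate_ratio_detected(self):
        # high- vs low-lunging lines (rate ratio 5): dominant-male lunge
        # counts differ in the generated direction at n=20 per group
        def dominant_lunges(cfg, tag, n=20):
            out = []
            for i in range(n):
                t = simulate_truth(cfg, derived_seed(tag, i))
                lunges = t.events.select(behavior="lunge")
                out.append(int((lunges["fly"] == t.dominant_id).sum()))
            return out

        base = dict(p_pre_established=0.0, p_never_established=0.0, p_reversal=0.0)
        hi_cfg = SimConfig(seed=61, **base)
        profiles = hi_cfg.act_rate_profiles
        lo_profiles = dict(profiles)
        from flydom.contest_sim import RateProfile

        lo_profiles["lunge"] = RateProfile(
            breakpoints=[(0.0, 0.0), (300.0, 2.0)], kind="point"
        )
        lo_cfg = SimConfig(seed=62, act_rate_profiles=lo_profiles, **base)
        hi = dominant_lunges(hi_cfg, 61)
        lo = dominant_lunges(lo_cfg, 62)
        res = lunge_count_comparisons({"high": hi, "low": lo})
        assert res.group_medians["high"] > res.group_medians["low"]
        assert res.p_value < 0.05


class TestPrecociousLunge:
    def test_identical_proportions_give_zero_chi2(self):
        rows_a = [("p", "g", "g", True, 1, 0, i < 5) for i in range(10)]
        rows_b = [("p", "g", "g", True, 1, 0, i < 5) for i in range(10)]
        res = precocious_lunge_analysis(outcome_df(rows_a), outcome_df(rows_b))
        assert res.chi2 == 0.0

    def test_chi2_matches_hand_computation(self):
        # 2x2 table [[20,5],[5,20]]: chi2 = sum (O-E)^2 / E = 18
        rows_a = [("p", "g", "g", True, 0, 0, i < 20) for i in range(25)]
        rows_b = [("p", "g", "g", True, 0, 0, i < 5) for i in range(25)]
        res = precocious_lunge_analysis(outcome_df(rows_a), outcome_df(rows_b))
        expected = 0.0
        obs = np.array([[20, 5], [5, 20]], float)
        e = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        expected = ((obs - e) ** 2 / e).sum()
        assert res.chi2 == pytest.approx(expected)

    def test_low_expected_cell_warns_and_reports_fisher(self):
        rows_a = [("p", "g", "g", True, 0, 0, i < 1) for i in range(3)]
        rows_b = [("p", "g", "g", True, 0, 0, False) for _ in range(3)]
        with pytest.warns(UserWarning, match="Fisher"):
            res = precocious_lunge_analysis(outcome_df(rows_a), outcome_df(rows_b))
        assert res.p_fisher is not None

    def test_rematch_design_detects_precocious_lunging(self, first_contest):
        # winner-rematch cohorts: the prior-dominant cohort lunges before
        # onset far more often than pairs of naive males
        cfg, first = first_contest
        n = 30
        naive = []
        for i in range(n):
            t = simulate_truth(cfg, derived_seed(81, i), f"n{i}")
            lunges = t.events.select(behavior="lunge")
            pre = lunges[lunges["start_s"] < t.onset_s]
            naive.append(
                ("naive", "g", "g", t.dominant_id == "A", 0, 0,
                 bool((pre["fly"] == "A").any()))
            )
        rematch = []
        for i in range(n):
            rm = winner_rematch(cfg, first, derived_seed(82, i), events_only=True)
            lunges = rm.truth.events.select(behavior="lunge")
            pre = lunges[lunges["start_s"] < rm.truth.onset_s]
            rematch.append(
                ("rematch", "g", "g", rm.truth.dominant_id == "A", 0, 0,
                 bool((pre["fly"] == "A").any()))
            )
        res = precocious_lunge_analysis(outcome_df(naive), outcome_df(rematch))
        assert res.prop_rematch > res.prop_first
        assert res.p_chi2 < 0.05
        # among early-lunging prior dominants, most go on to win
        assert res.n_lunged_won > res.n_lunged_lost


def test_outcome_table_from_contests_uses_final_dominant(first_contest):
    cfg, first = first_contest
    table = outcome_table_from_contests([first], pairing_label="x")
    assert len(table.df) == 1
    row = table.df.iloc[0]
    final_dom = first.truth.dominant_at(cfg.duration_s - 1e-6)
    assert row["focal_dominant"] == (final_dom == "A")
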