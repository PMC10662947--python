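import itertools

import numpy as np
import pandas as pd
import pytest

from symtraj import trajectories as tj
from symtraj.pairs import DirectionCounts, PairStat


def _stat(d1, d2, effect, p_eff, p_dir, fwd=10, bwd=1):
    return PairStat(
        d1=d1, d2=d2, source="registry", n_exposed=100, c_exposed=20,
        mean_comparison=5.0, effect=effect, effect_p=p_eff / 10,
        direction=DirectionCounts(fwd, bwd, 0), direction_p=p_dir / 10,
        effect_p_corrected=p_eff, direction_p_corrected=p_dir,
    )


class TestSignificantPairs:
    def test_keeps_forward_dominant_significant_pair(self):
        edges = tj.significant_pairs([_stat("A", "B", 3.0, 0.001, 0.001)])
        assert edges == {("A", "B")}

    def test_effect_below_threshold_excluded(self):
        assert tj.significant_pairs([_stat("A", "B", 0.8, 0.001, 0.001)]) == set()

    def test_nonsignificant_direction_excluded(self):
        assert tj.significant_pairs([_stat("A", "B", 3.0, 0.001, 0.3)]) == set()

    def test_backward_dominant_excluded(self):
        stat = _stat("A", "B", 3.0, 0.001, 0.001, fwd=1, bwd=10)
        assert tj.significant_pairs([stat]) == set()


def brute_force_paths(edges, length):
    nodes = {n for e in edges for n in e}
    out = []
    for tup in itertools.permutations(sorted(nodes), length):
        if all((a, b) in edges for a, b in zip(tup, tup[1:])):
            out.append(tup)
    return sorted(out)


class TestChaining:
    def test_single_chain(self):
        assert tj.chain_trajectories({("A", "B"), ("B", "C")}) == [("A", "B", "C")]

    def test_shortcut_edge_adds_no_new_triples(self):
        edges = {("A", "B"), ("B", "C"), ("A", "C")}
        assert tj.chain_trajectories(edges) == [("A", "B", "C")]

    def test_two_cycle_yields_nothing(self):
        assert tj.chain_trajectories({("A", "B"), ("B", "A")}) == []

    def test_length_four(self):
        edges = {("A", "B"), ("B", "C"), ("C", "D")}
        assert tj.chain_trajectories(edges, length=4) == [("A", "B", "C", "D")]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("length", [3, 4])
    def test_agrees_with_bruteforce_on_random_digraphs(self, seed, length):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        nodes = [f"N{i}" for i in range(n)]
        edges = {
            (a, b)
            for a in nodes
            for b in nodes
            if a != b and rng.random() < 0.25
        }
        assert tj.chain_trajectories(edges, length) == brute_force_paths(edges, length)


def first_dates(entries):
    idx = pd.MultiIndex.from_tuples(
        [(p, c) for p, c, _ in entries], names=["patient_id", "event_code"]
    )
    return pd.Series([pd.Timestamp(d) for *_, d in entries], index=idx)


class TestFollowers:
    def setup_method(self):
        self.first = first_dates(
            [
                ("p1", "A", "2010-01-10"), ("p1", "B", "2010-04-10"),
                ("p1", "C", "2010-08-01"),
                ("p2", "A", "2010-01-10"), ("p2", "B", "2010-01-10"),
                ("p2", "C", "2010-08-01"),
                ("p3", "A", "2010-02-01"), ("p3", "B", "2010-03-01"),
                ("p3", "D", "2010-04-01"),
            ]
        )
        self.index = pd.Series(
            pd.Timestamp("2011-01-01"), index=["p1", "p2", "p3"]
        )

    def test_strictly_increasing_order_required(self):
        n, ids = tj.count_followers(("A", "B", "C"), self.first, self.index)
        assert (n, ids) == (1, ["p1"])  # p2 ties A/B on the same day

    def test_patient_can_follow_multiple_paths(self):
        _, ids1 = tj.count_followers(("A", "B", "C"), self.first, self.index)
        _, ids2 = tj.count_followers(("A", "B", "D"), self.first, self.index)
        assert "p1" in ids1 and "p3" in ids2

    def test_pre_only_requires_all_codes_before_index(self):
        index = pd.Series(pd.Timestamp("2010-06-01"), index=["p1", "p2", "p3"])
        n, _ = tj.count_followers(("A", "B", "C"), self.first, index)
        assert n == 0  # p1's C falls after the index date
        n, _ = tj.count_followers(("A", "B", "C"), self.first, index, mode="straddle")
        assert n == 1

    def test_prefix_counts_dominate_path_counts(self):
        n_pref, _ = tj.count_followers(("A", "B"), self.first, self.index)
        n_full, _ = tj.count_followers(("A", "B", "C"), self.first, self.index)
        assert n_full <= n_pref

    def test_missing_code_gives_zero(self):
        n, ids = tj.count_followers(("A", "Z"), self.first, self.index)
        assert (n, ids) == (0, [])


class TestSupportAndSurvival:
    def _traj(self, n):
        return tj.Trajectory(("A", "B", "C"), n, tuple(range(n)), 100.0, "long")

    def test_support_threshold(self):
        kept = tj.filter_support([self._traj(99), self._traj(100), self._traj(20)], 100)
        assert [t.n_followers for t in kept] == [100]
        assert tj.filter_support([], 20) == []

    def test_lowering_threshold_is_monotone(self):
        trajs = [self._traj(n) for n in (5, 25, 120)]
        low = tj.filter_support(trajs, 5)
        high = tj.filter_support(trajs, 25)
        assert set(t.n_followers for t in high) <= set(t.n_followers for t in low)

    def _survival_series(self, death_days):
        ids = [f"p{i}" for i in range(len(death_days))]
        index = pd.Series(pd.Timestamp("2010-01-01"), index=ids)
        deaths = pd.Series(
            [pd.Timestamp("2010-01-01") + pd.Timedelta(days=d) if d is not None else pd.NaT
             for d in death_days],
            index=ids,
        )
        return ids, index, deaths

    def test_median_of_uncensored_deaths(self):
        ids, index, deaths = self._survival_series([10, 50, 200])
        med, cls, naive = tj.median_survival(ids, index, deaths, "2012-01-01")
        assert med == 50 and cls == "short" and naive == 50

    def test_long_survival_class(self):
        ids, index, deaths = self._survival_series([100, 120, 400])
        med, cls, _ = tj.median_survival(ids, index, deaths, "2012-01-01")
        assert med == 120 and cls == "long"

    def test_unreached_median_is_long(self):
        ids, index, deaths = self._survival_series([30, None, None, None, None])
        med, cls, _ = tj.median_survival(ids, index, deaths, "2010-06-01")
        assert np.isinf(med) and cls == "long"

    def test_empty_follower_group_rejected(self):
        ids, index, deaths = self._survival_series([10])
        with pytest.raises(ValueError):
            tj.median_survival([], index, deaths, "2012-01-01")


class TestCoverageAndComparison:
    def test_disjoint_follower_union(self):
        cases = [f"c{i}" for i in range(100)]
        t1 = tj.Trajectory(("A", "B", "C"), 10, tuple(cases[:10]), 50.0, "short")
        t2 = tj.Trajectory(("A", "B", "D"), 15, tuple(cases[10:25]), 120.0, "long")
        frac, pct = tj.trajectory_coverage([t1, t2], cases)
        assert frac == pytest.approx(0.25) and pct == 25

    def test_no_trajectories(self):
        frac, pct = tj.trajectory_coverage([], ["c1", "c2"])
        assert frac == 0.0 and pct == 0

    def test_set_partition(self):
        out = tj.compare_sources({"R10": 5, "R17": 9}, {"R17": 3, "R63": 2})
        assert out.both == {"R17"}
        assert out.registry_only == {"R10"}
        assert out.notes_only == {"R63"}
        assert out.table.set_index("code").loc["R17"].tolist() == [9, 3]

    def test_identical_sets(self):
        out = tj.compare_sources({"R10": 1}, {"R10": 4})
        assert out.both == {"R10"} and not out.registry_only and not out.notes_only


class TestTemporalDistribution:
    def test_planted_group_timing_orders_medians(self):
        from tests.conftest import make_events

        rows = []
        index = {}
        deaths = {}
        for i in range(40):
            pid = f"s{i}"  # short survivors: symptom close to diagnosis
            rows.append((pid, "R17", "2010-11-01", "2010-11-02", "A", f"e{pid}"))
            index[pid] = pd.Timestamp("2011-01-01")
            deaths[pid] = pd.Timestamp("2011-02-01")  # 31 days
        for i in range(40):
            pid = f"l{i}"  # long survivors: symptom far from diagnosis
            rows.append((pid, "R17", "2008-01-01", "2008-01-02", "A", f"e{pid}"))
            index[pid] = pd.Timestamp("2011-01-01")
            deaths[pid] = pd.Timestamp("2012-01-01")
        out = tj.temporal_distribution(
            "R17", make_events(rows), pd.Series(index), pd.Series(deaths)
        )
        assert np.median(out["short"]) < np.median(out["long"])
        summary = out["summary"].set_index("group")
        assert summary.loc["short", "n"] == 40

    def test_occurrence_outside_window_excluded(self):
        from tests.conftest import make_events

        ev = make_events([("p", "R17", "2001-01-01", "2001-01-02", "A", "e1")])
        out = tj.temporal_distribution(
            "R17", ev,
            pd.Series({"p": pd.Timestamp("2011-01-01")}),
            pd.Series({"p": pd.NaT}),
        )
        assert out["short"].size == 0 and out["long"].size == 0
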