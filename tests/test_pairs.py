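import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from symtraj import pairs as pr
from symtraj.cohort import StratumExhaustedError


class TestRelativeRisk:
    def test_exposed_over_mean_comparison(self):
        counts = pr.PairCounts("R10", "R17", 100, 30, [10, 12, 8, 10, 10])
        assert pr.relative_risk(counts) == pytest.approx(3.0)

    def test_null_is_one(self):
        counts = pr.PairCounts("R10", "R17", 100, 10, [10, 10])
        assert pr.relative_risk(counts) == pytest.approx(1.0)

    def test_all_zero_comparison_is_incalculable(self):
        counts = pr.PairCounts("R10", "R17", 100, 5, [0, 0, 0])
        with pytest.raises(pr.IncalculablePairError):
            pr.relative_risk(counts)

    def test_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            pr.PairCounts("a", "b", 10, 11, [1])
        with pytest.raises(ValueError):
            pr.PairCounts("a", "b", 10, 5, [])


class TestRRBinomialTest:
    def test_matches_exact_tail_sum(self):
        counts = pr.PairCounts("a", "b", 100, 30, [10] * 5)
        # independent oracle: explicit tail sum of the binomial pmf
        expected = sum(sps.binom.pmf(k, 100, 0.1) for k in range(30, 101))
        assert pr.rr_binomial_test(counts) == pytest.approx(expected, rel=1e-10)

    def test_null_center_not_significant(self):
        counts = pr.PairCounts("a", "b", 100, 10, [10] * 5)
        assert pr.rr_binomial_test(counts) > 0.4

    def test_zero_exposed_count_gives_one(self):
        counts = pr.PairCounts("a", "b", 100, 0, [10] * 5)
        assert pr.rr_binomial_test(counts) == 1.0

    def test_super_uniform_under_null(self):
        rng = np.random.default_rng(0)
        n, p0 = 200, 0.1
        cs = rng.binomial(n, p0, size=2000)
        pvals = np.array(
            [
                pr.rr_binomial_test(pr.PairCounts("a", "b", n, int(c), [int(p0 * n)] * 5))
                for c in cs
            ]
        )
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert (pvals <= t).mean() <= t + 0.02


class TestDirectionality:
    def test_nine_versus_one(self):
        p = pr.directionality_test(pr.DirectionCounts(9, 1, 0))
        assert p == pytest.approx(22 / 1024)

    def test_five_versus_zero(self):
        assert pr.directionality_test(pr.DirectionCounts(5, 0, 0)) == pytest.approx(2 / 32)

    def test_symmetric_counts_give_one(self):
        assert pr.directionality_test(pr.DirectionCounts(4, 4, 0)) == 1.0

    def test_same_day_counts_dilute_the_signal(self):
        sharp = pr.directionality_test(pr.DirectionCounts(8, 2, 0))
        diluted = pr.directionality_test(pr.DirectionCounts(8, 2, 6))
        assert diluted > sharp

    def test_empty_is_incalculable(self):
        with pytest.raises(pr.IncalculablePairError):
            pr.directionality_test(pr.DirectionCounts(0, 0, 0))


class TestBonferroni:
    def test_scales_and_caps(self):
        out = pr.bonferroni([0.01, 0.5], m=5)
        assert out.tolist() == [0.05, 1.0]

    def test_family_must_cover_tests(self):
        with pytest.raises(ValueError):
            pr.bonferroni([0.1, 0.2, 0.3], m=2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    def test_elementwise_map_invariant_under_permutation(self, ps, rnd):
        perm = ps[:]
        rnd.shuffle(perm)
        a = sorted(pr.bonferroni(ps, m=len(ps)))
        b = sorted(pr.bonferroni(perm, m=len(perm)))
        assert a == b


class TestOddsRatio:
    def test_single_stratum_equals_cross_product(self):
        case = np.r_[np.ones(30, bool), np.zeros(70, bool)]
        ctrl = np.r_[np.ones(10, bool), np.zeros(90, bool)]
        or_, p = pr.odds_ratio_pair(case, ctrl)
        assert or_ == pytest.approx((30 * 90) / (70 * 10))
        assert 0 < p < 0.05

    def test_equal_rates_give_unit_or(self):
        case = np.r_[np.ones(20, bool), np.zeros(80, bool)]
        or_, p = pr.odds_ratio_pair(case, case.copy())
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_no_exposed_controls_incalculable(self):
        case = np.r_[np.ones(20, bool), np.zeros(80, bool)]
        ctrl = np.zeros(100, bool)
        with pytest.raises(pr.IncalculablePairError):
            pr.odds_ratio_pair(case, ctrl)

    def test_stratified_fit_tracks_mantel_haenszel(self):
        rng = np.random.default_rng(1)
        n_sets, ratio = 200, 10
        case = rng.random(n_sets) < 0.35
        ctrl = rng.random(n_sets * ratio) < 0.15
        cs = np.arange(n_sets)
        ks = np.repeat(np.arange(n_sets), ratio)
        or_cl, _ = pr.odds_ratio_pair(case, ctrl, cs, ks)
        or_mh, _ = pr.mantel_haenszel_or(case, ctrl, cs, ks)
        assert or_cl == pytest.approx(or_mh, rel=0.10)
        true_or = (0.35 / 0.65) / (0.15 / 0.85)
        assert or_cl == pytest.approx(true_or, rel=0.35)

    def test_enrichment_extremes(self):
        rng = np.random.default_rng(2)
        n_sets, ratio = 100, 10
        cs = np.arange(n_sets)
        ks = np.repeat(np.arange(n_sets), ratio)
        planted = rng.random(n_sets) < 0.4
        absent_ctrl = rng.random(n_sets * ratio) < 0.02
        or_, p = pr.symptom_enrichment(planted, absent_ctrl, cs, ks)
        assert or_ > 5 and p < 0.05
        same_rate_case = rng.random(n_sets) < 0.2
        same_rate_ctrl = rng.random(n_sets * ratio) < 0.2
        or2, _ = pr.symptom_enrichment(same_rate_case, same_rate_ctrl, cs, ks)
        assert 0.5 < or2 < 2.0


class TestComparisonSampling:
    @pytest.fixture()
    def cohort(self, planted_sim):
        from symtraj import cohort as ch

        cfg, registry, _ = planted_sim
        patients = ch.filter_active(registry.patients)
        events = ch.filter_diagnosis_types(registry.events)
        events = events[events.patient_id.isin(set(patients.patient_id))]
        cases = ch.select_cases(patients, events, registry.confirmed_case_ids)
        attrs = patients.set_index("patient_id")
        cases = cases.merge(
            attrs[["sex", "birth_date"]], left_on="patient_id", right_index=True
        )
        case_ev = ch.windowed_case_events(
            cases[["patient_id", "index_date"]], events, 5
        )
        pool_pat = patients[patients.patient_id.str.startswith("P")]
        pool_ev = ch.dedup_per_encounter(
            events[events.patient_id.isin(set(pool_pat.patient_id))]
        )
        return cases, case_ev, pool_pat, pool_ev

    def test_groups_match_size_sex_band_and_week(self, cohort):
        cases, case_ev, pool_pat, pool_ev = cohort
        exposed = pr.build_exposed_group(case_ev, "R10")
        exposed = exposed.merge(
            cases[["patient_id", "sex", "birth_date"]], on="patient_id"
        )
        pool = pr.ComparisonPool(pool_pat, pool_ev)
        groups = pr.sample_comparison_groups(exposed, pool, n_groups=5, seed=3)
        assert len(groups) == 5
        weeks = pool_ev.assign(week=pool_ev.discharge_date.dt.isocalendar().week.clip(upper=52))
        week_sets = weeks.groupby("patient_id")["week"].agg(set)
        for g in groups:
            assert len(g) == len(exposed)
            assert len(set(g)) == len(g)  # without replacement within a group
            for member, rec in zip(g, exposed.itertuples()):
                target = min(pd.Timestamp(rec.anchor).isocalendar().week, 52)
                assert target in week_sets[member]

    def test_deterministic_under_seed(self, cohort):
        cases, case_ev, pool_pat, pool_ev = cohort
        exposed = pr.build_exposed_group(case_ev, "R17").merge(
            cases[["patient_id", "sex", "birth_date"]], on="patient_id"
        )
        pool = pr.ComparisonPool(pool_pat, pool_ev)
        g1 = pr.sample_comparison_groups(exposed, pool, 3, seed=11)
        g2 = pr.sample_comparison_groups(exposed, pool, 3, seed=11)
        assert all((a == b).all() for a, b in zip(g1, g2))

    def test_infeasible_member_raises(self, cohort):
        cases, case_ev, pool_pat, _ = cohort
        exposed = pr.build_exposed_group(case_ev, "R10").merge(
            cases[["patient_id", "sex", "birth_date"]], on="patient_id"
        )
        empty_pool = pr.ComparisonPool(
            pool_pat.iloc[:0],
            pd.DataFrame(columns=["patient_id", "discharge_date"]),
        )
        with pytest.raises(StratumExhaustedError):
            pr.sample_comparison_groups(exposed, empty_pool, 1, seed=0)

    def test_exposed_group_anchor_is_first_discharge(self):
        from tests.conftest import make_events

        ev = make_events(
            [
                ("p1", "R10", "2010-01-01", "2010-01-03", "A", "e1"),
                ("p1", "R10", "2009-05-01", "2009-05-02", "A", "e2"),
                ("p2", "R17", "2010-01-01", "2010-01-01", "A", "e3"),
            ]
        )
        exposed = pr.build_exposed_group(ev, "R10")
        assert exposed.patient_id.tolist() == ["p1"]
        assert exposed.anchor.iloc[0] == pd.Timestamp("2009-05-02")
        assert pr.build_exposed_group(ev, "K56").empty
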