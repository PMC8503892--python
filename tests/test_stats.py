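import numpy as np
import pytest

from epnsig.io import ClinicalRecord, load_table2
from epnsig.simulate import SurvivalDesign, SurvivalGroup, simulate_survival
from epnsig.stats import (ContingencyTable2x2, fisher_exact_two_sided,
                          fusion_concordance, km_estimate, logrank_test,
                          survivor_count, two_sample_ttest)

from oracles import fisher_oracle, km_oracle


def record(pid="p", group="G", time=100.0, death=False, prog=False,
           t_prog=None, **kwargs):
    return ClinicalRecord(
        patient_id=pid, age_years=5.0, sex="M", group_label=group,
        fusion_call=kwargs.get("fusion"), time_months=time, event_death=death,
        event_progression=prog,
        time_progression_months=t_prog if t_prog is not None else time,
    )


class TestFisher:
    def test_published_concordance_table(self):
        """9/10 signature-positive vs 0/4 unclassified fusion detections."""
        p = fisher_exact_two_sided(ContingencyTable2x2(9, 1, 0, 4))
        assert p == pytest.approx(fisher_oracle(9, 1, 0, 4), rel=1e-9)
        assert round(p, 3) == 0.005

    @pytest.mark.parametrize("table,expected", [
        ((1, 0, 0, 1), 1.0),   # both admissible tables have probability 1/2
        ((5, 5, 5, 5), 1.0),   # observed table is the mode
        ((0, 0, 0, 0), 1.0),   # empty table
    ])
    def test_known_values(self, table, expected):
        assert fisher_exact_two_sided(ContingencyTable2x2(*table)) \
            == pytest.approx(expected)

    def test_matches_enumeration_oracle_small_tables(self):
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        t = ContingencyTable2x2(a, b, c, d)
                        assert fisher_exact_two_sided(t) == pytest.approx(
                            fisher_oracle(a, b, c, d), rel=1e-8, abs=1e-12), (a, b, c, d)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        records = [record(pid=str(i), time=t) for i, t in enumerate([5, 10, 20])]
        curve = km_estimate(records)
        assert np.allclose(curve.survival, 1.0)
        assert curve.n_events == 0

    def test_no_censoring_equals_empirical_survival(self):
        records = [record(pid=str(i), time=float(i + 1), death=True)
                   for i in range(4)]
        curve = km_estimate(records)
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert curve.at(t) == pytest.approx(s)

    def test_hand_computed_product_limit(self):
        """death@10, censored@5, death@20: S(10) = 1/2, S(20) = 0."""
        records = [record(pid="a", time=10.0, death=True),
                   record(pid="b", time=5.0),
                   record(pid="c", time=20.0, death=True)]
        curve = km_estimate(records)
        times, surv = km_oracle([10, 5, 20], [True, False, True])
        assert curve.at(10) == pytest.approx(0.5) == pytest.approx(surv[0])
        assert curve.at(20) == pytest.approx(0.0) == pytest.approx(surv[1])

    def test_random_no_censoring_matches_oracle(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(50, size=30).round(1) + 1
        records = [record(pid=str(i), time=float(t), death=True)
                   for i, t in enumerate(times)]
        curve = km_estimate(records)
        otimes, osurv = km_oracle(times, [True] * 30)
        for t, s in zip(otimes, osurv):
            assert curve.at(t) == pytest.approx(s)

    def test_pfs_uses_first_of_progression_or_death(self):
        records = [record(pid="a", time=100.0, prog=True, t_prog=30.0),
                   record(pid="b", time=50.0, death=True),
                   record(pid="c", time=80.0)]
        curve = km_estimate(records, endpoint="PFS")
        assert curve.at(30) == pytest.approx(2 / 3)
        assert curve.at(50) == pytest.approx(1 / 3)

    def test_unknown_times_excluded_and_all_unknown_raises(self):
        known = record(pid="a", time=10.0)
        unknown = ClinicalRecord("b", 5.0, "F", "G", None, None, True, False, None)
        curve = km_estimate([known, unknown])
        assert curve.at(5) == 1.0
        with pytest.raises(ValueError, match="known follow-up"):
            km_estimate([unknown])


class TestLogrank:
    def test_identical_groups_null(self):
        recs = []
        for g in ("A", "B"):
            recs += [record(pid=f"{g}{i}", group=g, time=float(10 * (i + 1)),
                            death=(i % 2 == 0)) for i in range(6)]
        chi2, p = logrank_test(recs)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        recs = [record(pid=str(i), group=("A" if i < 10 else "B"),
                       time=float(rng.exponential(40) + 1), death=bool(rng.integers(2)))
                for i in range(20)]
        chi2_1, _ = logrank_test(recs)
        flipped = [ClinicalRecord(r.patient_id, r.age_years, r.sex,
                                  ("B" if r.group_label == "A" else "A"),
                                  r.fusion_call, r.time_months, r.event_death,
                                  r.event_progression, r.time_progression_months)
                   for r in recs]
        chi2_2, _ = logrank_test(flipped)
        assert chi2_1 == pytest.approx(chi2_2)
        assert chi2_1 >= 0

    def test_power_under_constructed_hazard_ratio(self):
        design = SurvivalDesign(
            groups=[SurvivalGroup("hi", 200, 0.02), SurvivalGroup("lo", 200, 0.002)],
            seed=12)
        records = simulate_survival(design)
        _, p = logrank_test(records)
        assert p < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([record(pid="a"), record(pid="b")])


class TestTableTwoCounting:
    def test_five_year_survivor_count(self):
        """Eight of the RELA+ patients are verified five-year survivors."""
        assert survivor_count(load_table2(), "RELA+", 60) == 8

    def test_zero_threshold_gives_group_size(self):
        records = load_table2()
        assert survivor_count(records, "RELA+", 0) == 10
        assert survivor_count(records, "YAP1+", 0) == 1

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            survivor_count(load_table2(), "PFB", 60)

    def test_fusion_concordance_table(self):
        table = fusion_concordance(load_table2())
        assert (table.a, table.b, table.c, table.d) == (9, 1, 0, 4)

    def test_other_fusion_counts_as_not_detected(self):
        records = load_table2()
        maml2 = [r for r in records if r.fusion_call == "ZFTA-MAML2"]
        assert len(maml2) == 1 and maml2[0].group_label == "NC"
        # it lands in d, not c
        assert fusion_concordance(records).c == 0

    def test_yap1_excluded_from_concordance(self):
        records = load_table2()
        assert fusion_concordance(records).n == 14

    def test_empty_input(self):
        t = fusion_concordance([])
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)


class TestTwoSampleTtest:
    def test_identical_groups(self):
        assert two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        assert two_sample_ttest([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_large_effect_power(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        assert two_sample_ttest(a, b) < 1e-6

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 12)
        p1 = two_sample_ttest(a, b)
        p2 = two_sample_ttest(3 * a + 7, 3 * b + 7)
        assert p1 == pytest.approx(p2)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            two_sample_ttest([1.0], [1.0, 2.0])
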