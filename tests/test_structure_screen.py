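import numpy as np
import pytest
from scipy import stats

from denovoscape.datasets import ProteinRecord, SequenceSet
from denovoscape.structure_screen import (
    DisorderProfile,
    SecondaryStructureString,
    StructureHit,
    TrajectorySet,
    architecture_age_test,
    assign_ecod,
    best_hit_per_query,
    correlate_rmsd_tm,
    disorder_fraction,
    filter_for_simulation,
    filter_hits,
    helix_fraction,
    mean_rmsd,
)


class TestDisorderFraction:
    def test_direct_count(self):
        p = DisorderProfile("a", (0.9, 0.1, 0.6, 0.4))
        assert disorder_fraction(p, cutoff=0.5) == 0.5

    def test_all_zeros(self):
        assert disorder_fraction(DisorderProfile("a", (0.0,) * 10)) == 0.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            DisorderProfile("a", ())

    def test_counting_oracle_random_scores(self):
        rng = np.random.default_rng(4)
        scores = tuple(rng.uniform(0, 1, size=1000))
        frac = disorder_fraction(DisorderProfile("a", scores), cutoff=0.5)
        assert frac == sum(1 for s in scores if s >= 0.5) / 1000


class TestHelixFraction:
    def test_direct_count(self):
        assert helix_fraction(SecondaryStructureString("a", "HHHH--")) == 4 / 6

    def test_no_helix(self):
        assert helix_fraction(SecondaryStructureString("a", "EEEE")) == 0.0

    def test_helix_code_configuration(self):
        ss = SecondaryStructureString("a", "GGHH")
        assert helix_fraction(ss, helix_codes={"H", "G", "I"}) == 1.0
        assert helix_fraction(ss) == 0.5

    def test_non_dssp_codes_rejected(self):
        with pytest.raises(ValueError):
            SecondaryStructureString("a", "HZXH")


class TestSimulationFilter:
    def _inputs(self, fractions):
        records = SequenceSet()
        profiles, ss = {}, {}
        for i, (d, h) in enumerate(fractions):
            pid = f"p{i}"
            L = 100
            records.add(ProteinRecord(pid, "M" * L))
            nd = int(round(d * L))
            profiles[pid] = DisorderProfile(pid, (1.0,) * nd + (0.0,) * (L - nd))
            nh = int(round(h * L))
            ss[pid] = SecondaryStructureString(pid, "H" * nh + "-" * (L - nh))
        return records, profiles, ss

    def test_boundary_30pct_excluded(self):
        records, profiles, ss = self._inputs([(0.30, 0.0)])
        assert len(filter_for_simulation(records, profiles, ss)) == 0

    def test_fully_ordered_included(self):
        records, profiles, ss = self._inputs([(0.0, 0.0)])
        assert len(filter_for_simulation(records, profiles, ss)) == 1

    def test_helix_boundary_95pct_excluded(self):
        records, profiles, ss = self._inputs([(0.0, 0.95), (0.0, 0.94)])
        out = filter_for_simulation(records, profiles, ss)
        assert out.ids == ["p1"]

    def test_missing_inputs_listed(self):
        records, profiles, ss = self._inputs([(0.0, 0.0)])
        del profiles["p0"]
        with pytest.raises(KeyError, match="p0"):
            filter_for_simulation(records, profiles, ss)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        fractions = [(rng.uniform(0, 0.6), rng.uniform(0, 1)) for _ in range(200)]
        records, profiles, ss = self._inputs(fractions)
        out = filter_for_simulation(records, profiles, ss)
        expected = [
            f"p{i}" for i, _ in enumerate(fractions)
            if disorder_fraction(profiles[f"p{i}"]) < 0.30
            and helix_fraction(ss[f"p{i}"]) < 0.95
        ]
        assert out.ids == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        fractions = [(rng.uniform(0, 0.6), rng.uniform(0, 1)) for _ in range(100)]
        records, profiles, ss = self._inputs(fractions)
        tight = filter_for_simulation(records, profiles, ss, 0.2, 0.8)
        loose = filter_for_simulation(records, profiles, ss, 0.4, 0.99)
        assert set(tight.ids) <= set(loose.ids)


class TestMeanRmsd:
    def test_arithmetic(self):
        t = TrajectorySet("a", ((1, 2, 3), (2, 2, 2), (3, 3, 3)))
        assert mean_rmsd(t) == pytest.approx((2 + 2 + 3) / 3)

    def test_single_replicate(self):
        assert mean_rmsd(TrajectorySet("a", ((5.0,),))) == 5.0

    def test_two_level_not_pooled_mean(self):
        # replicate means are 2 and 1; two-level mean 1.5, pooled would be 4/3
        t = TrajectorySet("a", ((0, 4), (1, 1, 1, 1)))
        assert mean_rmsd(t) == pytest.approx(1.5)
        assert mean_rmsd(t) != pytest.approx(6 / 6 + 2 / 6)

    def test_empty_replicate_rejected(self):
        with pytest.raises(ValueError):
            TrajectorySet("a", ((1.0,), ()))


class TestHitFilter:
    def _hit(self, tm=0.7, cov=0.9, taxon="Homo sapiens", q="q", t="t"):
        return StructureHit(q, t, tm, cov, taxon)

    def test_tm_boundary_strict(self):
        assert filter_hits([self._hit(tm=0.5)]) == []
        kept = filter_hits([self._hit(tm=0.51, cov=0.80)])
        assert len(kept) == 1

    def test_coverage_boundary_inclusive(self):
        assert len(filter_hits([self._hit(cov=0.8)])) == 1
        assert filter_hits([self._hit(cov=0.799)]) == []

    def test_taxon_prefix_exclusion(self):
        h = self._hit(taxon="Drosophila melanogaster")
        assert filter_hits([h], exclude_taxa={"Drosophila"}) == []
        assert filter_hits([h], exclude_taxa={"Homo"}) == [h]

    def test_taxon_match_case_insensitive(self):
        h = self._hit(taxon="drosophila simulans")
        assert filter_hits([h], exclude_taxa={"Drosophila"}) == []

    def test_predicate_oracle_and_idempotence(self):
        rng = np.random.default_rng(12)
        taxa = ["Homo sapiens", "Drosophila melanogaster", "Mus musculus"]
        hits = [
            self._hit(tm=float(rng.uniform(0, 1)), cov=float(rng.uniform(0, 1)),
                      taxon=taxa[int(rng.integers(0, 3))], q=f"q{i}")
            for i in range(1000)
        ]
        kept = filter_hits(hits, exclude_taxa={"Drosophila"})
        expected = [h for h in hits
                    if h.tm_score > 0.5 and h.target_coverage >= 0.8
                    and not h.target_taxon.startswith("Drosophila")]
        assert kept == expected
        assert filter_hits(kept, exclude_taxa={"Drosophila"}) == kept
        assert set(id(h) for h in kept) <= set(id(h) for h in hits)


class TestBestHit:
    def test_max_tm(self):
        hits = [StructureHit("q", f"t{i}", tm, 0.9, "x", replicate=i)
                for i, tm in enumerate((0.6, 0.8, 0.7))]
        assert best_hit_per_query(hits)["q"].tm_score == 0.8

    def test_tie_break_by_evalue_then_target(self):
        a = StructureHit("q", "tb", 0.7, 0.9, "x", evalue=1e-5)
        b = StructureHit("q", "ta", 0.7, 0.9, "x", evalue=1e-3)
        assert best_hit_per_query([a, b])["q"] is a
        c = StructureHit("q", "tb", 0.7, 0.9, "x", evalue=1e-5)
        d = StructureHit("q", "ta", 0.7, 0.9, "x", evalue=1e-5)
        assert best_hit_per_query([c, d])["q"] is d

    def test_argmax_oracle(self):
        rng = np.random.default_rng(14)
        hits = [
            StructureHit(f"q{i}", f"t{r}", float(rng.uniform(0, 1)), 0.9, "x",
                         replicate=r)
            for i in range(50) for r in (1, 2, 3)
        ]
        best = best_hit_per_query(hits)
        for qid, hit in best.items():
            tms = [h.tm_score for h in hits if h.query_id == qid]
            assert hit.tm_score == max(tms)


class TestEcodAssignment:
    def test_mapped_and_unmapped(self):
        best = {
            "q1": StructureHit("q1", "t1", 0.8, 0.9, "x"),
            "q2": StructureHit("q2", "t2", 0.7, 0.9, "x"),
        }
        assignments, unmapped = assign_ecod(best, {"t1": "alpha bundles"})
        assert [a.architecture for a in assignments] == ["alpha bundles"]
        assert unmapped == ["q2"]

    def test_planted_architecture_multiset(self):
        rng = np.random.default_rng(20)
        archs = ["alpha bundles", "alpha arrays", "beta sandwiches"]
        planted = {f"t{i}": archs[int(rng.integers(0, 3))] for i in range(42)}
        best = {f"q{i}": StructureHit(f"q{i}", f"t{i}", 0.8, 0.9, "x")
                for i in range(42)}
        assignments, unmapped = assign_ecod(best, planted)
        assert unmapped == []
        assert sorted(a.architecture for a in assignments) == sorted(planted.values())


class TestArchitectureAgeTest:
    def _records(self, ages):
        return SequenceSet(
            ProteinRecord(f"p{i}", "MK", age_mya=a) for i, a in enumerate(ages)
        )

    def test_proportional_gives_zero_statistic(self):
        # 2 groups x 10 proteins, 50% assigned in each
        ages = [1.0] * 10 + [50.0] * 10
        records = self._records(ages)
        from denovoscape.structure_screen import EcodAssignment

        assigned = [EcodAssignment(f"p{i}", "t", "a", 0.8)
                    for i in list(range(5)) + list(range(10, 15))]
        chi2, dof, p = architecture_age_test(assigned, records)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # table [[10,90],[30,70]]: expected [[20,80],[20,80]],
        # sum (O-E)^2/E = 5 + 1.25 + 5 + 1.25 = 12.5
        table = np.array([[10, 90], [30, 70]])
        res = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(12.5)


class TestRmsdTmCorrelation:
    def test_perfect_positive(self):
        r, _ = correlate_rmsd_tm({"a": 1, "b": 2, "c": 3}, {"a": 2, "b": 4, "c": 6})
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = correlate_rmsd_tm({"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1})
        assert r == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate_rmsd_tm({"a": 1, "b": 2}, {"a": 1, "b": 2})

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            correlate_rmsd_tm({"a": 1, "b": 1, "c": 1}, {"a": 1, "b": 2, "c": 3})

    def test_formula_oracle(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=100)
        y = 0.3 * x + rng.normal(size=100)
        rmsd = {f"p{i}": float(v) for i, v in enumerate(x)}
        tm = {f"p{i}": float(v) for i, v in enumerate(y)}
        r, _ = correlate_rmsd_tm(rmsd, tm)
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected, abs=1e-12)
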