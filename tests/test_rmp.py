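import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from strpop import rmp, simulate
from strpop.io import (
    AUTOSOMAL,
    AlleleFrequencyTable,
    GenotypeTable,
    LocusDef,
    LocusFrequencies,
    Sample,
    StrpopError,
    frequency_table_from_genotypes,
)


class TestRmpLocus:
    def test_homozygote_reduces_to_p_squared_at_zero_theta(self):
        assert rmp.rmp_locus(("10", "10"), {"10": 0.5}, 0.0) == pytest.approx(0.25, abs=1e-15)

    def test_heterozygote_reduces_to_2pq_at_zero_theta(self):
        f = {"10": 0.5, "11": 0.5}
        assert rmp.rmp_locus(("10", "11"), f, 0.0) == pytest.approx(0.5, abs=1e-15)

    def test_homozygote_approaches_one_at_full_correlation(self):
        v = rmp.rmp_locus(("10", "10"), {"10": 0.05, "11": 0.95}, 1.0 - 1e-9)
        assert v == pytest.approx(1.0, abs=1e-6)

    def test_homozygote_worked_value(self):
        # [2F+(1-F)p][3F+(1-F)p]/[(1+F)(1+2F)] at p=0.1, F=0.01
        v = rmp.rmp_locus(("10", "10"), {"10": 0.1, "11": 0.9}, 0.01)
        assert v == pytest.approx(0.119 * 0.129 / 1.0302, abs=1e-12)
        assert v == pytest.approx(0.014901, abs=5e-7)

    def test_heterozygote_worked_value(self):
        v = rmp.rmp_locus(("10", "11"), {"10": 0.1, "11": 0.2, "12": 0.7}, 0.01)
        assert v == pytest.approx(2 * 0.109 * 0.208 / 1.0302, abs=1e-12)
        assert v == pytest.approx(0.044015, abs=5e-7)

    def test_strictly_increasing_in_theta_for_rare_alleles(self):
        grid = np.linspace(0.0, 0.3, 61)
        for pa, pb in [(0.05, 0.1), (0.2, 0.3), (0.32, 0.1)]:
            fmap = {"a": pa, "b": pb, "c": 1 - pa - pb}
            het = [rmp.rmp_locus(("a", "b"), fmap, F) for F in grid]
            hom = [rmp.rmp_locus(("a", "a"), fmap, F) for F in grid]
            assert all(x < y for x, y in zip(het, het[1:]))
            assert all(x < y for x, y in zip(hom, hom[1:]))

    def test_unseen_allele_strict_policy(self):
        with pytest.raises(rmp.UnseenAlleleError):
            rmp.rmp_locus(("10", "12"), {"10": 1.0}, 0.0)

    def test_unseen_allele_floor_policy(self):
        v = rmp.rmp_locus(("10", "12"), {"10": 0.999, "11": 0.001}, 0.0,
                          rare_allele_floor=0.005)
        assert v == pytest.approx(2 * 0.999 * 0.005)


class TestRmpProfile:
    def _db(self):
        return AlleleFrequencyTable({
            "L1": LocusFrequencies({"10": 0.2, "11": 0.3, "12": 0.5}, 400),
            "L2": LocusFrequencies({"8": 0.5, "9": 0.5}, 400),
        })

    def test_single_locus_heterozygote(self):
        res = rmp.rmp_profile({"L1": ("10", "11")}, self._db(), 0.0, ["L1"])
        assert res.total == pytest.approx(0.12, abs=1e-15)

    def test_total_is_product_of_loci(self):
        db = self._db()
        res = rmp.rmp_profile({"L1": ("10", "11"), "L2": ("8", "8")}, db, 0.01,
                              ["L1", "L2"])
        assert res.total == pytest.approx(
            res.per_locus["L1"] * res.per_locus["L2"], abs=1e-18
        )

    def test_untyped_loci_skipped(self):
        res = rmp.rmp_profile({"L1": ("10", "11")}, self._db(), 0.0, ["L1", "L2"])
        assert set(res.per_locus) == {"L1"}

    def test_no_usable_loci_is_error(self):
        with pytest.raises(StrpopError):
            rmp.rmp_profile({}, self._db(), 0.0, ["L1"])


class TestFilterUnseen:
    def _cohort(self, n=205, n_unseen=9):
        model = simulate.default_model(seed=21, n_autosomal=5, n_x=0,
                                       cognate_sex_counts=(n, 0),
                                       noncognate_sex_counts=(50, 0))
        table = simulate.simulate_population(model).subset(populations=["cognate"])
        ref = frequency_table_from_genotypes(table)
        # hand exactly n_unseen samples an allele the reference lacks
        calls = dict(table.calls)
        for s in table.samples[:n_unseen]:
            calls[(s.sample_id, "CSF1PO")] = ("98", "99")
        return GenotypeTable(list(table.samples), calls, list(table.panel)), ref

    def test_removal_count_and_reasons(self):
        cohort, ref = self._cohort()
        kept, removed = rmp.filter_unseen(cohort, ref)
        assert len(removed) == 9
        assert len(kept.samples) == 196
        for hits in removed.values():
            assert ("CSF1PO", "99") in hits

    def test_clean_cohort_kept_whole(self):
        cohort, ref = self._cohort(n_unseen=0)
        kept, removed = rmp.filter_unseen(cohort, ref)
        assert removed == {}
        assert len(kept.samples) == len(cohort.samples)


class TestDStatistic:
    def test_equal_rmps(self):
        assert rmp.d_statistic(1e-8, 1e-8) == 0.0

    def test_overstated_evidence_positive(self):
        assert rmp.d_statistic(1e-8, 1e-10) == pytest.approx(2.0)

    def test_understated_evidence_negative(self):
        assert rmp.d_statistic(1e-10, 1e-8) == pytest.approx(-2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(StrpopError):
            rmp.d_statistic(0.0, 1e-8)


class TestDSummary:
    def test_hand_computed_summary(self):
        rep = rmp.d_summary([-0.5, 0.2, 0.7, 1.5, 2.5])
        assert rep.proportions == {0.0: 80.0, 0.5: 60.0, 1.0: 40.0, 2.0: 20.0}
        assert rep.mean_d == pytest.approx(0.88)
        assert rep.sd_d == pytest.approx(1.1628, abs=5e-5)

    def test_all_zero(self):
        rep = rmp.d_summary([0.0, 0.0, 0.0])
        assert all(v == 0.0 for v in rep.proportions.values())
        assert rep.mean_d == 0.0 and rep.sd_d == 0.0

    def test_single_value_sd_noted(self):
        rep = rmp.d_summary([1.0])
        assert rep.proportions == {0.0: 100.0, 0.5: 100.0, 1.0: 0.0, 2.0: 0.0}
        assert rep.sd_d == 0.0
        assert "SD undefined" in rep.note

    @settings(deadline=None, max_examples=50)
    @given(hst.lists(hst.floats(-5, 5), min_size=1, max_size=40))
    def test_proportions_non_increasing_in_threshold(self, values):
        rep = rmp.d_summary(values)
        props = [rep.proportions[t] for t in sorted(rep.thresholds)]
        assert all(a >= b for a, b in zip(props, props[1:]))
        assert rep.sd_d >= 0.0


class TestAudit:
    def test_self_comparison_is_centred_at_zero(self):
        model = simulate.default_model(seed=31, F=0.0, n_autosomal=8, n_x=0,
                                       cognate_sex_counts=(100, 0),
                                       noncognate_sex_counts=(100, 0))
        table = simulate.simulate_population(model)
        cohort = table.subset(populations=["cognate"])
        db = frequency_table_from_genotypes(table, populations=["cognate"])
        [rep] = rmp.audit(cohort, db, db, [0.0])
        assert rep.mean_d == pytest.approx(0.0, abs=1e-12)
        assert rep.proportions[0.0] == 0.0

    def test_uncorrected_audit_overstates_then_correction_shrinks(self):
        model = simulate.default_model(seed=33, F=0.01, n_x=0,
                                       cognate_sex_counts=(110, 95),
                                       noncognate_sex_counts=(1000, 1000))
        table = simulate.simulate_population(model)
        cohort = table.subset(populations=["cognate"])
        cog = frequency_table_from_genotypes(table, populations=["cognate"])
        non = frequency_table_from_genotypes(table, populations=["noncognate"])
        uncorrected, corrected = rmp.audit(cohort, cog, non, [0.0, 0.01])
        assert uncorrected.mean_d > 0.0
        assert corrected.proportions[0.0] < uncorrected.proportions[0.0]

    def test_deterministic(self):
        model = simulate.default_model(seed=35, F=0.01, n_autosomal=6, n_x=0,
                                       cognate_sex_counts=(60, 0),
                                       noncognate_sex_counts=(200, 0))
        table = simulate.simulate_population(model)
        cohort = table.subset(populations=["cognate"])
        cog = frequency_table_from_genotypes(table, populations=["cognate"])
        non = frequency_table_from_genotypes(table, populations=["noncognate"])
        r1 = rmp.audit(cohort, cog, non, [0.0, 0.0016])
        r2 = rmp.audit(cohort, cog, non, [0.0, 0.0016])
        assert [x.d_values for x in r1] == [x.d_values for x in r2]
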