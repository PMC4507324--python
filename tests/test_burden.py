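"""Burden counting, distribution summaries, group tables and the rank test."""

import numpy as np
import pytest
from scipy import stats

from carrierburden import burden
from carrierburden.burden import (
    group_summaries,
    maf_rank_test,
    per_individual_counts,
    standard_predicates,
    summarize,
)
from carrierburden.ingest import Genotype, Individual
from carrierburden.panels import GenePanel, Inheritance, PanelGene

from conftest import make_call, make_variant


def panel_of(*symbols):
    return GenePanel.from_genes(
        "p", (PanelGene(s, Inheritance.AR) for s in symbols)
    )


def always(v, call):
    return True


def never(v, call):
    return False


class TestPerIndividualCounts:
    def test_sites_counted_once_regardless_of_zygosity(self):
        """Three het sites plus one hom-alt site -> count 4."""
        inds = [Individual("a", "female", "g")]
        variants = [
            make_variant(pos=100 + i, gene="G1", calls={"a": make_call(Genotype.HET)})
            for i in range(3)
        ] + [make_variant(pos=200, gene="G1", calls={"a": make_call(Genotype.HOM_ALT)})]
        counts = per_individual_counts(variants, inds, panel_of("G1"), always)
        assert counts.tolist() == [4]
        dosage = per_individual_counts(
            variants, inds, panel_of("G1"), always, count_alleles=True
        )
        assert dosage.tolist() == [5]

    def test_false_predicate_gives_zero_vector(self):
        inds = [Individual("a", "female", "g"), Individual("b", "male", "g")]
        variants = [make_variant(calls={"a": make_call(Genotype.HET)})]
        counts = per_individual_counts(variants, inds, panel_of("GENE1"), never)
        assert counts.tolist() == [0, 0]

    def test_shared_site_counts_for_each_carrier(self):
        inds = [Individual("a", "female", "g"), Individual("b", "male", "g")]
        variants = [
            make_variant(
                calls={"a": make_call(Genotype.HET), "b": make_call(Genotype.HET)}
            )
        ]
        counts = per_individual_counts(variants, inds, panel_of("GENE1"), always)
        assert counts.tolist() == [1, 1]

    def test_off_panel_genes_ignored(self):
        inds = [Individual("a", "female", "g")]
        variants = [make_variant(gene="OTHER", calls={"a": make_call(Genotype.HET)})]
        counts = per_individual_counts(variants, inds, panel_of("GENE1"), always)
        assert counts.tolist() == [0]

    def test_qc_failing_carrier_not_counted(self):
        inds = [Individual("a", "female", "g")]
        variants = [
            make_variant(calls={"a": make_call(Genotype.HET, posterior=0.90)})
        ]
        counts = per_individual_counts(variants, inds, panel_of("GENE1"), always)
        assert counts.tolist() == [0]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            per_individual_counts([], [], panel_of("G1"), always)


class TestSummarize:
    def test_basic_summary(self):
        s = summarize([0, 1, 2])
        assert s.mean == pytest.approx(1.0)
        assert s.median == 1
        assert s.fraction_ge1 == pytest.approx(2 / 3)
        assert s.histogram == {0: 1, 1: 1, 2: 1}

    def test_histogram_sums_to_cohort_size(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, 500)
        s = summarize(counts)
        assert sum(s.histogram.values()) == 500
        assert s.fraction_ge1 == pytest.approx((500 - s.histogram.get(0, 0)) / 500)

    def test_printed_average_for_sf_nonsynonymous_burden(self):
        """23,892 variant occurrences across 11,068 exomes average to 2.2."""
        counts = np.full(11068, 2)
        counts[:1756] = 3
        assert counts.sum() == 23892
        s = summarize(counts)
        assert s.mean == pytest.approx(23892 / 11068)
        assert round(s.mean, 1) == 2.2

    def test_printed_average_for_sf_deleterious_burden(self):
        """8167 occurrences across 11,068 exomes average to 0.74."""
        counts = np.zeros(11068, dtype=int)
        counts[:5674] = 1  # 51% of individuals carry at least one
        counts[:2493] += 1
        assert counts.sum() == 8167
        s = summarize(counts)
        assert round(s.mean, 2) == 0.74
        assert round(s.fraction_ge1, 2) == 0.51

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestGroupSummaries:
    def _cohort(self):
        inds = [
            Individual("a1", "female", "ga"),
            Individual("a2", "male", "ga"),
            Individual("b1", "female", "gb"),
        ]
        variants = [
            make_variant(
                pos=100,
                calls={
                    "a1": make_call(Genotype.HET),
                    "a2": make_call(Genotype.HOM_REF),
                    "b1": make_call(Genotype.HOM_ALT),
                },
            ),
            make_variant(
                pos=200,
                calls={
                    "a1": make_call(Genotype.HET),
                    "a2": make_call(Genotype.HET),
                    "b1": make_call(Genotype.HOM_REF),
                },
            ),
        ]
        return inds, variants

    def test_per_group_matches_direct_computation(self):
        inds, variants = self._cohort()
        out = group_summaries(variants, inds, panel_of("GENE1"), {"any": always})
        assert out[("ga", "any")].mean == pytest.approx(1.5)  # counts 2 and 1
        assert out[("gb", "any")].mean == pytest.approx(1.0)

    def test_single_group_equals_summarize(self):
        inds, variants = self._cohort()
        inds = [Individual(i.id, i.sex, "same") for i in inds]
        out = group_summaries(variants, inds, panel_of("GENE1"), {"any": always})
        direct = summarize(
            per_individual_counts(variants, inds, panel_of("GENE1"), always)
        )
        assert out[("same", "any")] == direct

    def test_order_invariance(self):
        inds, variants = self._cohort()
        fwd = group_summaries(variants, inds, panel_of("GENE1"), {"any": always})
        rev = group_summaries(variants, inds[::-1], panel_of("GENE1"), {"any": always})
        assert fwd == rev

    def test_pooled_mean_reproduces_whole_cohort(self, small_cohort):
        """Group means weighted by group size equal the cohort-wide mean."""
        preds = standard_predicates(small_cohort.transcripts)
        pred = {"rare_nonsynonymous": preds["rare_nonsynonymous"]}
        out = group_summaries(
            small_cohort.variants, small_cohort.individuals, small_cohort.panels["AR"], pred
        )
        pooled = sum(
            s.mean * s.n for (g, _), s in out.items()
        ) / sum(s.n for s in out.values())
        whole = summarize(
            per_individual_counts(
                small_cohort.variants,
                small_cohort.individuals,
                small_cohort.panels["AR"],
                pred["rare_nonsynonymous"],
            )
        )
        assert pooled == pytest.approx(whole.mean, abs=1e-12)


class TestOccurrenceConservation:
    def test_sum_of_counts_equals_sum_of_carriers(self, small_cohort):
        """Sum over individuals of burden = sum over variants of carriers."""
        preds = standard_predicates(small_cohort.transcripts)
        panel = small_cohort.panels["AR"]
        pred = preds["rare_nonsynonymous"]
        counts = per_individual_counts(
            small_cohort.variants, small_cohort.individuals, panel, pred
        )
        ids = {i.id for i in small_cohort.individuals}
        carrier_total = 0
        for v in small_cohort.variants:
            if v.gene not in panel:
                continue
            for sid, call in v.calls.items():
                if (
                    sid in ids
                    and call.genotype.carries_alt
                    and burden.call_passes_qc(call)
                    and pred(v, call)
                ):
                    carrier_total += 1
        assert counts.sum() == carrier_total
        assert counts.sum() > 0


class TestMafRankTest:
    def test_identical_samples_give_p_one(self):
        stat, p = maf_rank_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        """Exact enumeration over the 20 rank assignments gives p = 0.1."""
        stat, p = maf_rank_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert stat == 0.0

    def test_shift_weakly_decreases_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40).tolist()
        b = rng.normal(0, 1, 40).tolist()
        _, p_null = maf_rank_test(a, b)
        _, p_shift = maf_rank_test(a, [x + 3 for x in b])
        assert p_shift <= p_null

    def test_exact_branch_agrees_with_scipy_on_tie_free_data(self):
        """Independent cross-check against scipy's exact enumeration."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.permutation(100)[:6].tolist()
            b = (rng.permutation(100)[:7] + 0.5).tolist()
            stat, p = maf_rank_test(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-9)
            assert stat == pytest.approx(ref.statistic)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.exponential(1.0, 200)
        b = rng.exponential(1.3, 200)
        stat, p = maf_rank_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            maf_rank_test([], [1.0])


class TestMeanBurdenConvergence:
    def test_mean_burden_matches_hwe_expectation(self, small_cohort):
        """Measured mean approaches sum of per-variant carrier probabilities."""
        truth = small_cohort.truth
        preds = standard_predicates(small_cohort.transcripts)
        counts = per_individual_counts(
            small_cohort.variants,
            small_cohort.individuals,
            small_cohort.panels["AR"],
            preds["rare_nonsynonymous"],
        )
        expected = truth.expected_mean_burden("AR", "rare_nonsynonymous")
        se = truth.mean_burden_se("AR", "rare_nonsynonymous")
        assert abs(counts.mean() - expected) <= 3 * se
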