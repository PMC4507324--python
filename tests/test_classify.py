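"""Classification cascade: rarity, deleteriousness, NMD escape, ClinVar/HGMD."""

import itertools
from collections import Counter

import numpy as np
import pytest

from carrierburden import classify
from carrierburden.classify import (
    OutsideCdsError,
    clinvar_pathogenic,
    hgmd_dm,
    is_nmd_escaping,
    is_nonsynonymous,
    is_novel,
    is_predicted_deleterious,
    is_rare,
    passes_deleterious_call_qc,
)
from carrierburden.ingest import Genotype
from carrierburden.panels import TranscriptModel

from conftest import make_call, make_transcript, make_variant


class TestNonsynonymous:
    @pytest.mark.parametrize(
        "fclass,expected",
        [
            ("missense", True),
            ("stop_gain", True),
            ("stop_loss", True),
            ("synonymous", False),
            ("other", False),
        ],
    )
    def test_class_membership(self, fclass, expected):
        assert is_nonsynonymous(make_variant(functional_class=fclass)) is expected


class TestRarity:
    def test_common_in_control_database_fails(self):
        v = make_variant(control_afs={"thousand_genomes": 0.015}, cohort_maf=0.001)
        assert not is_rare(v)

    def test_absent_control_record_counts_as_zero(self):
        assert is_rare(make_variant(control_afs={}, cohort_maf=0.019))

    def test_boundaries_pass(self):
        """Strict '>' exclusions: exactly 1% control and 2% cohort are kept."""
        v = make_variant(
            control_afs={"thousand_genomes": 0.01, "esp": 0.01}, cohort_maf=0.02
        )
        assert is_rare(v)

    def test_common_in_cohort_fails(self):
        assert not is_rare(make_variant(cohort_maf=0.021))

    def test_missing_cohort_maf_raises(self):
        with pytest.raises(ValueError):
            is_rare(make_variant(cohort_maf=None))


class TestDeleteriousCallQc:
    def test_low_depth_fails(self):
        assert not passes_deleterious_call_qc(make_call(depth=19, alt_reads=10))

    def test_boundary_passes(self):
        assert passes_deleterious_call_qc(make_call(depth=20, alt_reads=4))

    def test_low_alt_ratio_fails(self):
        assert not passes_deleterious_call_qc(make_call(depth=100, alt_reads=19))


class TestClinvarResolution:
    @pytest.mark.parametrize(
        "assertions,expected",
        [
            (["pathogenic"], True),
            (["pathogenic", "benign"], False),
            (["likely_pathogenic"], False),
            (["likely_pathogenic", "pathogenic"], True),
            ([], False),
            (["uncertain"], False),
            (["pathogenic", "likely_benign"], False),
            (["pathogenic", "uncertain", "other"], True),
        ],
    )
    def test_rule_examples(self, assertions, expected):
        assert clinvar_pathogenic(Counter(assertions)) is expected

    def test_exhaustive_truth_table_matches_brute_force(self):
        """All assertion multisets of size <= 3 against a literal oracle."""
        terms = ["pathogenic", "likely_pathogenic", "uncertain", "likely_benign", "benign", "other"]

        def oracle(multiset):
            no_benign = all(t not in ("benign", "likely_benign") for t in multiset)
            some_pathogenic = any(t == "pathogenic" for t in multiset)
            return no_benign and some_pathogenic

        n_checked = 0
        for size in range(4):
            for combo in itertools.combinations_with_replacement(terms, size):
                assert clinvar_pathogenic(Counter(combo)) == oracle(combo), combo
                n_checked += 1
        assert n_checked == 1 + 6 + 21 + 56


class TestReportedPathogenicAndNovel:
    def test_hgmd_dm_classes(self):
        assert hgmd_dm(make_variant(hgmd_class="DM"))
        assert not hgmd_dm(make_variant(hgmd_class="other"))
        assert not hgmd_dm(make_variant(hgmd_class="absent"))

    def test_novel_requires_absence_from_both_databases(self):
        assert is_novel(make_variant(control_afs={}))
        assert not is_novel(make_variant(control_afs={"thousand_genomes": 0.0}))
        assert not is_novel(
            make_variant(control_afs={"thousand_genomes": 0.001, "esp": 0.001})
        )


def nmd_walker_oracle(pos, transcript):
    """Base-by-base coding-coordinate walk, independent of the implementation.

    Enumerates every coding base in transcript (5'->3') order with its exon
    index, then applies the rule literally: escape iff the base is in the
    last exon, or in the penultimate exon among its final 50 coding bases.
    """
    walk = []  # (genomic position, exon index in transcript order)
    coding = transcript.coding_intervals()
    if transcript.strand == "+":
        for idx, (start, end) in enumerate(coding):
            for g in range(start, end):
                walk.append((g, idx))
    else:
        for idx, (start, end) in enumerate(reversed(coding)):
            for g in range(end - 1, start - 1, -1):
                walk.append((g, idx))
    n_exons = len(coding)
    positions = {g: i for i, (g, _) in enumerate(walk)}
    if pos - 1 not in positions:
        raise OutsideCdsError(str(pos))
    i = positions[pos - 1]
    exon_idx = walk[i][1]
    if exon_idx == n_exons - 1:
        return True
    if exon_idx == n_exons - 2:
        remaining_in_exon = sum(
            1 for j in range(i, len(walk)) if walk[j][1] == exon_idx
        )
        return remaining_in_exon <= 50
    return False


def stop_at(pos, gene="GENE1"):
    return make_variant(pos=pos, gene=gene, functional_class="stop_gain")


class TestNmdEscape:
    def test_last_exon_escapes(self):
        tx = make_transcript()  # + strand, 3 exons ending at 1900
        assert is_nmd_escaping(stop_at(1700), tx)

    def test_deep_in_penultimate_exon_degrades(self):
        tx = make_transcript()  # penultimate exon (800,1100): 300 coding bases
        # 60 coding bases before the 3' end: genomic 0-based 1100-60=1040 -> pos 1041
        assert not is_nmd_escaping(stop_at(1041), tx)

    def test_exactly_50_bases_from_junction_escapes(self):
        tx = make_transcript()
        # distance 50 inclusive: 0-based 1050 -> 1-based 1051
        assert is_nmd_escaping(stop_at(1051), tx)
        assert not is_nmd_escaping(stop_at(1050), tx)  # distance 51

    def test_reverse_strand_first_genomic_exon_is_transcript_last(self):
        tx = make_transcript(strand="-")
        assert is_nmd_escaping(stop_at(100), tx)
        assert not is_nmd_escaping(stop_at(1800), tx)  # transcript-first exon

    def test_single_exon_transcript_always_escapes(self):
        tx = make_transcript(exons=((0, 900),))
        assert is_nmd_escaping(stop_at(450), tx)

    def test_outside_cds_raises(self):
        tx = make_transcript(cds_start=100, cds_end=1800)
        with pytest.raises(OutsideCdsError):
            is_nmd_escaping(stop_at(50), tx)

    def test_non_stop_gain_rejected(self):
        with pytest.raises(ValueError):
            is_nmd_escaping(make_variant(functional_class="missense"), make_transcript())

    def test_agreement_with_walker_oracle_on_random_transcripts(self):
        """200 random transcripts (1-10 exons, both strands), every coding base."""
        rng = np.random.default_rng(42)
        checked = 0
        for t in range(200):
            n_exons = int(rng.integers(1, 11))
            exons = []
            cursor = int(rng.integers(0, 50))
            for _ in range(n_exons):
                length = int(rng.integers(20, 120))
                exons.append((cursor, cursor + length))
                cursor += length + int(rng.integers(30, 200))
            span_start, span_end = exons[0][0], exons[-1][1]
            cds_start = span_start + int(rng.integers(0, 15))
            cds_end = span_end - int(rng.integers(0, 15))
            tx = TranscriptModel(
                gene=f"T{t}",
                chrom="1",
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
            coding_positions = [
                g for s, e in tx.coding_intervals() for g in range(s, e)
            ]
            sample = rng.choice(coding_positions, size=min(40, len(coding_positions)), replace=False)
            for pos0 in sample:
                variant = stop_at(int(pos0) + 1)
                assert is_nmd_escaping(variant, tx) == nmd_walker_oracle(int(pos0) + 1, tx)
                checked += 1
        assert checked > 1000


class TestPredictedDeleterious:
    def test_rare_deleterious_missense_qualifies(self):
        v = make_variant(radialsvm_call="deleterious")
        assert is_predicted_deleterious(v, None, make_call(depth=40, alt_reads=20))

    def test_tolerated_missense_does_not_qualify(self):
        v = make_variant(radialsvm_call="tolerated")
        assert not is_predicted_deleterious(v, None, make_call(depth=40, alt_reads=20))

    def test_last_exon_stop_gain_excluded(self):
        v = stop_at(1700)
        assert not is_predicted_deleterious(v, make_transcript(), make_call(depth=40, alt_reads=20))

    def test_nmd_degraded_stop_gain_qualifies(self):
        v = stop_at(100)
        assert is_predicted_deleterious(v, make_transcript(), make_call(depth=40, alt_reads=20))

    def test_stop_loss_auto_qualifies_without_prediction(self):
        v = make_variant(functional_class="stop_loss", radialsvm_call="absent")
        assert is_predicted_deleterious(v, None, make_call(depth=40, alt_reads=20))

    def test_common_variant_gated_by_rarity(self):
        v = make_variant(
            functional_class="stop_gain", control_afs={"esp": 0.05}, pos=100
        )
        assert not is_predicted_deleterious(v, make_transcript(), make_call(depth=40, alt_reads=20))

    def test_failing_read_support_gates(self):
        v = make_variant(radialsvm_call="deleterious")
        assert not is_predicted_deleterious(v, None, make_call(depth=19, alt_reads=10))


class TestSubsetChain:
    def test_deleterious_subset_of_rare_nonsynonymous(self, small_cohort):
        """{predicted deleterious} <= {rare nonsynonymous} <= {nonsynonymous}."""
        deleterious = set()
        rare_nonsyn = set()
        nonsyn = set()
        for v in small_cohort.variants:
            tx = small_cohort.transcripts.get(v.gene)
            if is_nonsynonymous(v):
                nonsyn.add(v.site)
                if is_rare(v):
                    rare_nonsyn.add(v.site)
            if classify.variant_predicted_deleterious(v, tx):
                deleterious.add(v.site)
        assert deleterious <= rare_nonsyn <= nonsyn
        assert len(nonsyn) > 0
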