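"""Shared builders and fixtures for the carrierburden test suite."""

from collections import Counter

import pytest

from carrierburden.ingest import AnnotatedVariant, Genotype, SampleCall
from carrierburden.panels import TranscriptModel
from carrierburden import synthetic


def make_call(
    genotype=Genotype.HET,
    depth=60,
    alt_reads=None,
    alt_fwd=None,
    posterior=0.99,
):
    """A QC-clean call by default; override fields to probe the rules."""
    if alt_reads is None:
        alt_reads = {
            Genotype.HOM_REF: 0,
            Genotype.HET: depth // 2,
            Genotype.HOM_ALT: depth,
            Genotype.HEMI_ALT: depth,
            Genotype.HEMI_REF: 0,
            Genotype.MISSING: 0,
        }[genotype]
    if alt_fwd is None:
        alt_fwd = alt_reads // 2
    return SampleCall(
        genotype=genotype,
        depth=depth,
        alt_reads=alt_reads,
        alt_fwd=alt_fwd,
        alt_rev=alt_reads - alt_fwd,
        posterior=posterior,
    )


def make_variant(
    chrom="1",
    pos=1000,
    gene="GENE1",
    functional_class="missense",
    control_afs=None,
    radialsvm_call="absent",
    clinvar=(),
    hgmd_class="absent",
    calls=None,
    cohort_maf=0.001,
):
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        gene=gene,
        functional_class=functional_class,
        control_afs=control_afs or {},
        radialsvm_call=radialsvm_call,
        clinvar_submissions=Counter(clinvar),
        hgmd_class=hgmd_class,
        calls=calls or {},
        cohort_maf=cohort_maf,
    )


def make_transcript(gene="GENE1", chrom="1", strand="+", exons=((0, 300), (800, 1100), (1600, 1900)), cds_start=None, cds_end=None):
    exons = tuple(exons)
    return TranscriptModel(
        gene=gene,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=exons[0][0] if cds_start is None else cds_start,
        cds_end=exons[-1][1] if cds_end is None else cds_end,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by invariant-style tests."""
    config = synthetic.SimConfig(
        seed=20,
        groups=(
            synthetic.GroupSpec("ea", 250, 0.5, 1.0),
            synthetic.GroupSpec("aa", 150, 0.5, 1.3),
        ),
        n_sf_genes=12,
        n_ar_genes=25,
        n_xlr_genes=8,
        mean_variants_per_gene=3.0,
        p_clinvar_pathogenic=0.15,
        p_hgmd_dm=0.2,
        af_range=(1e-4, 0.02),
    )
    cohort = synthetic.simulate_cohort(config)
    from carrierburden.ingest import annotate_cohort_mafs

    annotate_cohort_mafs(cohort.variants)
    return cohort
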