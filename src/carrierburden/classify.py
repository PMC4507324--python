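"""Variant classification cascade.

Variants are flagged along independent axes, mirroring how a clinical
carrier-screening analysis whittles an exome down to reportable findings:

* **nonsynonymous** — missense, stop-gain (nonsense) or stop-loss;
* **rare** — at most 1% allele frequency in each control database
  (1000 Genomes, ESP) and at most 2% in the study cohort;
* **predicted deleterious** — rare nonsynonymous variants that survive the
  stricter read-support QC (>=20x depth, alt-read ratio >= 0.2) and are
  either stop-loss, stop-gain outside presumed NMD-escaping regions, or
  missense called deleterious by the RadialSVM ensemble predictor (dbNSFP);
* **reported pathogenic** — ClinVar (conflict-resolved across submitters)
  or HGMD class DM;
* **novel** — absent from both control databases (no record at all).

Nonsense-mediated decay (NMD) escape uses the standard 50-nucleotide rule:
a premature stop in the transcript-orientation last exon, or within the
last 50 coding bases of the penultimate exon, typically escapes transcript
surveillance and may produce a truncated protein rather than none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .ingest import AnnotatedVariant, SampleCall, call_passes_qc
from .panels import TranscriptModel

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "ClassificationFlags",
    "OutsideCdsError",
    "is_nonsynonymous",
    "is_rare",
    "passes_deleterious_call_qc",
    "is_nmd_escaping",
    "is_predicted_deleterious",
    "variant_predicted_deleterious",
    "clinvar_pathogenic",
    "hgmd_dm",
    "is_novel",
    "classify_variant",
    "flags_table",
]

NONSYNONYMOUS_CLASSES = frozenset({"missense", "stop_gain", "stop_loss"})

MAX_CONTROL_AF = 0.01
MAX_COHORT_MAF = 0.02
MIN_DELETERIOUS_DEPTH = 20
MIN_ALT_RATIO = 0.2
NMD_ESCAPE_WINDOW = 50  # coding bases at the 3' end of the penultimate exon


class OutsideCdsError(ValueError):
    """NMD assessment requested for a position outside the transcript CDS."""


def is_nonsynonymous(variant: AnnotatedVariant) -> bool:
    return variant.functional_class in NONSYNONYMOUS_CLASSES


def is_rare(variant: AnnotatedVariant) -> bool:
    """Rarity filter: <=1% in every control database and <=2% in the cohort.

    Both published thresholds are strict exclusions (">1%", ">2%"), so
    boundary frequencies pass. A control database with no record for the
    variant contributes frequency 0. The cohort MAF must have been computed
    (see :func:`carrierburden.ingest.annotate_cohort_mafs`).
    """
    if variant.cohort_maf is None:
        raise ValueError("cohort_maf not computed; run annotate_cohort_mafs first")
    if any(af > MAX_CONTROL_AF for af in variant.control_afs.values()):
        return False
    return variant.cohort_maf <= MAX_COHORT_MAF


def passes_deleterious_call_qc(
    call: SampleCall,
    *,
    min_depth: int = MIN_DELETERIOUS_DEPTH,
    min_alt_ratio: float = MIN_ALT_RATIO,
) -> bool:
    """Stricter read-support QC applied when building the deleterious set.

    Excludes calls with depth < 20 or alt-read ratio < 0.2 (boundaries
    pass); zero depth fails.
    """
    if call.depth < min_depth or call.depth == 0:
        return False
    return call.alt_reads / call.depth >= min_alt_ratio


def is_nmd_escaping(variant: AnnotatedVariant, transcript: TranscriptModel) -> bool:
    """Whether a stop-gain variant likely escapes nonsense-mediated decay.

    True iff the variant lies in the transcript-orientation last coding
    exon, or within the last ``NMD_ESCAPE_WINDOW`` coding bases (inclusive)
    of the penultimate coding exon at its 3' end. Single-coding-exon
    transcripts have no downstream junction, so every stop escapes.
    """
    if variant.functional_class != "stop_gain":
        raise ValueError("NMD escape is defined for stop-gain variants only")
    pos0 = variant.pos - 1
    coding = transcript.coding_intervals()
    exon_index = None
    for idx, (start, end) in enumerate(coding):
        if start <= pos0 < end:
            exon_index = idx
            break
    if exon_index is None:
        raise OutsideCdsError(
            f"{variant.chrom}:{variant.pos} outside CDS of {transcript.gene}"
        )
    if transcript.strand == "-":
        coding = coding[::-1]
        exon_index = len(coding) - 1 - exon_index
    if len(coding) == 1 or exon_index == len(coding) - 1:
        return True
    if exon_index == len(coding) - 2:
        start, end = coding[exon_index]
        if transcript.strand == "+":
            dist_from_3p = end - pos0  # last base of the exon has distance 1
        else:
            dist_from_3p = pos0 - start + 1
        return dist_from_3p <= NMD_ESCAPE_WINDOW
    return False


def is_predicted_deleterious(
    variant: AnnotatedVariant,
    transcript: Optional[TranscriptModel],
    call: SampleCall,
) -> bool:
    """Per-call predicted-deleterious status.

    Requires rarity and the stricter call QC, then branches on functional
    class: stop-loss qualifies outright, stop-gain qualifies unless it
    escapes NMD, and missense qualifies only with a deleterious RadialSVM
    call. RadialSVM scores missense variants only, so it does not gate the
    stop classes. A stop-gain without a transcript model cannot be assessed
    for NMD escape and is excluded conservatively.
    """
    if not is_nonsynonymous(variant) or not is_rare(variant):
        return False
    if not passes_deleterious_call_qc(call):
        return False
    fclass = variant.functional_class
    if fclass == "stop_loss":
        return True
    if fclass == "stop_gain":
        if transcript is None:
            return False
        return not is_nmd_escaping(variant, transcript)
    return variant.radialsvm_call == "deleterious"


def variant_predicted_deleterious(
    variant: AnnotatedVariant,
    transcript: Optional[TranscriptModel],
) -> bool:
    """Variant-level deleterious flag: >=1 carrier with a qualifying call."""
    return any(
        call.genotype.carries_alt
        and call_passes_qc(call)
        and is_predicted_deleterious(variant, transcript, call)
        for call in variant.calls.values()
    )


def clinvar_pathogenic(assertions: Mapping[str, int]) -> bool:
    """Resolve possibly discordant ClinVar submitter assertions.

    A variant counts as reported pathogenic iff (i) no submitter called it
    benign or likely benign, and (ii) at least one submitter called it
    pathogenic. Likely-pathogenic alone does not qualify; star ratings are
    ignored. A variant with only uncertain/other assertions is simply
    non-pathogenic.
    """
    if assertions.get("benign", 0) or assertions.get("likely_benign", 0):
        return False
    return assertions.get("pathogenic", 0) >= 1


def hgmd_dm(variant: AnnotatedVariant) -> bool:
    """Reported pathogenic per HGMD: class 'Disease-causing Mutation' only."""
    return variant.hgmd_class == "DM"


def is_novel(variant: AnnotatedVariant) -> bool:
    """Absent from both control databases (no record, not even AF 0)."""
    return not variant.control_afs


@dataclass(frozen=True)
class ClassificationFlags:
    """Variant-level flag vector produced by :func:`classify_variant`."""

    nonsynonymous: bool
    rare: bool
    predicted_deleterious: bool
    nmd_escaping: Optional[bool]  # None unless stop-gain with a transcript
    clinvar_pathogenic: bool
    hgmd_dm: bool
    novel: bool


def classify_variant(
    variant: AnnotatedVariant,
    transcript: Optional[TranscriptModel] = None,
) -> ClassificationFlags:
    """Run the full cascade for one variant (pure given cohort MAF)."""
    nonsyn = is_nonsynonymous(variant)
    rare = is_rare(variant)
    nmd: Optional[bool] = None
    if variant.functional_class == "stop_gain" and transcript is not None:
        nmd = is_nmd_escaping(variant, transcript)
    return ClassificationFlags(
        nonsynonymous=nonsyn,
        rare=rare,
        predicted_deleterious=variant_predicted_deleterious(variant, transcript),
        nmd_escaping=nmd,
        clinvar_pathogenic=clinvar_pathogenic(variant.clinvar_submissions),
        hgmd_dm=hgmd_dm(variant),
        novel=is_novel(variant),
    )


def flags_table(
    variants: Iterable[AnnotatedVariant],
    transcripts: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """Per-variant flags as a DataFrame (writable as the flags TSV)."""
    rows = []
    for v in variants:
        flags = classify_variant(v, transcripts.get(v.gene))
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "functional_class": v.functional_class,
                "cohort_maf": v.cohort_maf,
                "nonsynonymous": flags.nonsynonymous,
                "rare": flags.rare,
                "predicted_deleterious": flags.predicted_deleterious,
                "nmd_escaping": flags.nmd_escaping,
                "clinvar_pathogenic": flags.clinvar_pathogenic,
                "hgmd_dm": flags.hgmd_dm,
                "novel": flags.novel,
            }
        )
    return pd.DataFrame(rows)
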