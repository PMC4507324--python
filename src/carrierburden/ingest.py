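"""Variant ingestion: VCF reading, call-level QC, capture-design intersection
and cohort allele frequencies.

Coordinate conventions are centralised here: VCF positions are 1-based,
capture (BED) intervals are 0-based half-open, and a variant at 1-based
position ``p`` falls in interval ``[a, b)`` iff ``a <= p - 1 < b``.

Call-level QC follows strict exclusion thresholds — a call is removed when
its posterior probability is below 0.95, its total depth below 10x, or more
than 99% of its variant-supporting reads sit on a single strand — so values
exactly at a threshold pass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "Genotype",
    "SampleCall",
    "AnnotatedVariant",
    "Individual",
    "CaptureRegions",
    "VcfFieldMap",
    "UndefinedFrequencyError",
    "intersect_captures",
    "restrict_to_regions",
    "call_passes_qc",
    "cohort_maf",
    "annotate_cohort_mafs",
    "read_vcf",
    "read_sample_sheet",
]

# Default strict-exclusion thresholds for call-level QC.
MIN_POSTERIOR = 0.95
MIN_DEPTH = 10
MAX_STRAND_FRACTION = 0.99


class UndefinedFrequencyError(ValueError):
    """Cohort allele frequency requested where no genotype was called."""


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    HEMI_REF = "hemi_ref"
    MISSING = "missing"

    @property
    def alt_dose(self) -> int:
        return {
            Genotype.HOM_REF: 0,
            Genotype.HET: 1,
            Genotype.HOM_ALT: 2,
            Genotype.HEMI_ALT: 1,
            Genotype.HEMI_REF: 0,
            Genotype.MISSING: 0,
        }[self]

    @property
    def n_alleles(self) -> int:
        if self is Genotype.MISSING:
            return 0
        if self in (Genotype.HEMI_ALT, Genotype.HEMI_REF):
            return 1
        return 2

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)


@dataclass(frozen=True, slots=True)
class SampleCall:
    """One genotype call with the read-level evidence QC operates on."""

    genotype: Genotype
    depth: int
    alt_reads: int
    alt_fwd: int
    alt_rev: int
    posterior: float

    def __post_init__(self) -> None:
        if self.alt_fwd + self.alt_rev != self.alt_reads:
            raise ValueError("alt_fwd + alt_rev must equal alt_reads")
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads cannot exceed depth")
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must lie in [0, 1]")
        if min(self.depth, self.alt_reads, self.alt_fwd, self.alt_rev) < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class Individual:
    """Cohort member: stable id, sex and ethnicity/stratum label."""

    id: str
    sex: str
    group: str

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass
class AnnotatedVariant:
    """A biallelic SNV with its annotations and per-sample calls.

    ``control_afs`` maps a control-database name (``thousand_genomes``,
    ``esp``) to an allele frequency; absence of a key means the variant has
    no record at all in that database (which is what novelty tests).
    ``clinvar_submissions`` is a multiset of per-submitter assertions.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    functional_class: str
    control_afs: dict[str, float] = field(default_factory=dict)
    radialsvm_call: str = "absent"  # deleterious | tolerated | absent
    clinvar_submissions: Counter = field(default_factory=Counter)
    hgmd_class: str = "absent"  # DM | other | absent
    calls: dict[str, SampleCall] = field(default_factory=dict)
    cohort_maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("VCF positions are 1-based; pos must be >= 1")
        for source, af in self.control_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"control AF for {source!r} outside [0, 1]")

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# Capture regions
# ---------------------------------------------------------------------------


@dataclass
class CaptureRegions:
    """Per-chromosome sorted, merged 0-based half-open intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals: Mapping[str, Iterable[tuple[int, int]]]
    ) -> "CaptureRegions":
        return cls({c: _normalize(list(ivs)) for c, ivs in intervals.items()})

    @classmethod
    def from_bed(cls, path: str | Path) -> "CaptureRegions":
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                raw.setdefault(chrom, []).append((int(start), int(end)))
        return cls.from_intervals(raw)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position (binary search over merged runs)."""
        import bisect

        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        idx = bisect.bisect_right(ivs, (pos0, float("inf"))) - 1
        return idx >= 0 and ivs[idx][0] <= pos0 < ivs[idx][1]

    def total_span(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CaptureRegions):
            return NotImplemented
        a = {c: ivs for c, ivs in self.intervals.items() if ivs}
        b = {c: ivs for c, ivs in other.intervals.items() if ivs}
        return a == b


def _normalize(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge touching/overlapping half-open intervals."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if start >= end:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def intersect_captures(a: CaptureRegions, b: CaptureRegions) -> CaptureRegions:
    """Exact set intersection of two capture designs (two-pointer sweep)."""
    result: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a.intervals) & set(b.intervals):
        ia, ib = a.intervals[chrom], b.intervals[chrom]
        i = j = 0
        merged: list[tuple[int, int]] = []
        while i < len(ia) and j < len(ib):
            start = max(ia[i][0], ib[j][0])
            end = min(ia[i][1], ib[j][1])
            if start < end:
                merged.append((start, end))
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
        if merged:
            result[chrom] = merged
    return CaptureRegions(result)


def restrict_to_regions(
    variants: Iterable[AnnotatedVariant], regions: CaptureRegions
) -> list[AnnotatedVariant]:
    """Keep variants whose 1-based position maps into the 0-based regions."""
    return [v for v in variants if regions.contains(v.chrom, v.pos - 1)]


# ---------------------------------------------------------------------------
# Call-level QC and cohort allele frequency
# ---------------------------------------------------------------------------


def call_passes_qc(
    call: SampleCall,
    *,
    min_posterior: float = MIN_POSTERIOR,
    min_depth: int = MIN_DEPTH,
    max_strand_fraction: float = MAX_STRAND_FRACTION,
) -> bool:
    """Variant-level QC: posterior, depth and strand-bias exclusions.

    Boundaries pass: the published rules exclude posterior < 0.95, depth
    below tenfold, and strictly more than 99% of variant reads on one
    strand. Strand bias is assessed on variant-supporting reads only, so a
    call with zero alt reads trivially passes that sub-rule. Missing
    genotypes fail.
    """
    if call.genotype is Genotype.MISSING:
        return False
    if call.posterior < min_posterior or call.depth < min_depth:
        return False
    if call.alt_reads > 0:
        if max(call.alt_fwd, call.alt_rev) / call.alt_reads > max_strand_fraction:
            return False
    return True


def cohort_maf(
    variant: AnnotatedVariant,
    included_samples: Optional[Sequence[str]] = None,
    *,
    apply_qc: bool = True,
) -> float:
    """Folded minor-allele frequency over called alleles in the cohort.

    Diploid genotypes contribute two alleles, hemizygous ones a single
    allele. Calls failing QC are treated as missing when ``apply_qc`` is
    set (the default — QC precedes every downstream filter). Raises
    :class:`UndefinedFrequencyError` when no allele remains.
    """
    sample_ids = variant.calls.keys() if included_samples is None else included_samples
    alt = total = 0
    for sid in sample_ids:
        call = variant.calls.get(sid)
        if call is None or call.genotype is Genotype.MISSING:
            continue
        if apply_qc and not call_passes_qc(call):
            continue
        alt += call.genotype.alt_dose
        total += call.genotype.n_alleles
    if total == 0:
        raise UndefinedFrequencyError(
            f"no called alleles at {variant.chrom}:{variant.pos}"
        )
    freq = alt / total
    return min(freq, 1.0 - freq)


def annotate_cohort_mafs(
    variants: Iterable[AnnotatedVariant],
    included_samples: Optional[Sequence[str]] = None,
    *,
    apply_qc: bool = True,
) -> None:
    """Set ``cohort_maf`` in place on every variant."""
    for variant in variants:
        variant.cohort_maf = cohort_maf(variant, included_samples, apply_qc=apply_qc)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


@dataclass
class VcfFieldMap:
    """Names of the INFO/FORMAT keys the annotated VCF uses.

    Defaults match the synthetic-cohort writer; real pipelines remap via a
    YAML config (see :meth:`from_yaml`).
    """

    gene: str = "GENE"
    functional_class: str = "FCLASS"
    control_afs: dict[str, str] = field(
        default_factory=lambda: {"thousand_genomes": "AF_1KG", "esp": "AF_ESP"}
    )
    radialsvm: str = "RSVM"
    clinvar: str = "CLNSIG"
    hgmd: str = "HGMD"
    depth: str = "DP"
    alt_reads: str = "VR"
    alt_fwd: str = "SBF"
    alt_rev: str = "SBR"
    posterior: str = "CPP"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VcfFieldMap":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown field-map keys: {sorted(unknown)}")
        return cls(**data)


_CLINVAR_TERMS = {
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "uncertain": "uncertain",
    "uncertain_significance": "uncertain",
    "likely_benign": "likely_benign",
    "benign": "benign",
}


def _parse_assertions(text: Optional[str]) -> Counter:
    if not text or text == ".":
        return Counter()
    out: Counter = Counter()
    for token in str(text).split("|"):
        token = token.strip().lower().replace(" ", "_")
        if token:
            out[_CLINVAR_TERMS.get(token, "other")] += 1
    return out


def _genotype_from_gt(gt: Sequence[int]) -> Genotype:
    alleles = [a for a in gt[:-1] if isinstance(a, int)]  # cyvcf2 appends phase flag
    alleles = [a for a in alleles if a >= 0]
    if not alleles:
        return Genotype.MISSING
    if len(alleles) == 1:
        return Genotype.HEMI_ALT if alleles[0] > 0 else Genotype.HEMI_REF
    n_alt = sum(1 for a in alleles if a > 0)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]


def read_vcf(
    path: str | Path,
    field_map: Optional[VcfFieldMap] = None,
) -> tuple[list[AnnotatedVariant], list[str], Counter]:
    """Read an annotated multi-sample VCF into :class:`AnnotatedVariant` records.

    Only biallelic SNV records are ingested; multi-allelic records (which
    must be decomposed upstream) and non-SNV alleles are skipped and tallied
    in the returned warning counter. Returns (variants, sample ids, warnings).
    """
    from cyvcf2 import VCF

    fm = field_map or VcfFieldMap()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    warnings: Counter = Counter()
    for record in vcf:
        if len(record.ALT) != 1:
            warnings["multiallelic_skipped"] += 1
            continue
        ref, alt = record.REF, record.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            warnings["non_snv_skipped"] += 1
            continue
        control_afs: dict[str, float] = {}
        for source, key in fm.control_afs.items():
            value = record.INFO.get(key)
            if value is not None:
                control_afs[source] = float(value)
        depths = record.format(fm.depth)
        alts = record.format(fm.alt_reads)
        fwds = record.format(fm.alt_fwd)
        revs = record.format(fm.alt_rev)
        posts = record.format(fm.posterior)
        calls: dict[str, SampleCall] = {}
        for i, sid in enumerate(samples):
            genotype = _genotype_from_gt(record.genotypes[i])
            calls[sid] = SampleCall(
                genotype=genotype,
                depth=int(depths[i][0]),
                alt_reads=int(alts[i][0]),
                alt_fwd=int(fwds[i][0]),
                alt_rev=int(revs[i][0]),
                posterior=float(posts[i][0]),
            )
        variants.append(
            AnnotatedVariant(
                chrom=record.CHROM,
                pos=record.POS,
                ref=ref,
                alt=alt,
                gene=record.INFO.get(fm.gene, ""),
                functional_class=record.INFO.get(fm.functional_class, "other"),
                control_afs=control_afs,
                radialsvm_call=record.INFO.get(fm.radialsvm, "absent"),
                clinvar_submissions=_parse_assertions(record.INFO.get(fm.clinvar)),
                hgmd_class=record.INFO.get(fm.hgmd, "absent"),
                calls=calls,
            )
        )
    vcf.close()
    return variants, samples, warnings


def read_sample_sheet(path: str | Path) -> list[Individual]:
    """Read the sample sheet TSV (columns: id, sex, group)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("id", "sex", "group") if c not in frame.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    return [
        Individual(id=str(r.id), sex=str(r.sex), group=str(r.group))
        for r in frame.itertuples(index=False)
    ]
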