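"""Synthetic exome-cohort generator with closed-form ground truth.

Emulates the structure of a stratified exome study — several ethnicity
groups of both sexes, three gene panels (secondary-findings, autosomal
recessive, X-linked recessive), biallelic SNVs with control-database
frequencies, deleteriousness predictions, ClinVar submitter assertions and
HGMD classes, plus per-call read evidence — so that every pipeline stage
can be tested end to end without any external download.

Genotypes are drawn under Hardy-Weinberg equilibrium per group from
per-variant allele frequencies (X-linked variants are hemizygous in males);
per-group frequency multipliers mimic higher variant loads in some
ancestries without asserting any biology. The generator is split into two
named random substreams: the *variant table* (gene models, positions,
frequencies, annotations) depends only on ``(seed, 0)``, and genotype/read
sampling on ``(seed, 1)``. Closed-form expectations — mean burden, fraction
of individuals with >=1 qualifying variant, couple risk — are therefore
exactly conditional on the deterministic variant table, with genotype
sampling the only stochastic layer, which makes n-sigma recovery tests
well-posed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify
from .ingest import AnnotatedVariant, Genotype, Individual, SampleCall
from .panels import GenePanel, Inheritance, PanelGene, TranscriptModel, write_panel

__all__ = [
    "GroupSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedCohort",
    "build_variant_truth",
    "simulate_cohort",
    "expected_mean_burden",
    "expected_couple_risk",
    "TRUTH_PREDICATES",
]

TRUTH_PREDICATES = (
    "rare_nonsynonymous",
    "predicted_deleterious",
    "clinvar_pathogenic",
    "hgmd_dm",
)

_PANEL_INHERITANCE = {
    "SF": Inheritance.ACTIONABLE,
    "AR": Inheritance.AR,
    "XLR": Inheritance.XLR,
}


@dataclass(frozen=True)
class GroupSpec:
    """One cohort stratum: ethnicity label, size, sex split, AF scaling."""

    label: str
    n_individuals: int
    female_fraction: float = 0.5
    af_multiplier: float = 1.0


@dataclass
class SimConfig:
    """Generator parameters; defaults describe a desk-scale two-group cohort.

    Allele frequencies are log-uniform over ``af_range`` (a rare-variant
    regime: most mass near the low end). Annotation rates echo the realized
    fractions seen in published exome screens of this kind: roughly 5% of
    rare nonsynonymous variants ClinVar-pathogenic, 10% HGMD-DM, and 45% of
    rare missense called deleterious by the ensemble predictor. QC-failure
    injection rates default to 0 (clean post-QC data); raise them to
    exercise the QC rules.
    """

    seed: int = 0
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("european_american", 1200, 0.55, 1.0),
        GroupSpec("african_american", 800, 0.55, 1.3),
    )
    n_sf_genes: int = 56
    n_ar_genes: int = 120
    n_xlr_genes: int = 40
    mean_variants_per_gene: float = 2.5
    af_range: tuple[float, float] = (1e-5, 0.02)
    functional_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.62,
            "synonymous": 0.25,
            "stop_gain": 0.05,
            "stop_loss": 0.01,
            "other": 0.07,
        }
    )
    p_clinvar_pathogenic: float = 0.05
    p_clinvar_other: float = 0.10  # likely-pathogenic or uncertain primary
    p_conflicting: float = 0.05  # discordant second submitter, given a record
    p_hgmd_dm: float = 0.10
    p_radialsvm_deleterious: float = 0.45  # among missense
    p_control_record: float = 0.5  # per database, independently
    mean_depth: float = 92.0
    depth_sigma: float = 0.25
    p_low_posterior: float = 0.0
    p_strand_bias: float = 0.0
    p_low_depth: float = 0.0

    def validate(self) -> None:
        problems = []
        if not self.groups:
            problems.append("groups: at least one group required")
        for g in self.groups:
            if g.n_individuals < 1:
                problems.append(f"groups[{g.label}].n_individuals: must be >= 1")
            if not (0.0 <= g.female_fraction <= 1.0):
                problems.append(f"groups[{g.label}].female_fraction: outside [0, 1]")
            if g.af_multiplier < 0:
                problems.append(f"groups[{g.label}].af_multiplier: negative")
        if not (0 < self.af_range[0] <= self.af_range[1] <= 1.0):
            problems.append("af_range: need 0 < low <= high <= 1")
        if abs(sum(self.functional_mix.values()) - 1.0) > 1e-9:
            problems.append("functional_mix: probabilities must sum to 1")
        for name in (
            "p_clinvar_pathogenic",
            "p_clinvar_other",
            "p_conflicting",
            "p_hgmd_dm",
            "p_radialsvm_deleterious",
            "p_control_record",
            "p_low_posterior",
            "p_strand_bias",
            "p_low_depth",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                problems.append(f"{name}: outside [0, 1]")
        if self.p_clinvar_pathogenic + self.p_clinvar_other > 1.0:
            problems.append("ClinVar record probabilities sum above 1")
        if self.mean_depth <= 0 or self.depth_sigma < 0:
            problems.append("depth model: mean_depth > 0 and depth_sigma >= 0 required")
        if self.mean_variants_per_gene < 0:
            problems.append("mean_variants_per_gene: negative")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), stream)))


# ---------------------------------------------------------------------------
# Variant-table construction (substream 0; fully deterministic given config)
# ---------------------------------------------------------------------------


@dataclass
class _VariantTruth:
    """Per-variant ground truth prior to genotype sampling."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    panel: str  # SF | AR | XLR
    functional_class: str
    base_af: float
    group_afs: dict[str, float]
    control_afs: dict[str, float]
    radialsvm_call: str
    clinvar_submissions: Counter
    hgmd_class: str
    qualifies: dict[str, bool] = field(default_factory=dict)
    expected_cohort_maf: float = 0.0


@dataclass
class SimTruth:
    """Deterministic ground truth for one configuration.

    Carries the variant table with per-predicate qualification flags and the
    closed-form expectations the recovery tests target, together with
    standard-error helpers derived from the independent-variant HWE model.
    """

    config: SimConfig
    variants: list[_VariantTruth]
    transcripts: dict[str, TranscriptModel]
    panels: dict[str, GenePanel]

    # -- cohort composition helpers --

    def _group_sizes(self) -> dict[str, tuple[int, int]]:
        """label -> (n_females, n_males)."""
        out = {}
        for g in self.config.groups:
            n_f = int(round(g.n_individuals * g.female_fraction))
            out[g.label] = (n_f, g.n_individuals - n_f)
        return out

    def _carrier_prob(self, v: _VariantTruth, label: str, sex: str) -> float:
        p = v.group_afs[label]
        if v.panel == "XLR" and sex == "male":
            return p
        return 1.0 - (1.0 - p) ** 2

    def _qualifying(self, panel: str, predicate: str) -> list[_VariantTruth]:
        return [v for v in self.variants if v.panel == panel and v.qualifies[predicate]]

    def _strata(self, sex: Optional[str]) -> list[tuple[str, str, int]]:
        """(group label, sex, n) for every non-empty stratum in scope."""
        out = []
        for label, (n_f, n_m) in self._group_sizes().items():
            if sex in (None, "female") and n_f:
                out.append((label, "female", n_f))
            if sex in (None, "male") and n_m:
                out.append((label, "male", n_m))
        return out

    # -- closed-form expectations --

    def expected_mean_burden(
        self, panel: str, predicate: str, sex: Optional[str] = None
    ) -> float:
        """E[mean per-individual count] = weighted sum of carrier probs."""
        strata = self._strata(sex)
        n_total = sum(n for _, _, n in strata)
        qualifying = self._qualifying(panel, predicate)
        total = 0.0
        for label, s, n in strata:
            total += n * sum(self._carrier_prob(v, label, s) for v in qualifying)
        return total / n_total

    def mean_burden_se(
        self, panel: str, predicate: str, sex: Optional[str] = None
    ) -> float:
        """SE of the measured cohort mean under independent HWE genotypes."""
        strata = self._strata(sex)
        n_total = sum(n for _, _, n in strata)
        qualifying = self._qualifying(panel, predicate)
        var = 0.0
        for label, s, n in strata:
            for v in qualifying:
                c = self._carrier_prob(v, label, s)
                var += n * c * (1.0 - c)
        return float(np.sqrt(var) / n_total)

    def expected_fraction_ge1(
        self, panel: str, predicate: str, sex: Optional[str] = None
    ) -> float:
        """E[fraction of individuals with >=1 qualifying panel variant]."""
        strata = self._strata(sex)
        n_total = sum(n for _, _, n in strata)
        qualifying = self._qualifying(panel, predicate)
        total = 0.0
        for label, s, n in strata:
            none = 1.0
            for v in qualifying:
                none *= 1.0 - self._carrier_prob(v, label, s)
            total += n * (1.0 - none)
        return total / n_total

    def fraction_ge1_se(
        self, panel: str, predicate: str, sex: Optional[str] = None
    ) -> float:
        strata = self._strata(sex)
        n_total = sum(n for _, _, n in strata)
        qualifying = self._qualifying(panel, predicate)
        var = 0.0
        for label, s, n in strata:
            none = 1.0
            for v in qualifying:
                none *= 1.0 - self._carrier_prob(v, label, s)
            q = 1.0 - none
            var += n * q * (1.0 - q)
        return float(np.sqrt(var) / n_total)

    def _sex_gene_carrier_probs(self, predicate: str, sex: str) -> dict[str, float]:
        """Carrier probability per AR-panel gene for a random same-sex draw."""
        strata = [(lbl, s, n) for lbl, s, n in self._strata(sex)]
        n_sex = sum(n for _, _, n in strata)
        by_gene: dict[str, dict[str, float]] = {}
        for v in self._qualifying("AR", predicate):
            by_gene.setdefault(v.gene, {})
        probs = {}
        for gene in by_gene:
            c = 0.0
            for label, s, n in strata:
                none = 1.0
                for v in self._qualifying("AR", predicate):
                    if v.gene == gene:
                        none *= 1.0 - self._carrier_prob(v, label, s)
                c += (n / n_sex) * (1.0 - none)
            probs[gene] = c
        return probs

    def expected_couple_risk(self, predicate: str) -> float:
        """Exact P(random male and female share >=1 AR carrier gene).

        Marginalises over the pair of group labels (carrier status is
        correlated across genes through group membership), assuming
        independence across genes within a group.
        """
        group_sizes = self._group_sizes()
        n_f = sum(f for f, _ in group_sizes.values())
        n_m = sum(m for _, m in group_sizes.values())
        qualifying = self._qualifying("AR", predicate)
        genes = sorted({v.gene for v in qualifying})
        by_gene = {g: [v for v in qualifying if v.gene == g] for g in genes}
        risk = 0.0
        for lf, (nf, _) in group_sizes.items():
            if nf == 0:
                continue
            for lm, (_, nm) in group_sizes.items():
                if nm == 0:
                    continue
                share_free = 1.0
                for gene in genes:
                    cf = 1.0
                    cm = 1.0
                    for v in by_gene[gene]:
                        cf *= 1.0 - self._carrier_prob(v, lf, "female")
                        cm *= 1.0 - self._carrier_prob(v, lm, "male")
                    share_free *= 1.0 - (1.0 - cf) * (1.0 - cm)
                risk += (nf / n_f) * (nm / n_m) * (1.0 - share_free)
        return risk

    def couple_risk_se(self, predicate: str, iterations: Optional[int] = None) -> float:
        """Approximate SE of the measured couple-risk fraction.

        Delta-method term for the finite sampled cohort (per-gene carrier
        counts are binomial within each sex stratum) plus, for Monte Carlo,
        the binomial resampling term.
        """
        group_sizes = self._group_sizes()
        n_f = sum(f for f, _ in group_sizes.values())
        n_m = sum(m for _, m in group_sizes.values())
        cf = self._sex_gene_carrier_probs(predicate, "female")
        cm = self._sex_gene_carrier_probs(predicate, "male")
        var = 0.0
        for gene in set(cf) | set(cm):
            f, m = cf.get(gene, 0.0), cm.get(gene, 0.0)
            var += f * f * m * (1.0 - m) / n_m + m * m * f * (1.0 - f) / n_f
        if iterations:
            q = self.expected_couple_risk(predicate)
            var += q * (1.0 - q) / iterations
        return float(np.sqrt(var))

    def to_json(self) -> str:
        payload = {
            "seed": self.config.seed,
            "n_variants": len(self.variants),
            "expectations": {},
        }
        for panel in ("SF", "AR", "XLR"):
            for predicate in TRUTH_PREDICATES:
                key = f"{panel}.{predicate}"
                payload["expectations"][key] = {
                    "mean_burden": self.expected_mean_burden(panel, predicate),
                    "fraction_ge1": self.expected_fraction_ge1(panel, predicate),
                }
        for predicate in TRUTH_PREDICATES:
            payload["expectations"][f"couple_risk.{predicate}"] = (
                self.expected_couple_risk(predicate)
            )
        return json.dumps(payload, indent=2, sort_keys=True)


def _make_transcript(
    rng: np.random.Generator, gene: str, chrom: str, cursor: int
) -> tuple[TranscriptModel, int]:
    n_exons = int(rng.integers(1, 7))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = cursor
    for _ in range(n_exons):
        length = int(rng.integers(120, 301))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(500, 2001))
    utr5 = int(rng.integers(10, 60))
    utr3 = int(rng.integers(10, 60))
    cds_start = exons[0][0] + utr5
    cds_end = exons[-1][1] - utr3
    model = TranscriptModel(
        gene=gene,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return model, exons[-1][1] + 10_000


def build_variant_truth(config: SimConfig) -> SimTruth:
    """Deterministically build panels, transcripts and the variant table."""
    config.validate()
    rng = config._rng(0)
    panels: dict[str, GenePanel] = {}
    transcripts: dict[str, TranscriptModel] = {}
    gene_plan: list[tuple[str, str]] = []  # (gene, panel kind)
    for kind, count, prefix in (
        ("SF", config.n_sf_genes, "SFG"),
        ("AR", config.n_ar_genes, "ARG"),
        ("XLR", config.n_xlr_genes, "XLG"),
    ):
        genes = [f"{prefix}{i + 1:04d}" for i in range(count)]
        panels[kind] = GenePanel.from_genes(
            f"{kind}_panel",
            (PanelGene(symbol=g, inheritance=_PANEL_INHERITANCE[kind]) for g in genes),
        )
        gene_plan.extend((g, kind) for g in genes)

    autosomes = [str(c) for c in range(1, 23)]
    cursors: dict[str, int] = {}
    auto_idx = 0
    variants: list[_VariantTruth] = []
    bases = np.array(list("ACGT"))
    classes = list(config.functional_mix)
    class_p = np.array([config.functional_mix[c] for c in classes])
    low, high = config.af_range
    for gene, kind in gene_plan:
        if kind == "XLR":
            chrom = "X"
        else:
            chrom = autosomes[auto_idx % len(autosomes)]
            auto_idx += 1
        cursor = cursors.get(chrom, 1_000)
        tx, cursor = _make_transcript(rng, gene, chrom, cursor)
        cursors[chrom] = cursor
        transcripts[gene] = tx
        coding = np.concatenate([np.arange(s, e) for s, e in tx.coding_intervals()])
        n_var = int(rng.poisson(config.mean_variants_per_gene))
        n_var = min(n_var, coding.size)
        if n_var == 0:
            continue
        positions = np.sort(rng.choice(coding, size=n_var, replace=False))
        for pos0 in positions:
            ref, alt = rng.choice(bases, size=2, replace=False)
            fclass = classes[int(rng.choice(len(classes), p=class_p))]
            base_af = float(np.exp(rng.uniform(np.log(low), np.log(high))))
            group_afs = {
                g.label: min(1.0, base_af * g.af_multiplier) for g in config.groups
            }
            control_afs = {}
            for source in ("thousand_genomes", "esp"):
                if rng.random() < config.p_control_record:
                    control_afs[source] = base_af
            if fclass == "missense":
                rsvm = (
                    "deleterious"
                    if rng.random() < config.p_radialsvm_deleterious
                    else "tolerated"
                )
            else:
                rsvm = "absent"
            clinvar: Counter = Counter()
            u = rng.random()
            if u < config.p_clinvar_pathogenic:
                clinvar["pathogenic"] += 1
                if rng.random() < config.p_conflicting:
                    clinvar["likely_benign" if rng.random() < 0.5 else "benign"] += 1
            elif u < config.p_clinvar_pathogenic + config.p_clinvar_other:
                clinvar["likely_pathogenic" if rng.random() < 0.5 else "uncertain"] += 1
                if rng.random() < config.p_conflicting:
                    clinvar["pathogenic"] += 1
            if rng.random() < config.p_hgmd_dm:
                hgmd = "DM"
            elif rng.random() < 0.05:
                hgmd = "other"
            else:
                hgmd = "absent"
            variants.append(
                _VariantTruth(
                    chrom=chrom,
                    pos=int(pos0) + 1,
                    ref=str(ref),
                    alt=str(alt),
                    gene=gene,
                    panel=kind,
                    functional_class=fclass,
                    base_af=base_af,
                    group_afs=group_afs,
                    control_afs=control_afs,
                    radialsvm_call=rsvm,
                    clinvar_submissions=clinvar,
                    hgmd_class=hgmd,
                )
            )
    truth = SimTruth(config=config, variants=variants, transcripts=transcripts, panels=panels)
    _annotate_qualification(truth)
    return truth


def _expected_cohort_maf(truth: SimTruth, v: _VariantTruth) -> float:
    """Allele-count-weighted expected alt frequency, folded to minor."""
    alt = total = 0.0
    for label, (n_f, n_m) in truth._group_sizes().items():
        p = v.group_afs[label]
        if v.panel == "XLR":
            alleles = 2 * n_f + n_m
        else:
            alleles = 2 * (n_f + n_m)
        alt += alleles * p
        total += alleles
    f = alt / total
    return min(f, 1.0 - f)


def _annotate_qualification(truth: SimTruth) -> None:
    """Evaluate the variant-level classification flags on true frequencies."""
    for v in truth.variants:
        probe = AnnotatedVariant(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            gene=v.gene,
            functional_class=v.functional_class,
            control_afs=dict(v.control_afs),
            radialsvm_call=v.radialsvm_call,
            clinvar_submissions=Counter(v.clinvar_submissions),
            hgmd_class=v.hgmd_class,
        )
        v.expected_cohort_maf = _expected_cohort_maf(truth, v)
        probe.cohort_maf = v.expected_cohort_maf
        rare_nonsyn = classify.is_nonsynonymous(probe) and classify.is_rare(probe)
        if v.functional_class == "stop_loss":
            damaging = True
        elif v.functional_class == "stop_gain":
            damaging = not classify.is_nmd_escaping(probe, truth.transcripts[v.gene])
        elif v.functional_class == "missense":
            damaging = v.radialsvm_call == "deleterious"
        else:
            damaging = False
        v.qualifies = {
            "rare_nonsynonymous": rare_nonsyn,
            "predicted_deleterious": rare_nonsyn and damaging,
            "clinvar_pathogenic": rare_nonsyn
            and classify.clinvar_pathogenic(v.clinvar_submissions),
            "hgmd_dm": rare_nonsyn and v.hgmd_class == "DM",
        }


# ---------------------------------------------------------------------------
# Cohort sampling (substream 1) and file output
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """In-memory simulated cohort plus its ground truth."""

    individuals: list[Individual]
    variants: list[AnnotatedVariant]
    panels: dict[str, GenePanel]
    transcripts: dict[str, TranscriptModel]
    truth: SimTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _make_individuals(config: SimConfig) -> list[Individual]:
    individuals = []
    counter = 0
    for g in config.groups:
        n_f = int(round(g.n_individuals * g.female_fraction))
        for i in range(g.n_individuals):
            counter += 1
            individuals.append(
                Individual(
                    id=f"S{counter:06d}",
                    sex="female" if i < n_f else "male",
                    group=g.label,
                )
            )
    return individuals


def simulate_cohort(
    config: SimConfig, out_dir: Optional[str | Path] = None
) -> SimulatedCohort:
    """Draw a full cohort under the config; optionally write all artefacts.

    Outputs (when ``out_dir`` is given): ``cohort.vcf``, ``samples.tsv``,
    ``panel_{sf,ar,xlr}.tsv``, ``transcripts.tsv`` and ``truth.json``.
    Identical seed and config produce byte-identical files.
    """
    truth = build_variant_truth(config)
    rng = config._rng(1)
    individuals = _make_individuals(config)
    n = len(individuals)
    sample_ids = [ind.id for ind in individuals]
    group_labels = np.array([ind.group for ind in individuals])
    is_male = np.array([ind.sex == "male" for ind in individuals])

    mu = np.log(config.mean_depth) - 0.5 * config.depth_sigma**2
    variants: list[AnnotatedVariant] = []
    for v in truth.variants:
        p = np.array([v.group_afs[g] for g in group_labels])
        u = rng.random(n)
        if v.panel == "XLR":
            # females diploid HWE; males hemizygous
            dose = np.where(u < p * p, 2, np.where(u < p * (2.0 - p), 1, 0))
            male_dose = (rng.random(n) < p).astype(np.int64)
            dose = np.where(is_male, male_dose, dose)
            hemi = is_male
        else:
            dose = np.where(u < p * p, 2, np.where(u < p * (2.0 - p), 1, 0))
            hemi = np.zeros(n, dtype=bool)
        depth = np.maximum(1, np.rint(np.exp(rng.normal(mu, config.depth_sigma, n)))).astype(np.int64)
        if config.p_low_depth > 0:
            low_mask = rng.random(n) < config.p_low_depth
            depth = np.where(low_mask, rng.integers(1, 10, n), depth)
        alt = np.zeros(n, dtype=np.int64)
        het = (dose == 1) & ~hemi
        alt[het] = rng.binomial(depth[het], 0.5)
        full = ((dose == 2) & ~hemi) | (hemi & (dose == 1))
        alt[full] = depth[full]
        fwd = rng.binomial(alt, 0.5)
        if config.p_strand_bias > 0:
            bias = (rng.random(n) < config.p_strand_bias) & (alt > 0)
            fwd = np.where(bias, alt, fwd)
        posterior = rng.uniform(0.97, 1.0, n)
        if config.p_low_posterior > 0:
            lowp = rng.random(n) < config.p_low_posterior
            posterior = np.where(lowp, rng.uniform(0.5, 0.9499, n), posterior)
        calls = {}
        for i, sid in enumerate(sample_ids):
            if hemi[i]:
                genotype = Genotype.HEMI_ALT if dose[i] == 1 else Genotype.HEMI_REF
            else:
                genotype = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[dose[i]]
            calls[sid] = SampleCall(
                genotype=genotype,
                depth=int(depth[i]),
                alt_reads=int(alt[i]),
                alt_fwd=int(fwd[i]),
                alt_rev=int(alt[i] - fwd[i]),
                posterior=float(np.round(posterior[i], 4)),
            )
        variants.append(
            AnnotatedVariant(
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alt=v.alt,
                gene=v.gene,
                functional_class=v.functional_class,
                control_afs=dict(v.control_afs),
                radialsvm_call=v.radialsvm_call,
                clinvar_submissions=Counter(v.clinvar_submissions),
                hgmd_class=v.hgmd_class,
                calls=calls,
            )
        )

    cohort = SimulatedCohort(
        individuals=individuals,
        variants=variants,
        panels=truth.panels,
        transcripts=truth.transcripts,
        truth=truth,
    )
    if out_dir is not None:
        cohort.paths = _write_outputs(cohort, Path(out_dir))
    return cohort


_VCF_HEADER_TEMPLATE = """##fileformat=VCFv4.2
##source=carrierburden-synthetic
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">
##INFO=<ID=AF_1KG,Number=1,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=AF_ESP,Number=1,Type=Float,Description="ESP allele frequency">
##INFO=<ID=RSVM,Number=1,Type=String,Description="RadialSVM call">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar submitter assertions, |-separated">
##INFO=<ID=HGMD,Number=1,Type=String,Description="HGMD class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=VR,Number=1,Type=Integer,Description="Variant-supporting reads">
##FORMAT=<ID=SBF,Number=1,Type=Integer,Description="Variant reads on forward strand">
##FORMAT=<ID=SBR,Number=1,Type=Integer,Description="Variant reads on reverse strand">
##FORMAT=<ID=CPP,Number=1,Type=Float,Description="Call posterior probability">
"""

_GT_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.HEMI_REF: "0",
    Genotype.HEMI_ALT: "1",
    Genotype.MISSING: "./.",
}


def _write_vcf(cohort: SimulatedCohort, path: Path) -> None:
    sample_ids = [ind.id for ind in cohort.individuals]
    chroms = sorted({v.chrom for v in cohort.variants}, key=lambda c: (c != "X", c.zfill(2)))
    with open(path, "w") as out:
        out.write(_VCF_HEADER_TEMPLATE)
        for chrom in chroms:
            out.write(f"##contig=<ID={chrom}>\n")
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        out.write("\t".join(sample_ids) + "\n")
        ordered = sorted(cohort.variants, key=lambda v: (chroms.index(v.chrom), v.pos))
        for v in ordered:
            info = [f"GENE={v.gene}", f"FCLASS={v.functional_class}"]
            if "thousand_genomes" in v.control_afs:
                info.append(f"AF_1KG={v.control_afs['thousand_genomes']:.6g}")
            if "esp" in v.control_afs:
                info.append(f"AF_ESP={v.control_afs['esp']:.6g}")
            if v.radialsvm_call != "absent":
                info.append(f"RSVM={v.radialsvm_call}")
            if v.clinvar_submissions:
                tokens = []
                for term in sorted(v.clinvar_submissions):
                    tokens.extend([term] * v.clinvar_submissions[term])
                info.append("CLNSIG=" + "|".join(tokens))
            if v.hgmd_class != "absent":
                info.append(f"HGMD={v.hgmd_class}")
            fields = [
                v.chrom,
                str(v.pos),
                ".",
                v.ref,
                v.alt,
                ".",
                "PASS",
                ";".join(info),
                "GT:DP:VR:SBF:SBR:CPP",
            ]
            for sid in sample_ids:
                c = v.calls[sid]
                fields.append(
                    f"{_GT_STRING[c.genotype]}:{c.depth}:{c.alt_reads}:"
                    f"{c.alt_fwd}:{c.alt_rev}:{c.posterior:.4f}"
                )
            out.write("\t".join(fields) + "\n")


def _write_outputs(cohort: SimulatedCohort, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "samples": out_dir / "samples.tsv",
        "panel_sf": out_dir / "panel_sf.tsv",
        "panel_ar": out_dir / "panel_ar.tsv",
        "panel_xlr": out_dir / "panel_xlr.tsv",
        "transcripts": out_dir / "transcripts.tsv",
        "truth": out_dir / "truth.json",
    }
    _write_vcf(cohort, paths["vcf"])
    pd.DataFrame(
        [{"id": i.id, "sex": i.sex, "group": i.group} for i in cohort.individuals]
    ).to_csv(paths["samples"], sep="\t", index=False)
    write_panel(cohort.panels["SF"], paths["panel_sf"])
    write_panel(cohort.panels["AR"], paths["panel_ar"])
    write_panel(cohort.panels["XLR"], paths["panel_xlr"])
    rows = []
    for tx in cohort.transcripts.values():
        rows.append(
            {
                "symbol": tx.gene,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "exon_starts": ",".join(str(s) for s, _ in tx.exons),
                "exon_ends": ",".join(str(e) for _, e in tx.exons),
                "cds_start": tx.cds_start,
                "cds_end": tx.cds_end,
            }
        )
    pd.DataFrame(rows).to_csv(paths["transcripts"], sep="\t", index=False)
    paths["truth"].write_text(cohort.truth.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# Config-level expectation helpers (no cohort sampling involved)
# ---------------------------------------------------------------------------


def expected_mean_burden(
    config: SimConfig, panel: str = "AR", predicate: str = "rare_nonsynonymous"
) -> float:
    """Closed-form expected mean burden for the config's variant table."""
    return build_variant_truth(config).expected_mean_burden(panel, predicate)


def expected_couple_risk(
    config: SimConfig, predicate: str = "clinvar_pathogenic"
) -> float:
    """Closed-form expected at-risk couple fraction for the config."""
    return build_variant_truth(config).expected_couple_risk(predicate)
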