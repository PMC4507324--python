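# Methods

## Scope and data model

The package quantifies reportable variation in an annotated multi-sample
exome VCF against three curated gene panels: dominantly acting actionable
("secondary findings", SF) genes, autosomal-recessive (AR) disease genes,
and X-linked recessive (XLR) genes used for female carrier analysis. The
unit of analysis is a biallelic SNV (`AnnotatedVariant`) carrying gene and
functional-class annotations, control-database allele frequencies, a
deleteriousness prediction call, a multiset of ClinVar submitter
assertions, an HGMD class, and one `SampleCall` (genotype plus read-level
evidence) per cohort member. Multi-allelic records must be decomposed
upstream; the reader skips non-SNV alleles and undecomposed records and
tallies them in a warning counter. Indels, phasing, genotype calling and
ancestry inference are out of scope.

## Panel curation

AR and XLR panels are produced from candidate tables by a deterministic
rule standing in for a manual literature review: retain a candidate iff
`(on_prior_lists OR (omim_entry_found AND inheritance_evidence)) AND NOT
force_exclude`, where the evidence flag means biallelic disease variants
(AR) or hemizygous male disease (XLR). Lookups against MedGen/OMIM are
deliberately not performed — evidence arrives as boolean columns — because
the decision logic, not the literature search, is the reproducible part.
Candidates on prior lists are retained without consulting the OMIM flags;
how genes absent from both sources were handled historically is not
documented, so the rule follows the narrative reading. Every exclusion is
attributed to exactly one rule (checked in the order force-exclusion,
missing OMIM entry, missing evidence) and the audit is asserted to balance.
One canonical transcript per gene is assumed; multi-transcript NMD logic is
out of scope.

## Coordinates and QC

VCF positions are 1-based; capture (BED) intervals are 0-based half-open;
the conversion lives in one place (`restrict_to_regions`). Capture designs
are normalised (sorted, merged) and intersected with a two-pointer sweep so
a comparative analysis can be restricted to the region both designs cover.

Call-level QC mirrors strict published exclusions: a call fails when its
posterior probability is below 0.95, its depth below 10×, or strictly more
than 99% of its variant-supporting reads lie on one strand (evaluated on
variant reads only, so zero alt reads trivially passes). Boundary values
therefore pass; the tests pin this down. The deleterious set applies a
second, stricter read-support gate per call: depth ≥ 20× and alt-read
ratio ≥ 0.2. This gate is per-sample: a variant enters an individual's
deleterious burden only through that individual's passing call, and a
variant-level deleterious flag requires ≥ 1 passing carrier.

Cohort minor-allele frequency is computed after treating QC-failing calls
as missing (QC precedes all downstream filters; an `apply_qc=False` path
exists because the original ordering is not documented). Diploid genotypes
contribute two alleles, hemizygous ones a single allele, and the frequency
is folded to `min(f, 1−f)`.

## Classification cascade

* **nonsynonymous** — missense, stop-gain, stop-loss.
* **rare** — every control AF ≤ 0.01 (absent record = 0) and cohort MAF
  ≤ 0.02, both strict-exclusion boundaries.
* **NMD escape** (stop-gain only) — true in the transcript-orientation last
  coding exon, or within the final 50 coding bases (inclusive) of the
  penultimate coding exon at its 3′ end; single-coding-exon transcripts
  always escape (no downstream junction). Distances are measured in coding
  bases after clipping exons to the CDS; a position outside the CDS is an
  error rather than a silent false.
* **predicted deleterious** — rare ∧ nonsynonymous ∧ per-call read-support
  QC ∧ (stop-loss ∨ (stop-gain ∧ ¬NMD-escape) ∨ (missense ∧ RadialSVM
  deleterious)). Stop-loss is not gated by RadialSVM because the predictor
  scores missense variants only; a stop-gain without a transcript model is
  excluded conservatively.
* **ClinVar pathogenic** — no benign/likely-benign assertion and ≥ 1
  pathogenic assertion; likely-pathogenic alone does not qualify; star
  ratings are ignored; uncertain/other-only records are simply
  non-pathogenic.
* **HGMD** — class DM only.
* **novel** — no record (not even AF 0) in either control database.

The reported-pathogenic burden predicates additionally require the variant
to be rare and nonsynonymous, since the screen draws all candidate variants
from that pool.

## Burden statistics

Burden counts distinct variant sites carried (hom-alt counts once),
matching "number of variants per individual" semantics; allele-dosage
counting is an option. Medians are taken on the integer vector without
interpolation. The report layer rounds means to 2 decimals and fractions to
3; all internal values are exact. Group tables are computed per (ethnicity
group × predicate) and are invariant to individual ordering; pooled group
means reproduce the cohort mean to machine precision.

The MAF rank-sum comparison is a two-sided Wilcoxon/Mann-Whitney test:
exact enumeration over all C(n₁+n₂, n₁) rank assignments (midranks for
ties) when both samples have ≤ 8 observations — written here because
scipy's exact method does not handle ties — and scipy's normal
approximation with tie correction otherwise. The exact branch is
cross-checked against scipy on tie-free inputs.

## Couple risk

Carrier profiles are per-individual sets of panel genes containing ≥ 1
qualifying carried variant; zygosity is ignored because the procedure tests
gene sharing only (a hom-alt partner actually implies a 50% rather than 25%
offspring risk — a documented simplification of the resampling design).
The Monte Carlo estimator draws one male and one female uniformly with
replacement per iteration from disjoint sex strata (self-pairing is
impossible) and reports the fraction of iterations with intersecting gene
sets, a normal-approximation binomial 95% CI, the iteration count and the
seed. Gene sets are encoded as bitmasks; with ≤ 63 distinct carrier genes
the whole resampling loop is vectorised. The exact estimator enumerates all
pairs by grouping identical masks, and is the Monte Carlo limit. Closed
forms — `4 × disease frequency` for the prevalence inversion (valid to a
frequency of 0.25) and `1 − Π(1 − c_g²)` under gene independence — serve as
population-level expectations.

## Synthetic cohorts and ground truth

The generator emulates a stratified exome study: ethnicity groups with
sizes, female fractions and allele-frequency multipliers; panels of
configurable size; per-gene transcripts (1–6 exons, 120–300 bp, both
strands, short UTRs) on a surrogate genome; Poisson variant counts per gene
placed at distinct coding positions; log-uniform allele frequencies
(default range 1e-5–0.02, a rare-variant regime); annotation rates for
ClinVar (with a configurable discordant-second-submitter rate so the
resolution rule is exercised on both branches), HGMD-DM and RadialSVM; and
a read model (log-normal depth around 92×, binomial alt reads and strand
split, posteriors in [0.97, 1]). Genotypes follow Hardy–Weinberg
equilibrium per group; X-linked variants are hemizygous in males.
QC-failure injection rates (low posterior, strand bias, low depth) default
to 0 — the defaults emulate clean post-QC data — and are raised explicitly
by tests that exercise the QC rules.

Randomness is split into two named substreams: `(seed, 0)` drives the
variant/annotation table and `(seed, 1)` genotype and read sampling. The
closed-form expectations (mean burden Σ(1−(1−p)²), fraction-with-≥1,
couple risk marginalised over the pair of group labels, since group
membership correlates carrier status across genes) are therefore exactly
conditional on a deterministic variant table, and their standard errors
under independent HWE genotypes are provided alongside
(`mean_burden_se`, `fraction_ge1_se`, `couple_risk_se` — the latter a
delta-method term for finite cohort size plus the binomial resampling term).
Identical seed and config produce byte-identical output files.

Desk-scale defaults (two groups totalling 2000 individuals; panels of
56/120/40 genes; ~2.5 variants per gene) were chosen once as a realistic,
tractable simulation size; panel sizes and cohort composition are fully
configurable, and the published-scale curation arithmetic (1496 → 1423,
126 → 112) is exercised exactly through the candidate-table fixtures rather
than through simulation.

What the generator does **not** model: linkage disequilibrium and within-
gene phase, pedigree structure and consanguinity, sequencing-error
profiles, population substructure beyond per-group AF scaling, and
annotation errors. Passing recovery tests therefore demonstrate the
internal consistency of the pipeline under its stated sampling model, not
calibration against real human cohorts.

## Numerical and test-design choices

* End-to-end recovery tests use an AF range of (1e-5, 0.008) with group
  multipliers ≤ 1.3 so no variant sits near the 1%/2% rarity thresholds:
  variant qualification is then deterministic and the 3·SE bands are exact.
  At the default range top (0.02) a boundary variant's estimated cohort MAF
  can flip its qualification stochastically, which is realistic but makes
  the conditional closed form approximate.
* The couples recovery config raises the ClinVar-pathogenic rate to 0.5 so
  the expected risk (~1–2%) is large relative to its standard error; at the
  default 5% rate the expectation on a 120-gene panel is too close to zero
  for a meaningful two-sided check.
* Problem sizes in the suite — cohorts of 400–5000, panels of tens of
  genes, 1e5 Monte Carlo iterations, 30 couple-risk fixtures — keep the
  whole suite around a minute while leaving every statistical check with
  3·SE power.
* Degenerate inputs are errors, not silent values: empty cohorts, empty
  rank-test samples, all-missing genotypes, positions outside the CDS, and
  prevalences above 0.25 all raise.

## Known limitations

* One transcript per gene; NMD assessment on alternative isoforms is not
  represented.
* The rarity filter's interaction with call-level QC follows a documented
  choice (QC first) that cannot be verified against the original pipeline.
* Whether stop-loss variants were prediction-gated originally is ambiguous;
  the implemented reading (auto-deleterious) is flagged in the docstrings.
* Couple-risk semantics count gene sharing only; compound heterozygosity
  within a partner and zygosity-dependent offspring risk are not modelled.
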