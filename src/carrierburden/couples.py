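"""At-risk couple estimation for autosomal-recessive carrier status.

A male-female pair is *at risk* when both partners carry a qualifying
variant in the same autosomal-recessive disease gene: each child then has a
nominal 1-in-4 chance of being affected. The published procedure pairs a
random male exome with a random female exome and tests whether their
carrier gene sets intersect; repeated a million times this estimates the
population fraction of at-risk couples. Sharing is counted regardless of
zygosity — a hom-alt partner actually confers a higher offspring risk, but
the resampling procedure only tests gene sharing.

Alongside the Monte Carlo estimator this module provides the exact
all-pairs enumeration (the estimator's oracle), the female X-linked carrier
fraction, and two closed-form expectation helpers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .burden import Predicate
from .ingest import AnnotatedVariant, Individual, call_passes_qc
from .panels import GenePanel

__all__ = [
    "CarrierProfile",
    "CoupleRiskResult",
    "build_carrier_profiles",
    "couple_risk_monte_carlo",
    "couple_risk_exact",
    "female_xlinked_carrier_fraction",
    "expected_risk_from_prevalence",
    "expected_risk_closed_form",
]


@dataclass(frozen=True)
class CarrierProfile:
    """Panel genes in which one individual carries >=1 qualifying variant."""

    id: str
    sex: str
    gene_set: frozenset[str]


@dataclass(frozen=True)
class CoupleRiskResult:
    """Fraction of male-female pairs sharing a carrier gene.

    ``method`` is ``monte_carlo`` (with iteration count, seed and a
    normal-approximation 95% binomial CI) or ``exact`` (all-pairs
    enumeration; CI degenerate at the value).
    """

    method: str
    at_risk_fraction: float
    n_males: int
    n_females: int
    iterations: Optional[int] = None
    seed: Optional[int] = None
    ci95: Optional[tuple[float, float]] = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "at_risk_fraction": self.at_risk_fraction,
            "n_males": self.n_males,
            "n_females": self.n_females,
            "iterations": self.iterations,
            "seed": self.seed,
            "ci95": list(self.ci95) if self.ci95 else None,
        }


def build_carrier_profiles(
    variants: Iterable[AnnotatedVariant],
    individuals: Sequence[Individual],
    panel: GenePanel,
    predicate: Predicate,
) -> list[CarrierProfile]:
    """One profile per individual: genes with >=1 qualifying carried variant.

    A gene enters the set when the individual has at least one alternate
    allele at a panel-gene variant whose call passes QC and which satisfies
    the predicate; zygosity and multiplicity within the gene are ignored
    (set semantics).
    """
    gene_sets: dict[str, set[str]] = {ind.id: set() for ind in individuals}
    for variant in variants:
        if variant.gene not in panel:
            continue
        for sid, call in variant.calls.items():
            if sid not in gene_sets or not call.genotype.carries_alt:
                continue
            if call_passes_qc(call) and predicate(variant, call):
                gene_sets[sid].add(variant.gene)
    return [
        CarrierProfile(id=ind.id, sex=ind.sex, gene_set=frozenset(gene_sets[ind.id]))
        for ind in individuals
    ]


def _gene_masks(
    males: Sequence[CarrierProfile], females: Sequence[CarrierProfile]
) -> tuple[list[int], list[int]]:
    """Encode gene sets as integer bitmasks for fast intersection tests."""
    genes = sorted({g for p in males for g in p.gene_set} | {g for p in females for g in p.gene_set})
    bit = {g: 1 << i for i, g in enumerate(genes)}
    def mask(p: CarrierProfile) -> int:
        m = 0
        for g in p.gene_set:
            m |= bit[g]
        return m
    return [mask(p) for p in males], [mask(p) for p in females]


def couple_risk_monte_carlo(
    males: Sequence[CarrierProfile],
    females: Sequence[CarrierProfile],
    iterations: int = 1_000_000,
    seed: int = 0,
) -> CoupleRiskResult:
    """Resampling estimate of the at-risk couple fraction.

    Each iteration draws one male and one female uniformly with replacement
    (independently across iterations; the two are drawn from disjoint sex
    strata, so self-pairing cannot occur) and scores whether their carrier
    gene sets intersect. Reproducible given the seed.
    """
    if not males or not females:
        raise ValueError("both sex strata must be non-empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    m_masks, f_masks = _gene_masks(males, females)
    m_idx = rng.integers(0, len(males), size=iterations)
    f_idx = rng.integers(0, len(females), size=iterations)
    if all(m.bit_length() <= 63 for m in m_masks + f_masks):
        mm = np.array(m_masks, dtype=np.uint64)
        fm = np.array(f_masks, dtype=np.uint64)
        hits = int(np.count_nonzero(mm[m_idx] & fm[f_idx]))
    else:
        hits = sum(1 for i, j in zip(m_idx, f_idx) if m_masks[i] & f_masks[j])
    frac = hits / iterations
    se = np.sqrt(frac * (1.0 - frac) / iterations)
    ci = (max(0.0, frac - 1.96 * se), min(1.0, frac + 1.96 * se))
    return CoupleRiskResult(
        method="monte_carlo",
        at_risk_fraction=frac,
        n_males=len(males),
        n_females=len(females),
        iterations=iterations,
        seed=seed,
        ci95=ci,
    )


def couple_risk_exact(
    males: Sequence[CarrierProfile], females: Sequence[CarrierProfile]
) -> CoupleRiskResult:
    """Exact all-pairs at-risk fraction (the Monte Carlo limit).

    Groups identical gene-set bitmasks so the pair loop runs over unique
    (mask, multiplicity) combinations rather than all |M| x |F| pairs.
    """
    if not males or not females:
        raise ValueError("both sex strata must be non-empty")
    m_masks, f_masks = _gene_masks(males, females)
    m_counts = Counter(m_masks)
    f_counts = Counter(f_masks)
    hits = 0
    for mm, cm in m_counts.items():
        if not mm:
            continue
        for fm, cf in f_counts.items():
            if mm & fm:
                hits += cm * cf
    frac = hits / (len(males) * len(females))
    return CoupleRiskResult(
        method="exact",
        at_risk_fraction=frac,
        n_males=len(males),
        n_females=len(females),
    )


def female_xlinked_carrier_fraction(
    females: Sequence[CarrierProfile],
    xl_panel: GenePanel,
    profiles_are_xl: bool = True,
) -> float:
    """Fraction of females carrying >=1 qualifying X-linked panel variant.

    Profiles should have been built against the XLR panel; when built
    against a wider panel pass ``profiles_are_xl=False`` to re-restrict the
    gene sets here.
    """
    if not females:
        raise ValueError("no females in cohort")
    if profiles_are_xl:
        carriers = sum(1 for p in females if p.gene_set)
    else:
        carriers = sum(1 for p in females if p.gene_set & xl_panel.symbols)
    return carriers / len(females)


def expected_risk_from_prevalence(ar_disease_frequency: float) -> float:
    """Population expectation: at-risk couple fraction from disease frequency.

    Inverts the 1-in-4 offspring risk: if a fraction ``f`` of births are
    affected by autosomal-recessive disease, about ``4 f`` of couples must
    be at risk. Valid for ``f <= 0.25``.
    """
    if not (0.0 <= ar_disease_frequency <= 0.25):
        raise ValueError("disease frequency must lie in [0, 0.25]")
    return 4.0 * ar_disease_frequency


def expected_risk_closed_form(per_gene_carrier_probs: Mapping[str, float]) -> float:
    """Closed-form at-risk fraction under gene independence.

    With carrier probability ``c_g`` per gene (equal in both sexes), a
    couple shares no gene with probability ``prod_g (1 - c_g^2)``.
    """
    risk_free = 1.0
    for gene, c in per_gene_carrier_probs.items():
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"carrier probability for {gene!r} outside [0, 1]")
        risk_free *= 1.0 - c * c
    return 1.0 - risk_free
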