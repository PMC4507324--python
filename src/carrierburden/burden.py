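"""Per-individual burden counts, distribution summaries and group tables.

A *burden* is the number of distinct variant sites, within a gene panel and
satisfying a classification predicate, at which an individual carries at
least one alternate allele on a QC-passing call. Hom-alt genotypes count the
site once by default ("number of variants per individual"); allele-dosage
counting is available as an option.

Predicates take ``(variant, call)`` so that per-call criteria (the stricter
read-support QC of the predicted-deleterious set) can participate; purely
variant-level predicates ignore the call argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import classify
from .ingest import AnnotatedVariant, Individual, SampleCall, call_passes_qc
from .panels import GenePanel, TranscriptModel

__all__ = [
    "Predicate",
    "BurdenSummary",
    "standard_predicates",
    "per_individual_counts",
    "summarize",
    "group_summaries",
    "group_table",
    "maf_rank_test",
]

Predicate = Callable[[AnnotatedVariant, SampleCall], bool]


def standard_predicates(
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> dict[str, Predicate]:
    """The predicate set used throughout the published-style tables.

    ``rare_nonsynonymous`` and the two reported-pathogenic predicates are
    variant-level; ``predicted_deleterious`` additionally applies the
    per-call read-support QC. ``nonsense`` restricts to rare stop-gains.
    """
    tx = transcripts or {}

    def rare_nonsyn(v: AnnotatedVariant, call: SampleCall) -> bool:
        return classify.is_nonsynonymous(v) and classify.is_rare(v)

    def deleterious(v: AnnotatedVariant, call: SampleCall) -> bool:
        return classify.is_predicted_deleterious(v, tx.get(v.gene), call)

    def clinvar(v: AnnotatedVariant, call: SampleCall) -> bool:
        return rare_nonsyn(v, call) and classify.clinvar_pathogenic(v.clinvar_submissions)

    def hgmd(v: AnnotatedVariant, call: SampleCall) -> bool:
        return rare_nonsyn(v, call) and classify.hgmd_dm(v)

    def nonsense(v: AnnotatedVariant, call: SampleCall) -> bool:
        return v.functional_class == "stop_gain" and classify.is_rare(v)

    return {
        "rare_nonsynonymous": rare_nonsyn,
        "predicted_deleterious": deleterious,
        "clinvar_pathogenic": clinvar,
        "hgmd_dm": hgmd,
        "nonsense": nonsense,
    }


def per_individual_counts(
    variants: Iterable[AnnotatedVariant],
    individuals: Sequence[Individual],
    panel: GenePanel,
    predicate: Predicate,
    *,
    count_alleles: bool = False,
) -> np.ndarray:
    """Count qualifying variant sites carried by each individual.

    A site contributes to an individual's count when the variant's gene is
    on the panel, the individual's call carries >=1 alternate allele and
    passes variant-level QC, and ``predicate(variant, call)`` holds. With
    ``count_alleles`` the contribution is the allele dose (hom-alt counts 2).
    """
    if not individuals:
        raise ValueError("cohort must contain at least one individual")
    index = {ind.id: i for i, ind in enumerate(individuals)}
    counts = np.zeros(len(individuals), dtype=np.int64)
    for variant in variants:
        if variant.gene not in panel:
            continue
        for sid, call in variant.calls.items():
            pos = index.get(sid)
            if pos is None or not call.genotype.carries_alt:
                continue
            if not call_passes_qc(call):
                continue
            if predicate(variant, call):
                counts[pos] += call.genotype.alt_dose if count_alleles else 1
    return counts


@dataclass(frozen=True)
class BurdenSummary:
    """Distribution summary of a burden vector."""

    n: int
    mean: float
    median: float
    min: int
    max: int
    fraction_ge1: float
    histogram: dict[int, int]

    def rounded(self) -> dict[str, float]:
        """Report-layer rounding: means to 2 decimals, fractions to 3."""
        return {
            "n": self.n,
            "mean": round(self.mean, 2),
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "fraction_ge1": round(self.fraction_ge1, 3),
        }


def summarize(counts: np.ndarray | Sequence[int]) -> BurdenSummary:
    """Exact mean/median/min/max/fraction-with->=1 plus integer histogram."""
    arr = np.asarray(counts, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty burden vector")
    values, freqs = np.unique(arr, return_counts=True)
    histogram = {int(v): int(c) for v, c in zip(values, freqs)}
    return BurdenSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        min=int(arr.min()),
        max=int(arr.max()),
        fraction_ge1=float((arr >= 1).sum() / arr.size),
        histogram=histogram,
    )


def group_summaries(
    variants: Sequence[AnnotatedVariant],
    individuals: Sequence[Individual],
    panel: GenePanel,
    predicates: Mapping[str, Predicate],
    *,
    count_alleles: bool = False,
) -> dict[tuple[str, str], BurdenSummary]:
    """One :class:`BurdenSummary` per (ethnicity group, predicate name).

    Groups with zero individuals cannot arise (groups are read off the
    individuals themselves); ordering of individuals does not affect the
    result.
    """
    groups: dict[str, list[Individual]] = {}
    for ind in individuals:
        groups.setdefault(ind.group, []).append(ind)
    out: dict[tuple[str, str], BurdenSummary] = {}
    for name, predicate in predicates.items():
        counts = per_individual_counts(
            variants, individuals, panel, predicate, count_alleles=count_alleles
        )
        by_id = dict(zip((i.id for i in individuals), counts))
        for label, members in groups.items():
            member_counts = np.array([by_id[m.id] for m in members])
            out[(label, name)] = summarize(member_counts)
    return out


def group_table(
    summaries: Mapping[tuple[str, str], BurdenSummary]
) -> pd.DataFrame:
    """Published-table shape: rows = metric per predicate, columns = group."""
    groups = sorted({g for g, _ in summaries})
    predicates = sorted({p for _, p in summaries})
    rows = {}
    rows["n_samples"] = {
        g: next(s.n for (gg, _), s in summaries.items() if gg == g) for g in groups
    }
    for pred in predicates:
        rows[f"mean_{pred}"] = {
            g: round(summaries[(g, pred)].mean, 2) for g in groups if (g, pred) in summaries
        }
        rows[f"fraction_ge1_{pred}"] = {
            g: round(summaries[(g, pred)].fraction_ge1, 3)
            for g in groups
            if (g, pred) in summaries
        }
    return pd.DataFrame(rows).T[groups]


# ---------------------------------------------------------------------------
# Rank-sum comparison of MAF distributions
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Wilcoxon rank-sum by enumeration of rank assignments.

    Enumerates all C(n1+n2, n1) ways the pooled midranks could be split
    between the samples and counts assignments whose Mann-Whitney U is at
    least as far from its null mean as the observed one. Handles ties via
    midranks, which scipy's exact method does not.
    """
    pooled = list(a) + list(b)
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    rank_sum_a = ranks[:n1].sum()
    u_obs = rank_sum_a - n1 * (n1 + 1) / 2.0
    mid = n1 * n2 / 2.0
    obs_dev = abs(u_obs - mid)
    total = extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mid) >= obs_dev - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def maf_rank_test(
    mafs_a: Sequence[float], mafs_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum comparison of two MAF distributions.

    Returns ``(U statistic for the first sample, two-sided p value)``.
    Uses exact enumeration over rank assignments when both samples have at
    most 8 observations, and the normal approximation with tie correction
    (via scipy) otherwise.
    """
    if len(mafs_a) == 0 or len(mafs_b) == 0:
        raise ValueError("both samples must be non-empty")
    if len(mafs_a) <= 8 and len(mafs_b) <= 8:
        return _exact_rank_sum_p(mafs_a, mafs_b)
    result = stats.mannwhitneyu(
        mafs_a, mafs_b, alternative="two-sided", method="asymptotic"
    )
    return float(result.statistic), float(result.pvalue)
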