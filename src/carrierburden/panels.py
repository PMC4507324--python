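"""Gene panels: loading, curation and transcript models.

Three panels drive the analysis: the ACMG secondary-findings (SF) panel of
dominantly acting, medically actionable genes; an autosomal-recessive (AR)
disease-gene panel; and an X-linked recessive (XLR) panel used for female
carrier analysis. The AR and XLR panels are produced from candidate tables
by a deterministic curation rule that mirrors a manual literature review:
a candidate survives if it was already on an established disease-gene list,
or if its OMIM entry was located and shows the inheritance-appropriate
evidence (biallelic disease variants for AR, hemizygous disease in males
for XLR) — and it is not force-excluded (e.g. *TTN*, whose enormous mutation
count would dominate burden statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Inheritance",
    "TranscriptModel",
    "PanelGene",
    "GenePanel",
    "CandidateGene",
    "CurationAudit",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "load_candidates",
    "curate_recessive_panel",
    "load_transcripts",
]


class PanelFormatError(ValueError):
    """A panel/candidate/transcript file does not have the expected columns."""


class PanelValidationError(ValueError):
    """Panel content violates an invariant (e.g. duplicate gene symbols)."""


class Inheritance(str, Enum):
    """Inheritance mode attached to a panel gene."""

    ACTIONABLE = "AD-or-actionable"
    AR = "AR"
    XLR = "XLR"

    @classmethod
    def parse(cls, text: str) -> "Inheritance":
        text = text.strip()
        for member in cls:
            if text == member.value or text == member.name:
                return member
        raise PanelFormatError(f"unknown inheritance mode: {text!r}")


@dataclass(frozen=True)
class TranscriptModel:
    """Canonical transcript of a gene: exon structure plus CDS limits.

    Coordinates are genomic, 0-based half-open for exons; ``cds_start`` and
    ``cds_end`` delimit the coding span ``[cds_start, cds_end)`` regardless
    of strand (``cds_start < cds_end`` always).
    """

    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise PanelValidationError(f"{self.gene}: strand must be '+' or '-'")
        if not self.exons:
            raise PanelValidationError(f"{self.gene}: transcript needs >=1 exon")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise PanelValidationError(f"{self.gene}: empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise PanelValidationError(
                    f"{self.gene}: exons must be sorted and non-overlapping"
                )
            prev_end = end
        if not (self.exons[0][0] <= self.cds_start < self.cds_end <= self.exons[-1][1]):
            raise PanelValidationError(
                f"{self.gene}: CDS [{self.cds_start},{self.cds_end}) outside exon span"
            )

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exons clipped to the CDS, in genomic order (may drop UTR-only exons)."""
        out = []
        for start, end in self.exons:
            s = max(start, self.cds_start)
            e = min(end, self.cds_end)
            if s < e:
                out.append((s, e))
        return out


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    inheritance: Inheritance
    disorders: tuple[str, ...] = ()
    transcript: Optional[TranscriptModel] = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelValidationError("gene symbol must be non-empty")


@dataclass
class GenePanel:
    """An ordered collection of panel genes with unique symbols."""

    name: str
    genes: dict[str, PanelGene] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[PanelGene]) -> "GenePanel":
        panel = cls(name=name)
        for gene in genes:
            panel.add(gene)
        return panel

    def add(self, gene: PanelGene) -> None:
        if gene.symbol in self.genes:
            raise PanelValidationError(
                f"duplicate gene symbol {gene.symbol!r} in panel {self.name!r}"
            )
        self.genes[gene.symbol] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __iter__(self):
        return iter(self.genes.values())

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class CandidateGene:
    """One row of a curation candidate table; all flags must be populated.

    ``evidence`` is inheritance-mode specific: biallelic disease variants for
    AR candidates, hemizygous male disease for XLR candidates.
    """

    symbol: str
    on_prior_lists: bool
    omim_entry_found: bool
    evidence: bool
    force_exclude: bool = False


@dataclass
class CurationAudit:
    """Per-rule exclusion bookkeeping for one curation run."""

    mode: str
    n_candidates: int
    n_retained: int
    n_force_excluded: int
    n_no_evidence: int
    n_no_omim_entry: int

    @property
    def n_excluded(self) -> int:
        return self.n_force_excluded + self.n_no_evidence + self.n_no_omim_entry

    def check(self) -> None:
        if self.n_retained + self.n_excluded != self.n_candidates:
            raise PanelValidationError("curation audit does not balance")


_PANEL_COLUMNS = ("symbol", "inheritance", "disorders")


def load_panel(path: str | Path, name: Optional[str] = None) -> GenePanel:
    """Load a curated panel TSV (columns: symbol, inheritance, disorders).

    Disorders are semicolon-separated. Duplicate symbols are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"{path.name}: missing columns {missing}")
    panel = GenePanel(name=name or path.stem)
    for row in frame.itertuples(index=False):
        disorders = tuple(d for d in str(row.disorders).split(";") if d)
        panel.add(
            PanelGene(
                symbol=str(row.symbol).strip(),
                inheritance=Inheritance.parse(str(row.inheritance)),
                disorders=disorders,
            )
        )
    return panel


_MODE_EVIDENCE_COLUMN = {"AR": "biallelic_evidence", "XLR": "hemizygous_evidence"}

_TRUE = {"1", "true", "yes", "t"}
_FALSE = {"0", "false", "no", "f"}


def _parse_flag(value: object, column: str, symbol: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise PanelFormatError(
        f"candidate {symbol!r}: flag column {column!r} has non-boolean value {value!r}"
    )


def load_candidates(path: str | Path, mode: str) -> list[CandidateGene]:
    """Load a candidate TSV for curation in the given mode ('AR' or 'XLR')."""
    if mode not in _MODE_EVIDENCE_COLUMN:
        raise ValueError(f"unknown curation mode {mode!r}; expected 'AR' or 'XLR'")
    evidence_col = _MODE_EVIDENCE_COLUMN[mode]
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["symbol", "on_prior_lists", "omim_entry_found", evidence_col, "force_exclude"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"{Path(path).name}: missing columns {missing}")
    candidates = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        symbol = str(d["symbol"]).strip()
        candidates.append(
            CandidateGene(
                symbol=symbol,
                on_prior_lists=_parse_flag(d["on_prior_lists"], "on_prior_lists", symbol),
                omim_entry_found=_parse_flag(d["omim_entry_found"], "omim_entry_found", symbol),
                evidence=_parse_flag(d[evidence_col], evidence_col, symbol),
                force_exclude=_parse_flag(d["force_exclude"], "force_exclude", symbol),
            )
        )
    return candidates


def curate_recessive_panel(
    candidates: Sequence[CandidateGene],
    mode: str,
    panel_name: Optional[str] = None,
) -> tuple[GenePanel, CurationAudit]:
    """Apply the curation rule and return the retained panel plus an audit.

    A candidate is retained iff
    ``(on_prior_lists OR (omim_entry_found AND evidence)) AND NOT force_exclude``.
    The audit attributes each exclusion to exactly one rule, checked first to
    last: force-exclusion, missing OMIM entry, missing inheritance evidence.
    """
    if mode not in _MODE_EVIDENCE_COLUMN:
        raise ValueError(f"unknown curation mode {mode!r}; expected 'AR' or 'XLR'")
    inheritance = Inheritance.AR if mode == "AR" else Inheritance.XLR
    retained: list[PanelGene] = []
    n_force = n_no_omim = n_no_evidence = 0
    for cand in candidates:
        if cand.force_exclude:
            n_force += 1
            continue
        if cand.on_prior_lists or (cand.omim_entry_found and cand.evidence):
            retained.append(PanelGene(symbol=cand.symbol, inheritance=inheritance))
        elif not cand.omim_entry_found:
            n_no_omim += 1
        else:
            n_no_evidence += 1
    audit = CurationAudit(
        mode=mode,
        n_candidates=len(candidates),
        n_retained=len(retained),
        n_force_excluded=n_force,
        n_no_evidence=n_no_evidence,
        n_no_omim_entry=n_no_omim,
    )
    audit.check()
    panel = GenePanel.from_genes(panel_name or f"{mode}_panel", retained)
    return panel, audit


_TRANSCRIPT_COLUMNS = (
    "symbol",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
)


def load_transcripts(path: str | Path) -> dict[str, TranscriptModel]:
    """Load the canonical-transcript TSV into a symbol -> model mapping.

    Exon starts/ends are comma-separated 0-based half-open coordinates.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TRANSCRIPT_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"{path.name}: missing columns {missing}")
    models: dict[str, TranscriptModel] = {}
    for row in frame.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).rstrip(",").split(",")]
        ends = [int(x) for x in str(row.exon_ends).rstrip(",").split(",")]
        if len(starts) != len(ends):
            raise PanelFormatError(f"{row.symbol}: exon_starts/exon_ends length mismatch")
        symbol = str(row.symbol).strip()
        if symbol in models:
            raise PanelValidationError(f"duplicate transcript for gene {symbol!r}")
        models[symbol] = TranscriptModel(
            gene=symbol,
            chrom=str(row.chrom),
            strand=str(row.strand),
            exons=tuple(zip(starts, ends)),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
        )
    return models


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel back to the TSV interchange format."""
    rows = [
        {
            "symbol": g.symbol,
            "inheritance": g.inheritance.value,
            "disorders": ";".join(g.disorders),
        }
        for g in panel
    ]
    pd.DataFrame(rows, columns=list(_PANEL_COLUMNS)).to_csv(path, sep="\t", index=False)
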