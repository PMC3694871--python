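"""Build, curate, summarize and serialize the druggable-gene catalog.

The catalog reconciles per-class source lists (specialized databases,
reviews) through the NCBI symbol resolver into a single table: the 15
gene_info columns plus an appended 16th column, ``class``, holding one of
ten druggable class codes. Candidates supported by a single source are
flagged for manual curation; the curation verdicts live in a plain TSV
ledger so the manual step is reproducible and diffable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from .errors import IncompleteCurationError, UnknownClassError
from .ncbi_gene import (
    GENE_INFO_COLUMNS,
    GeneRecord,
    Resolution,
    STATUS_OFFICIAL,
    STATUS_SYNONYM,
    SymbolIndex,
    record_from_fields,
    record_to_fields,
    resolve_symbol,
)

#: The ten druggable classes, code -> display description.
DEFAULT_CLASSES: dict[str, str] = {
    "GPCR": "G-protein coupled receptors",
    "PROTEASES": "Proteases",
    "ST_KINASE": "Serine/Threonine kinases",
    "PROT_INHIB": "Protease inhibitors",
    "Y_KINASE": "Tyrosine kinases",
    "PTP": "Phosphotyrosine phosphatases",
    "NHR": "Nuclear hormone receptors",
    "PTP_MTMR": "Myotubularin related phosphotyrosine phosphatases",
    "PI3K": "Phosphatidylinositol 3 kinases",
    "PTEN": "Phosphatase and tensin homologues",
}


@dataclass
class ClassRegistry:
    """Closed but configurable registry of druggable class codes.

    New classes can be added from configuration without code changes;
    the default registry carries the canonical ten.
    """

    classes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASSES))

    def __contains__(self, code: str) -> bool:
        return code in self.classes

    def validate(self, code: str) -> str:
        if code not in self.classes:
            raise UnknownClassError(code)
        return code

    def add(self, code: str, description: str) -> None:
        self.classes[code] = description

    @property
    def codes(self) -> list[str]:
        return list(self.classes)


DEFAULT_REGISTRY = ClassRegistry()


@dataclass(frozen=True)
class SourceList:
    """Raw identifiers claimed by one source for one class."""

    class_code: str
    source_name: str
    entries: tuple[str, ...]
    id_kind: str = "gene_symbol"  # or "protein_name"

    def __post_init__(self):
        if not self.entries:
            raise ValueError(
                f"source {self.source_name!r} for class {self.class_code} is empty"
            )


@dataclass
class CandidateEntry:
    """A (gene, class) pairing with the sources that support it."""

    gene_id: int
    class_code: str
    supporting_sources: set[str]
    resolution: Resolution

    @property
    def needs_curation(self) -> bool:
        return len(self.supporting_sources) == 1


@dataclass(frozen=True)
class CurationDecision:
    """One recorded manual verdict from the curation ledger."""

    query: str  # gene_id as string, or the raw source identifier
    class_code: str
    verdict: str  # include | exclude
    evidence_tag: str = ""  # homology, experimental_function,
    #                         uniprot_go_check, literature, pseudogene_homolog
    note: str = ""


@dataclass(frozen=True)
class CatalogEntry:
    """One catalog row: a GeneRecord plus the appended class column."""

    record: GeneRecord
    class_code: str

    @property
    def gene_id(self) -> int:
        return self.record.gene_id

    @property
    def symbol(self) -> str:
        return self.record.symbol


def merge_sources(
    sources: list[SourceList],
    index: SymbolIndex,
    registry: ClassRegistry = DEFAULT_REGISTRY,
) -> tuple[list[CandidateEntry], list[Resolution]]:
    """Reconcile per-class source lists through the symbol resolver.

    Returns one CandidateEntry per resolved (gene_id, class) pair carrying
    the union of supporting sources, plus the Resolutions of every query
    that could not be mapped to a single gene (unresolved or ambiguous) —
    those are reported, never silently dropped.
    """
    if not sources:
        raise ValueError("no source lists supplied")
    candidates: dict[tuple[int, str], CandidateEntry] = {}
    rejects: list[Resolution] = []
    order: list[tuple[int, str]] = []
    for source in sources:
        registry.validate(source.class_code)
        for raw in source.entries:
            res = resolve_symbol(index, raw)
            if res.status not in (STATUS_OFFICIAL, STATUS_SYNONYM):
                rejects.append(res)
                continue
            key = (res.gene_id, source.class_code)
            if key not in candidates:
                candidates[key] = CandidateEntry(
                    gene_id=res.gene_id,
                    class_code=source.class_code,
                    supporting_sources=set(),
                    resolution=res,
                )
                order.append(key)
            candidates[key].supporting_sources.add(source.source_name)
    return [candidates[k] for k in order], rejects


def flag_single_source(candidates: list[CandidateEntry]) -> list[CandidateEntry]:
    """Candidates backed by exactly one source, in input order."""
    return [c for c in candidates if c.needs_curation]


def apply_curation(
    candidates: list[CandidateEntry],
    ledger: list[CurationDecision],
    strict: bool = True,
    default_flagged_verdict: str = "exclude",
) -> list[tuple[int, str]]:
    """Apply ledger verdicts; return the accepted (gene_id, class) pairs.

    Multi-source candidates are included unless the ledger explicitly
    excludes them (the build bias is towards inclusion). Single-source
    candidates require a verdict: in strict mode a missing verdict is an
    error; otherwise ``default_flagged_verdict`` applies.
    """
    verdicts: dict[tuple[str, str], str] = {
        (d.query, d.class_code): d.verdict for d in ledger
    }

    def verdict_for(cand: CandidateEntry) -> Optional[str]:
        v = verdicts.get((str(cand.gene_id), cand.class_code))
        if v is None:
            v = verdicts.get((cand.resolution.query, cand.class_code))
        return v

    missing = [
        (c.gene_id, c.class_code)
        for c in candidates
        if c.needs_curation and verdict_for(c) is None
    ]
    if strict and missing:
        raise IncompleteCurationError(missing)

    accepted: list[tuple[int, str]] = []
    for cand in candidates:
        verdict = verdict_for(cand)
        if cand.needs_curation:
            if verdict is None:
                verdict = default_flagged_verdict
            if verdict == "include":
                accepted.append((cand.gene_id, cand.class_code))
        else:
            if verdict != "exclude":
                accepted.append((cand.gene_id, cand.class_code))
    return accepted


def build_entries(
    accepted: Iterable[tuple[int, str]],
    records: Iterable[GeneRecord],
    registry: ClassRegistry = DEFAULT_REGISTRY,
) -> list[CatalogEntry]:
    """Materialize accepted (gene_id, class) pairs into catalog rows."""
    by_id = {r.gene_id: r for r in records}
    entries = []
    for gene_id, class_code in accepted:
        registry.validate(class_code)
        entries.append(CatalogEntry(record=by_id[gene_id], class_code=class_code))
    return entries


def multi_class_genes(entries: list[CatalogEntry]) -> dict[int, list[str]]:
    """Genes appearing under more than one class (for the build report)."""
    seen: dict[int, list[str]] = {}
    for e in entries:
        seen.setdefault(e.gene_id, []).append(e.class_code)
    return {g: codes for g, codes in seen.items() if len(codes) > 1}


# ---------------------------------------------------------------------------
# Serialization: the 16-column catalog format
# ---------------------------------------------------------------------------

CATALOG_HEADER = "\t".join(("#" + GENE_INFO_COLUMNS[0],) + GENE_INFO_COLUMNS[1:] + ("class",))


def write_catalog(entries: list[CatalogEntry], sink: Union[str, Path, IO]) -> None:
    """Write the catalog as 16-column tab-delimited UTF-8 with a header."""
    own = isinstance(sink, (str, Path))
    handle = open(sink, "w", encoding="utf-8", newline="") if own else sink
    try:
        handle.write(CATALOG_HEADER + "\n")
        for entry in entries:
            handle.write(
                "\t".join(record_to_fields(entry.record) + [entry.class_code]) + "\n"
            )
    finally:
        if own:
            handle.close()


def read_catalog(
    source: Union[str, Path, IO, Iterable[str]],
    registry: ClassRegistry = DEFAULT_REGISTRY,
) -> list[CatalogEntry]:
    """Read a 16-column catalog file back into entries.

    Raises :class:`UnknownClassError` on a class code outside the registry.
    """
    own = isinstance(source, (str, Path))
    handle = open(source, "r", encoding="utf-8") if own else source
    entries: list[CatalogEntry] = []
    try:
        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 16:
                raise ValueError(
                    f"catalog row has {len(fields)} fields, expected 16"
                )
            class_code = registry.validate(fields[15])
            entries.append(
                CatalogEntry(record=record_from_fields(fields[:15]), class_code=class_code)
            )
    finally:
        if own:
            handle.close()
    return entries


@dataclass(frozen=True)
class CatalogSummary:
    per_class: dict[str, int]
    total: int


def catalog_summary(entries: Iterable[CatalogEntry]) -> CatalogSummary:
    """Per-class entry counts plus their total."""
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.class_code] = counts.get(e.class_code, 0) + 1
    return CatalogSummary(per_class=counts, total=sum(counts.values()))


def summarize_counts(per_class: dict[str, int]) -> CatalogSummary:
    """Totaling logic applied to pre-tabulated per-class counts."""
    return CatalogSummary(per_class=dict(per_class), total=sum(per_class.values()))


# ---------------------------------------------------------------------------
# Source-list and ledger file I/O (two-column TSV / five-column TSV)
# ---------------------------------------------------------------------------

def read_source_lists(
    path: Union[str, Path],
    class_code: str,
    id_kind: str = "gene_symbol",
) -> list[SourceList]:
    """Read a per-class two-column TSV (identifier, source_name)."""
    groups: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            identifier, source_name = row[0], row[1]
            groups.setdefault(source_name, []).append(identifier)
    return [
        SourceList(class_code=class_code, source_name=name,
                   entries=tuple(items), id_kind=id_kind)
        for name, items in groups.items()
    ]


def write_source_lists(sources: list[SourceList], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("#identifier\tsource_name\n")
        for source in sources:
            for entry in source.entries:
                handle.write(f"{entry}\t{source.source_name}\n")


LEDGER_COLUMNS = ("query", "class", "verdict", "evidence_tag", "note")


def read_ledger(path: Union[str, Path]) -> list[CurationDecision]:
    """Read the curation ledger TSV (query, class, verdict, evidence, note)."""
    decisions = []
    with open(path, encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            row = list(row) + [""] * (5 - len(row))
            decisions.append(
                CurationDecision(
                    query=row[0], class_code=row[1], verdict=row[2],
                    evidence_tag=row[3], note=row[4],
                )
            )
    return decisions


def write_ledger(decisions: list[CurationDecision], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("#" + "\t".join(LEDGER_COLUMNS) + "\n")
        for d in decisions:
            handle.write(
                "\t".join((d.query, d.class_code, d.verdict, d.evidence_tag, d.note))
                + "\n"
            )
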