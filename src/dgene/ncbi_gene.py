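"""NCBI gene_info parsing and gene-symbol resolution.

The NCBI per-species ``gene_info`` file is the mapping authority for every
other component: tab-delimited, one gene per line, comment/header lines
starting with ``#``, and 15 columns whose third (Symbol) and fifth
(Synonyms, ``|``-separated) carry the strings by which genes are named in
the literature. ``-`` is NCBI's placeholder for an empty field.

Resolution policy: a query that equals an *official* symbol always wins,
even when the same string is also listed as a synonym of another gene;
synonyms are consulted only for queries that are not official symbols.
A synonym shared by several genes is reported as ambiguous, never
silently assigned. Matching is exact first, then case-folded (uppercase),
because mutation tables vary wildly in symbol casing.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from .errors import (
    DuplicateGeneIdError,
    InvalidQueryError,
    MalformedRecordError,
    SymbolCollisionError,
)

HUMAN_TAX_ID = 9606

#: Column names of the first 15 gene_info columns, in file order.
GENE_INFO_COLUMNS = (
    "tax_id",
    "GeneID",
    "Symbol",
    "LocusTag",
    "Synonyms",
    "dbXrefs",
    "chromosome",
    "map_location",
    "description",
    "type_of_gene",
    "Symbol_from_nomenclature_authority",
    "Full_name_from_nomenclature_authority",
    "Nomenclature_status",
    "Other_designations",
    "Modification_date",
)


@dataclass(frozen=True)
class GeneRecord:
    """One parsed gene_info row.

    ``synonyms`` never contains the ``-`` placeholder nor the record's own
    official symbol; an empty Synonyms field yields an empty tuple.
    """

    tax_id: int
    gene_id: int
    symbol: str
    locus_tag: str
    synonyms: tuple[str, ...]
    dbxrefs: str
    chromosome: str
    map_location: str
    description: str
    type_of_gene: str
    nomenclature_symbol: str
    nomenclature_full_name: str
    nomenclature_status: str
    other_designations: str
    modification_date: str


def _blank(value: str) -> str:
    return "" if value == "-" else value


def _unblank(value: str) -> str:
    return "-" if value == "" else value


def record_from_fields(fields: list[str]) -> GeneRecord:
    """Build a GeneRecord from the 15 raw column strings."""
    symbol = _blank(fields[2])
    raw_syn = fields[4]
    if raw_syn in ("", "-"):
        synonyms: tuple[str, ...] = ()
    else:
        synonyms = tuple(
            s for s in raw_syn.split("|") if s and s != "-" and s != symbol
        )
    return GeneRecord(
        tax_id=int(fields[0]),
        gene_id=int(fields[1]),
        symbol=symbol,
        locus_tag=_blank(fields[3]),
        synonyms=synonyms,
        dbxrefs=_blank(fields[5]),
        chromosome=_blank(fields[6]),
        map_location=_blank(fields[7]),
        description=_blank(fields[8]),
        type_of_gene=_blank(fields[9]),
        nomenclature_symbol=_blank(fields[10]),
        nomenclature_full_name=_blank(fields[11]),
        nomenclature_status=_blank(fields[12]),
        other_designations=_blank(fields[13]),
        modification_date=_blank(fields[14]),
    )


def record_to_fields(record: GeneRecord) -> list[str]:
    """Inverse of :func:`record_from_fields` (15 raw column strings)."""
    return [
        str(record.tax_id),
        str(record.gene_id),
        _unblank(record.symbol),
        _unblank(record.locus_tag),
        "|".join(record.synonyms) if record.synonyms else "-",
        _unblank(record.dbxrefs),
        _unblank(record.chromosome),
        _unblank(record.map_location),
        _unblank(record.description),
        _unblank(record.type_of_gene),
        _unblank(record.nomenclature_symbol),
        _unblank(record.nomenclature_full_name),
        _unblank(record.nomenclature_status),
        _unblank(record.other_designations),
        _unblank(record.modification_date),
    ]


def _open_text(source: Union[str, Path, IO]) -> Iterator[str]:
    """Yield text lines from a path (plain or .gz) or an open stream."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt", encoding="utf-8") as handle:
            yield from handle
        return
    read = getattr(source, "read", None)
    if read is None:  # plain iterable of lines
        yield from source
        return
    data = read()
    if isinstance(data, bytes):  # byte stream: sniff the gzip magic
        if data[:2] == b"\x1f\x8b":
            data = gzip.decompress(data)
        data = data.decode("utf-8")
    yield from io.StringIO(data)


def parse_gene_info(
    source: Union[str, Path, IO, Iterable[str]],
    species_filter: Optional[int] = HUMAN_TAX_ID,
) -> list[GeneRecord]:
    """Parse a gene_info file into GeneRecords, preserving file order.

    Parameters
    ----------
    source
        Path (optionally ``.gz``), open text/bytes stream, or iterable of
        lines.
    species_filter
        Keep only rows with this tax_id; ``None`` keeps every species.
        Defaults to human (9606).

    Raises
    ------
    MalformedRecordError
        A data line has fewer than 15 tab-separated fields. Lines with
        *extra* trailing columns are accepted with a warning (NCBI has
        appended columns in later releases); only the first 15 are read.
    DuplicateGeneIdError
        Two retained rows share a GeneID.
    """
    records: list[GeneRecord] = []
    seen: set[int] = set()
    for line_number, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 15:
            raise MalformedRecordError(line_number, len(fields))
        if len(fields) > 15:
            warnings.warn(
                f"line {line_number}: {len(fields)} columns; "
                "reading the first 15 only",
                stacklevel=2,
            )
            fields = fields[:15]
        record = record_from_fields(fields)
        if species_filter is not None and record.tax_id != species_filter:
            continue
        if record.gene_id in seen:
            raise DuplicateGeneIdError(record.gene_id, line_number)
        seen.add(record.gene_id)
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# Symbol index and resolution
# ---------------------------------------------------------------------------

#: Resolution status literals.
STATUS_OFFICIAL = "official"
STATUS_SYNONYM = "synonym"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Resolution:
    """Outcome of mapping one query string to a GeneID.

    ``gene_id`` is set exactly when ``status`` is ``official`` or
    ``synonym``; ``candidates`` is non-empty exactly when ``status`` is
    ``ambiguous`` (a synonym claimed by two or more genes).
    ``case_folded`` marks matches found only after uppercase folding.
    """

    query: str
    status: str
    gene_id: Optional[int] = None
    candidates: frozenset[int] = frozenset()
    case_folded: bool = False


@dataclass
class SymbolIndex:
    """Lookup maps from symbol strings to GeneIDs.

    Exact-spelling maps are kept alongside uppercase-folded maps so
    resolution can prefer an exact hit and only then fall back to a
    case-insensitive one (``normalization="casefold"``, the default).
    """

    official: dict[str, int] = field(default_factory=dict)
    synonym: dict[str, set[int]] = field(default_factory=dict)
    official_folded: dict[str, int] = field(default_factory=dict)
    synonym_folded: dict[str, set[int]] = field(default_factory=dict)
    normalization: str = "casefold"
    gene_ids: set[int] = field(default_factory=set)


def build_symbol_index(
    records: list[GeneRecord], normalization: str = "casefold"
) -> SymbolIndex:
    """Index official symbols and synonyms of a record set.

    Raises :class:`SymbolCollisionError` if two records share an official
    symbol (after folding, when ``normalization="casefold"``).
    """
    if normalization not in ("casefold", "exact"):
        raise ValueError(f"unknown normalization policy: {normalization!r}")
    if not records:
        raise ValueError("cannot index an empty record set")
    index = SymbolIndex(normalization=normalization)
    for rec in records:
        index.gene_ids.add(rec.gene_id)
        if rec.symbol:
            if rec.symbol in index.official:
                raise SymbolCollisionError(
                    rec.symbol, {index.official[rec.symbol], rec.gene_id}
                )
            index.official[rec.symbol] = rec.gene_id
            folded = rec.symbol.upper()
            if (
                normalization == "casefold"
                and folded in index.official_folded
                and index.official_folded[folded] != rec.gene_id
            ):
                raise SymbolCollisionError(
                    folded, {index.official_folded[folded], rec.gene_id}
                )
            index.official_folded[folded] = rec.gene_id
        for syn in rec.synonyms:
            index.synonym.setdefault(syn, set()).add(rec.gene_id)
            index.synonym_folded.setdefault(syn.upper(), set()).add(rec.gene_id)
    return index


def _synonym_resolution(
    query: str, hits: set[int], case_folded: bool
) -> Resolution:
    if len(hits) == 1:
        return Resolution(
            query, STATUS_SYNONYM, gene_id=next(iter(hits)),
            case_folded=case_folded,
        )
    return Resolution(
        query, STATUS_AMBIGUOUS, candidates=frozenset(hits),
        case_folded=case_folded,
    )


def resolve_symbol(index: SymbolIndex, query: str) -> Resolution:
    """Resolve a symbol-like string against the index.

    Official symbols take absolute precedence over synonyms; an exact
    spelling match takes precedence over a case-folded one. A pure
    function of (index, query).
    """
    if not isinstance(query, str) or not query.strip():
        raise InvalidQueryError(f"empty or whitespace-only query: {query!r}")
    q = query.strip()
    if q in index.official:
        return Resolution(q, STATUS_OFFICIAL, gene_id=index.official[q])
    fold = index.normalization == "casefold"
    if fold and q.upper() in index.official_folded:
        return Resolution(
            q, STATUS_OFFICIAL, gene_id=index.official_folded[q.upper()],
            case_folded=True,
        )
    if q in index.synonym:
        return _synonym_resolution(q, index.synonym[q], case_folded=False)
    if fold and q.upper() in index.synonym_folded:
        return _synonym_resolution(
            q, index.synonym_folded[q.upper()], case_folded=True
        )
    return Resolution(q, STATUS_UNRESOLVED)
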