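"""Annotate somatic mutation tables with druggable-class membership.

Given a mutation table (minimally patient identifier + gene), each row is
resolved to an NCBI GeneID — by direct numeric join when the table carries
GeneIDs, otherwise through the symbol resolver — and, when the gene sits
in the druggable catalog, the class term is appended as a new column.
Downstream screens reduce the annotated table to druggable rows, to genes
recurrently mutated across patients, and to patient x class / gene x
patient matrices.

Ambiguous symbol resolutions never receive a class: they are retained with
their status so a reviewer can adjudicate, but are excluded from the
druggable table rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .catalog_builder import CatalogEntry
from .ncbi_gene import (
    Resolution,
    STATUS_AMBIGUOUS,
    STATUS_OFFICIAL,
    STATUS_SYNONYM,
    STATUS_UNRESOLVED,
    SymbolIndex,
    build_symbol_index,
    resolve_symbol,
)

logger = logging.getLogger(__name__)

#: Status literal for rows joined directly by numeric GeneID.
STATUS_GENE_ID = "gene_id"

#: Column aliases recognized in mutation tables (MAF-style names included).
PATIENT_ALIASES = ("patient_id", "patient", "sample", "Tumor_Sample_Barcode")
SYMBOL_ALIASES = ("gene", "gene_symbol", "symbol", "Hugo_Symbol")
GENE_ID_ALIASES = ("gene_id", "entrez_id", "Entrez_Gene_Id")
VARIANT_ALIASES = ("variant", "protein_change", "HGVSp", "Protein_Change")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation row: who and in which gene."""

    patient_id: str
    gene: Union[str, int]
    variant: Optional[str] = None

    def __post_init__(self):
        if not str(self.patient_id).strip() or not str(self.gene).strip():
            raise ValueError("patient_id and gene must be non-empty")


@dataclass(frozen=True)
class AnnotatedMutation:
    """A MutationRecord with its resolution outcome and catalog class."""

    patient_id: str
    gene: Union[str, int]
    variant: Optional[str]
    gene_id: Optional[int]
    class_code: Optional[str]
    resolution_status: str
    symbol: Optional[str] = None  # official symbol, when the gene resolved


def catalog_class_map(catalog: Iterable[CatalogEntry]) -> dict[int, str]:
    """gene_id -> class code (first class wins for multi-class genes)."""
    mapping: dict[int, str] = {}
    for entry in catalog:
        mapping.setdefault(entry.gene_id, entry.class_code)
    return mapping


def index_from_catalog(catalog: list[CatalogEntry]) -> SymbolIndex:
    """Build a resolver index from the catalog's own gene_info columns.

    Sufficient for druggable filtering when no full gene_info file is at
    hand; official-symbol precedence is then guaranteed only within the
    catalog's records.
    """
    return build_symbol_index([e.record for e in catalog])


def _resolve_gene(
    gene: Union[str, int], index: Optional[SymbolIndex]
) -> tuple[Optional[int], str]:
    """Return (gene_id, status) for one gene field.

    A positive numeric id is taken at face value (the study's tables carry
    up-to-date GeneIDs); whether it is druggable is decided by the catalog
    join. Symbols go through the resolver.
    """
    text = str(gene).strip()
    if isinstance(gene, int) or text.isdigit():
        gid = int(text)
        if gid > 0:
            return gid, STATUS_GENE_ID
        return None, STATUS_UNRESOLVED
    if index is None:
        return None, STATUS_UNRESOLVED
    res: Resolution = resolve_symbol(index, text)
    if res.status in (STATUS_OFFICIAL, STATUS_SYNONYM):
        return res.gene_id, res.status
    return None, res.status


def annotate_mutations(
    muts: list[MutationRecord],
    catalog: list[CatalogEntry],
    index: Optional[SymbolIndex] = None,
) -> list[AnnotatedMutation]:
    """Resolve every mutation's gene and append the catalog class.

    Every input row is preserved. Numeric GeneIDs join directly (the
    preferred path); symbols go through :func:`resolve_symbol`. The class
    column is set only when the resolved gene is in the catalog.
    Unresolved and ambiguous rows keep their status and are logged.
    """
    if index is None:
        index = index_from_catalog(catalog) if catalog else None
    class_map = catalog_class_map(catalog)
    symbol_map = {e.gene_id: e.symbol for e in catalog}
    if index is not None:
        official_by_id = {gid: sym for sym, gid in index.official.items()}
    else:
        official_by_id = {}

    annotated: list[AnnotatedMutation] = []
    n_problem = 0
    for mut in muts:
        gene_id, status = _resolve_gene(mut.gene, index)
        class_code = class_map.get(gene_id) if gene_id is not None else None
        if status in (STATUS_AMBIGUOUS, STATUS_UNRESOLVED):
            n_problem += 1
        annotated.append(
            AnnotatedMutation(
                patient_id=mut.patient_id,
                gene=mut.gene,
                variant=mut.variant,
                gene_id=gene_id,
                class_code=class_code,
                resolution_status=status,
                symbol=symbol_map.get(gene_id) or official_by_id.get(gene_id),
            )
        )
    if n_problem:
        logger.warning(
            "%d of %d mutation rows were ambiguous or unresolved", n_problem, len(muts)
        )
    return annotated


def filter_druggable(annotated: list[AnnotatedMutation]) -> list[AnnotatedMutation]:
    """Exactly the rows with a class term, in input order."""
    return [row for row in annotated if row.class_code is not None]


def recurrence_table(
    filtered: list[AnnotatedMutation], min_patients: int = 1
) -> pd.DataFrame:
    """Per-gene recurrence across patients.

    One row per gene with the distinct-patient count (a patient with
    several mutations in one gene counts once) and the raw event count;
    genes seen in fewer than ``min_patients`` patients are dropped.
    Sorted by n_patients descending, then symbol.
    """
    if min_patients < 1:
        raise ValueError(f"min_patients must be >= 1, got {min_patients}")
    rows: dict[int, dict] = {}
    for row in filtered:
        slot = rows.setdefault(
            row.gene_id,
            {
                "gene_id": row.gene_id,
                "symbol": row.symbol or str(row.gene),
                "class_code": row.class_code,
                "patients": set(),
                "n_mutations": 0,
            },
        )
        slot["patients"].add(row.patient_id)
        slot["n_mutations"] += 1
    data = [
        {
            "gene_id": s["gene_id"],
            "symbol": s["symbol"],
            "class_code": s["class_code"],
            "n_patients": len(s["patients"]),
            "n_mutations": s["n_mutations"],
        }
        for s in rows.values()
        if len(s["patients"]) >= min_patients
    ]
    frame = pd.DataFrame(
        data, columns=["gene_id", "symbol", "class_code", "n_patients", "n_mutations"]
    )
    return frame.sort_values(
        ["n_patients", "symbol"], ascending=[False, True]
    ).reset_index(drop=True)


def class_by_patient_matrix(filtered: list[AnnotatedMutation]) -> pd.DataFrame:
    """Patients x classes matrix of druggable event counts.

    Cell sums equal the number of filtered rows.
    """
    if not filtered:
        return pd.DataFrame()
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in filtered],
            "class_code": [r.class_code for r in filtered],
        }
    )
    return (
        frame.groupby(["patient_id", "class_code"])
        .size()
        .unstack(fill_value=0)
        .rename_axis(index=None, columns=None)
    )


def gene_by_patient_matrix(filtered: list[AnnotatedMutation]) -> pd.DataFrame:
    """Genes x patients 0/1 presence matrix; row sums = n_patients per gene."""
    if not filtered:
        return pd.DataFrame()
    frame = pd.DataFrame(
        {
            "symbol": [r.symbol or str(r.gene) for r in filtered],
            "patient_id": [r.patient_id for r in filtered],
        }
    )
    matrix = (
        frame.groupby(["symbol", "patient_id"]).size().unstack(fill_value=0)
    )
    return (matrix > 0).astype(int).rename_axis(index=None, columns=None)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _pick(columns, aliases, mapping, key):
    if mapping and key in mapping:
        return mapping[key]
    for alias in aliases:
        if alias in columns:
            return alias
    return None


def read_mutation_table(
    path: Union[str, Path],
    column_mapping: Optional[dict[str, str]] = None,
) -> list[MutationRecord]:
    """Read a mutation TSV, recognizing minimal-MAF column names.

    ``column_mapping`` may override the detected columns with keys
    ``patient``, ``symbol``, ``gene_id``, ``variant``. When both a symbol
    and a positive Entrez_Gene_Id are present the numeric id is used.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    cols = set(frame.columns)
    patient_col = _pick(cols, PATIENT_ALIASES, column_mapping, "patient")
    symbol_col = _pick(cols, SYMBOL_ALIASES, column_mapping, "symbol")
    id_col = _pick(cols, GENE_ID_ALIASES, column_mapping, "gene_id")
    variant_col = _pick(cols, VARIANT_ALIASES, column_mapping, "variant")
    if patient_col is None or (symbol_col is None and id_col is None):
        raise ValueError(
            f"cannot identify patient/gene columns among {sorted(cols)}"
        )
    records = []
    for _, row in frame.iterrows():
        gene: Union[str, int, None] = None
        if id_col is not None and pd.notna(row.get(id_col)):
            raw = str(row[id_col]).strip()
            if raw.isdigit() and int(raw) > 0:
                gene = int(raw)
        if gene is None and symbol_col is not None and pd.notna(row.get(symbol_col)):
            gene = str(row[symbol_col]).strip()
        if gene is None or gene == "":
            continue
        variant = None
        if variant_col is not None and pd.notna(row.get(variant_col)):
            variant = str(row[variant_col])
        records.append(
            MutationRecord(patient_id=str(row[patient_col]), gene=gene, variant=variant)
        )
    return records


def annotated_to_frame(annotated: list[AnnotatedMutation]) -> pd.DataFrame:
    """Flatten annotated rows for TSV export (input columns + gene_id + class)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in annotated],
            "gene": [r.gene for r in annotated],
            "variant": [r.variant for r in annotated],
            "gene_id": [r.gene_id for r in annotated],
            "symbol": [r.symbol for r in annotated],
            "class": [r.class_code for r in annotated],
            "resolution_status": [r.resolution_status for r in annotated],
        }
    )
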