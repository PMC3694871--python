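"""Screen per-patient per-gene copy-number ratios and intersect with the catalog.

One event is one patient x gene fold-change measurement (1.0 = copy
neutral). The screen keeps only events strictly below a low cutoff or
strictly above a high cutoff; cutoffs come either as absolute ratios
(0.7x / 1.5x in the reference analysis) or as percentile ranks of the
pooled ratio distribution across all patients and genes (20th / 80th).
Passing events are intersected with the druggable catalog, split into
gains and losses, and a gene-family view renders every member of one
class against relaxed display cutoffs so sub-threshold changes stay
visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .catalog_builder import CatalogEntry, ClassRegistry, DEFAULT_REGISTRY
from .errors import InvalidThresholdError
from .ncbi_gene import SymbolIndex
from .snv_annotator import _resolve_gene, catalog_class_map, index_from_catalog

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CopyNumberEvent:
    """One patient x gene fold-change measurement."""

    patient_id: str
    gene: Union[str, int]
    cn_ratio: float

    def __post_init__(self):
        if not self.cn_ratio > 0:
            raise ValueError(f"cn_ratio must be positive, got {self.cn_ratio}")


@dataclass(frozen=True)
class DruggableCnEvent(CopyNumberEvent):
    """A screened event resolved into the catalog."""

    gene_id: int = 0
    class_code: str = ""
    symbol: str = ""


@dataclass(frozen=True)
class CnThresholds:
    """Resolved low/high ratio cutoffs and how they were specified.

    ``mode`` is ``absolute`` (low_spec/high_spec are ratios) or
    ``percentile`` (they are percentile ranks in (0, 100)).
    ``quantile_method`` names the estimator used in percentile mode;
    the default is linear interpolation between order statistics.
    """

    mode: str
    low_spec: float
    high_spec: float
    low_ratio: float
    high_ratio: float
    quantile_method: str = "linear"


def resolve_thresholds(
    events: Optional[Iterable[CopyNumberEvent]],
    mode: str = "absolute",
    low: float = 0.7,
    high: float = 1.5,
    quantile_method: str = "linear",
) -> CnThresholds:
    """Turn a threshold specification into concrete ratio cutoffs.

    Percentile mode pools every event's ratio (all patients x genes) and
    takes the stated quantiles with the declared estimator. The resolved
    cutoffs must satisfy low_ratio < high_ratio, otherwise the
    distribution is too degenerate to screen.
    """
    if mode == "absolute":
        low_ratio, high_ratio = float(low), float(high)
    elif mode == "percentile":
        if not (0 < low < 100 and 0 < high < 100):
            raise InvalidThresholdError(
                f"percentile ranks must lie in (0, 100): {low}, {high}"
            )
        if low >= high:
            raise InvalidThresholdError(f"low percentile >= high: {low} >= {high}")
        ratios = np.asarray([e.cn_ratio for e in events], dtype=float)
        if ratios.size == 0:
            raise InvalidThresholdError("percentile mode requires events")
        low_ratio = float(np.percentile(ratios, low, method=quantile_method))
        high_ratio = float(np.percentile(ratios, high, method=quantile_method))
    else:
        raise InvalidThresholdError(f"unknown threshold mode: {mode!r}")
    if not low_ratio < high_ratio:
        raise InvalidThresholdError(
            f"resolved cutoffs are degenerate: low {low_ratio} >= high {high_ratio}"
        )
    return CnThresholds(
        mode=mode, low_spec=float(low), high_spec=float(high),
        low_ratio=low_ratio, high_ratio=high_ratio,
        quantile_method=quantile_method,
    )


def screen_events(
    events: Iterable[CopyNumberEvent], thresholds: CnThresholds
) -> list[CopyNumberEvent]:
    """Events strictly below the low or strictly above the high cutoff.

    Events exactly at a cutoff are copy-change candidates the screen
    rejects: the inequalities are strict on both sides.
    """
    return [
        e
        for e in events
        if e.cn_ratio < thresholds.low_ratio or e.cn_ratio > thresholds.high_ratio
    ]


def filter_druggable_cn(
    passing: Iterable[CopyNumberEvent],
    catalog: list[CatalogEntry],
    index: Optional[SymbolIndex] = None,
) -> list[DruggableCnEvent]:
    """Subset of screened events whose gene resolves into the catalog."""
    if index is None:
        index = index_from_catalog(catalog) if catalog else None
    class_map = catalog_class_map(catalog)
    symbol_map = {e.gene_id: e.symbol for e in catalog}
    out: list[DruggableCnEvent] = []
    n_problem = 0
    for event in passing:
        gene_id, status = _resolve_gene(event.gene, index)
        if status in ("ambiguous", "unresolved"):
            n_problem += 1
            continue
        if gene_id in class_map:
            out.append(
                DruggableCnEvent(
                    patient_id=event.patient_id,
                    gene=event.gene,
                    cn_ratio=event.cn_ratio,
                    gene_id=gene_id,
                    class_code=class_map[gene_id],
                    symbol=symbol_map[gene_id],
                )
            )
    if n_problem:
        logger.warning("%d CN events were ambiguous or unresolved", n_problem)
    return out


def split_gain_loss(
    druggable: list[DruggableCnEvent], thresholds: CnThresholds
) -> tuple[list[DruggableCnEvent], list[DruggableCnEvent]]:
    """Partition screened events into (gains, losses); disjoint and complete."""
    gains = [e for e in druggable if e.cn_ratio > thresholds.high_ratio]
    losses = [e for e in druggable if e.cn_ratio < thresholds.low_ratio]
    return gains, losses


def family_view(
    events: Iterable[CopyNumberEvent],
    catalog: list[CatalogEntry],
    class_code: str,
    display_thresholds: Optional[CnThresholds] = None,
    index: Optional[SymbolIndex] = None,
    registry: ClassRegistry = DEFAULT_REGISTRY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x patients ratio matrix for one class, with a pass/fail mask.

    Takes *unscreened* events so relaxed display cutoffs (default
    <0.85x / >1.15x) can reveal changes below the analysis thresholds.
    Returns (matrix, mask): matrix cells are cn_ratio (NaN where
    unmeasured); mask is True where the cell lies outside the display
    cutoffs. Per-gene loss/gain patient counts follow from the mask.
    """
    registry.validate(class_code)
    if display_thresholds is None:
        display_thresholds = resolve_thresholds(None, "absolute", 0.85, 1.15)
    family = [e for e in catalog if e.class_code == class_code]
    if not family:
        logger.warning("class %s has no catalog members; empty matrix", class_code)
        return pd.DataFrame(), pd.DataFrame()
    if index is None:
        index = index_from_catalog(catalog)
    family_ids = {e.gene_id: e.symbol for e in family}
    cells: dict[tuple[str, str], float] = {}
    patients: list[str] = []
    seen_patients: set[str] = set()
    for event in events:
        gene_id, status = _resolve_gene(event.gene, index)
        if event.patient_id not in seen_patients:
            seen_patients.add(event.patient_id)
            patients.append(event.patient_id)
        if gene_id in family_ids:
            cells[(family_ids[gene_id], event.patient_id)] = event.cn_ratio
    symbols = sorted(family_ids.values())
    matrix = pd.DataFrame(np.nan, index=symbols, columns=patients, dtype=float)
    for (symbol, patient), ratio in cells.items():
        matrix.loc[symbol, patient] = ratio
    mask = (matrix < display_thresholds.low_ratio) | (
        matrix > display_thresholds.high_ratio
    )
    mask = mask.fillna(False).astype(bool)
    return matrix, mask


def family_loss_gain_counts(
    matrix: pd.DataFrame, thresholds: CnThresholds
) -> pd.DataFrame:
    """Per-gene counts of patients with a loss / gain at the given cutoffs."""
    losses = (matrix < thresholds.low_ratio).sum(axis=1)
    gains = (matrix > thresholds.high_ratio).sum(axis=1)
    return pd.DataFrame(
        {"n_loss_patients": losses.astype(int), "n_gain_patients": gains.astype(int)}
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

CN_PATIENT_ALIASES = ("patient_id", "patient", "sample", "Tumor_Sample_Barcode")
CN_GENE_ALIASES = ("gene", "gene_symbol", "symbol", "Hugo_Symbol", "gene_id",
                   "Entrez_Gene_Id")
CN_RATIO_ALIASES = ("cn_ratio", "ratio", "fold_change", "copy_number_ratio", "CN")


def read_cn_table(
    path: Union[str, Path],
    column_mapping: Optional[dict[str, str]] = None,
) -> list[CopyNumberEvent]:
    """Read a per-patient per-gene copy-number ratio TSV."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    cols = set(frame.columns)

    def pick(aliases, key):
        if column_mapping and key in column_mapping:
            return column_mapping[key]
        for alias in aliases:
            if alias in cols:
                return alias
        return None

    patient_col = pick(CN_PATIENT_ALIASES, "patient")
    gene_col = pick(CN_GENE_ALIASES, "gene")
    ratio_col = pick(CN_RATIO_ALIASES, "ratio")
    if patient_col is None or gene_col is None or ratio_col is None:
        raise ValueError(f"cannot identify CN columns among {sorted(cols)}")
    events = []
    for _, row in frame.iterrows():
        gene_raw = str(row[gene_col]).strip()
        gene: Union[str, int] = int(gene_raw) if gene_raw.isdigit() else gene_raw
        events.append(
            CopyNumberEvent(
                patient_id=str(row[patient_col]),
                gene=gene,
                cn_ratio=float(row[ratio_col]),
            )
        )
    return events


def cn_events_to_frame(events: Iterable[CopyNumberEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        row = {"patient_id": e.patient_id, "gene": e.gene, "cn_ratio": e.cn_ratio}
        if isinstance(e, DruggableCnEvent):
            row.update(gene_id=e.gene_id, symbol=e.symbol, **{"class": e.class_code})
        rows.append(row)
    return pd.DataFrame(rows)
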