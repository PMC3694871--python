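"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates a miniature gene universe (valid 15-column gene_info text),
per-class source lists with single-source decoys and a matching curation
ledger, a patient x gene somatic-mutation table, and a patient x gene
copy-number ratio table. Every count a pipeline stage should recover —
druggable mutation rows, recurrent genes, events passing the
copy-number screen, gains/losses, per-family loss patterns — is tallied
*while sampling*, so a generator bug cannot be cancelled by a matching
pipeline bug.

The default specification emulates the shape of the reference breast
cancer analysis at reduced gene count: 77 patients with ~34 somatic
mutations each of which ~14% fall in druggable genes, and a 46-patient
copy-number grid with ~36% of events outside the 0.7x/1.5x cutoffs.
Symbols use a reserved GSYN/SYN namespace so no fixture symbol collides
with a real human gene name.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

from .catalog_builder import (
    CatalogEntry,
    CurationDecision,
    DEFAULT_CLASSES,
    SourceList,
)
from .errors import FixtureSpecError
from .ncbi_gene import GeneRecord, record_to_fields

GENE_INFO_HEADER = (
    "#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs\tchromosome\t"
    "map_location\tdescription\ttype_of_gene\t"
    "Symbol_from_nomenclature_authority\tFull_name_from_nomenclature_authority\t"
    "Nomenclature_status\tOther_designations\tModification_date"
)

#: Default per-class planted memberships: the reference class-size profile
#: scaled to a ~100-gene druggable core; the PTEN family keeps its real
#: size (7) because the family view is exercised on it.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "GPCR": 22,
    "PROTEASES": 15,
    "ST_KINASE": 11,
    "PROT_INHIB": 6,
    "Y_KINASE": 5,
    "PTP": 4,
    "NHR": 3,
    "PTP_MTMR": 2,
    "PI3K": 2,
    "PTEN": 7,
}


@dataclass
class FixtureSpec:
    """Knobs of the synthetic study; defaults mirror the reference analysis."""

    n_genes: int = 400
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    n_patients: int = 77  # mutation cohort
    n_cn_patients: int = 46  # copy-number cohort (whole-genome subset)
    snv_rate: float = 34.0  # expected mutations per patient (2622/77)
    druggable_snv_fraction: float = 0.14  # 368/2622
    cn_outlier_fraction: float = 0.36  # 54301 of ~150000 events
    synonym_collision_count: int = 2
    decoys_per_class: int = 2  # single-source candidates with exclude verdicts
    unmappable_per_class: int = 1
    seed: int = 0

    def validate(self) -> None:
        n_druggable = sum(self.class_sizes.values())
        if self.n_genes <= 0:
            raise FixtureSpecError("n_genes must be positive")
        reserved = (
            n_druggable
            + len(self.class_sizes) * self.decoys_per_class
            + 2 * self.synonym_collision_count
            + 2
        )
        if reserved > self.n_genes:
            raise FixtureSpecError(
                f"class sizes + decoys need {reserved} genes, only {self.n_genes} available"
            )
        for name in ("druggable_snv_fraction", "cn_outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise FixtureSpecError(f"{name} must lie in [0, 1], got {v}")
        unknown = set(self.class_sizes) - set(DEFAULT_CLASSES)
        if unknown:
            raise FixtureSpecError(f"unknown class codes in class_sizes: {unknown}")

    @property
    def n_druggable(self) -> int:
        return sum(self.class_sizes.values())


@dataclass
class GroundTruth:
    """Expected counts recorded at generation time, by construction."""

    druggable_by_class: dict[str, list[int]] = field(default_factory=dict)
    ambiguous_synonyms: list[str] = field(default_factory=list)
    official_synonym_overlap: Optional[str] = None
    decoy_gene_ids: dict[str, list[int]] = field(default_factory=dict)
    # SNV table
    snv_total_rows: int = 0
    druggable_snv_rows: int = 0
    druggable_snv_genes: int = 0
    recurrent_gene_ids_min2: list[int] = field(default_factory=list)
    # CN table
    cn_total_events: int = 0
    cn_pass_events: int = 0
    cn_pass_genes: int = 0
    cn_druggable_events: int = 0
    cn_druggable_genes: int = 0
    cn_gains: int = 0
    cn_losses: int = 0
    family_class: str = "PTEN"
    family_loss_counts: dict[str, int] = field(default_factory=dict)
    family_gain_counts: dict[str, int] = field(default_factory=dict)

    @property
    def recurrent_genes_min2(self) -> int:
        return len(self.recurrent_gene_ids_min2)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["recurrent_genes_min2"] = self.recurrent_genes_min2
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class FixtureUniverse:
    """The generated gene universe plus the planted class structure."""

    records: list[GeneRecord]
    gene_info_text: str
    class_members: dict[str, list[int]]  # class -> planted druggable gene_ids
    decoys: dict[str, list[int]]  # class -> single-source decoy gene_ids
    truth: GroundTruth

    @property
    def druggable_ids(self) -> set[int]:
        return {g for ids in self.class_members.values() for g in ids}

    @property
    def records_by_id(self) -> dict[int, GeneRecord]:
        return {r.gene_id: r for r in self.records}


def _gene_id(i: int) -> int:
    return 1001 + i


def _symbol(i: int) -> str:
    return f"GSYN{i:04d}"


def make_gene_universe(spec: FixtureSpec) -> FixtureUniverse:
    """Generate a valid gene_info universe with planted resolver hazards.

    Plants ``synonym_collision_count`` synonyms shared by two genes each
    (ambiguous lookups) and one string that is simultaneously a synonym of
    one gene and the official symbol of another (official precedence
    check). Hazards are planted among non-druggable, non-decoy genes so
    catalog construction is unaffected. Deterministic under the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    chroms = [str(c) for c in range(1, 23)] + ["X", "Y"]

    # Partition: [druggable classes][decoys per class][hazard pool][rest]
    class_members: dict[str, list[int]] = {}
    cursor = 0
    for code, size in spec.class_sizes.items():
        class_members[code] = [_gene_id(i) for i in range(cursor, cursor + size)]
        cursor += size
    decoys: dict[str, list[int]] = {}
    for code in spec.class_sizes:
        decoys[code] = [
            _gene_id(i) for i in range(cursor, cursor + spec.decoys_per_class)
        ]
        cursor += spec.decoys_per_class
    hazard_start = cursor

    records: list[GeneRecord] = []
    synonyms_by_gene: dict[int, list[str]] = {}
    for i in range(n):
        gid = _gene_id(i)
        n_syn = int(rng.integers(0, 4))
        syns = [f"SYN{i:04d}{chr(65 + j)}" for j in range(n_syn)]
        synonyms_by_gene[gid] = syns
        records.append(
            GeneRecord(
                tax_id=9606,
                gene_id=gid,
                symbol=_symbol(i),
                locus_tag="",
                synonyms=tuple(syns),
                dbxrefs="",
                chromosome=str(chroms[int(rng.integers(0, len(chroms)))]),
                map_location="",
                description=f"synthetic gene {i}",
                type_of_gene="protein-coding",
                nomenclature_symbol=_symbol(i),
                nomenclature_full_name=f"synthetic gene {i}",
                nomenclature_status="O",
                other_designations="",
                modification_date="20130703",
            )
        )

    truth = GroundTruth(
        druggable_by_class={c: list(ids) for c, ids in class_members.items()},
        decoy_gene_ids={c: list(ids) for c, ids in decoys.items()},
    )

    # Planted hazards live in the non-druggable tail starting at hazard_start.
    def with_extra_synonym(idx: int, extra: str) -> None:
        rec = records[idx]
        records[idx] = replace(rec, synonyms=rec.synonyms + (extra,))

    h = hazard_start
    for k in range(spec.synonym_collision_count):
        shared = f"AMBSYN{k:03d}"
        with_extra_synonym(h, shared)
        with_extra_synonym(h + 1, shared)
        truth.ambiguous_synonyms.append(shared)
        h += 2
    # One gene's official symbol is also another gene's synonym.
    overlap_symbol = records[h + 1].symbol
    with_extra_synonym(h, overlap_symbol)
    truth.official_synonym_overlap = overlap_symbol

    lines = [GENE_INFO_HEADER]
    lines.extend("\t".join(record_to_fields(r)) for r in records)
    text = "\n".join(lines) + "\n"
    return FixtureUniverse(
        records=records,
        gene_info_text=text,
        class_members=class_members,
        decoys=decoys,
        truth=truth,
    )


def make_catalog_sources(
    spec: FixtureSpec, universe: FixtureUniverse
) -> tuple[list[SourceList], list[CurationDecision]]:
    """Per-class source lists plus the curation ledger.

    Two sources per class both carry the full planted membership (some
    entries spelled as synonyms or case-mangled to exercise the
    resolver); the first source additionally carries single-source decoy
    genes, each given an exclude verdict in the ledger, and optionally
    unmappable names that must land in the rejects report. Applying
    curation therefore recovers exactly the planted class sizes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    by_id = universe.records_by_id
    sources: list[SourceList] = []
    ledger: list[CurationDecision] = []
    for code, members in universe.class_members.items():
        entries_a: list[str] = []
        entries_b: list[str] = []
        for gid in members:
            rec = by_id[gid]
            entries_a.append(rec.symbol)
            # Source B sometimes names the gene by synonym or odd casing.
            pick = rng.random()
            if pick < 0.3 and rec.synonyms:
                entries_b.append(rec.synonyms[0])
            elif pick < 0.5:
                entries_b.append(rec.symbol.lower())
            else:
                entries_b.append(rec.symbol)
        for gid in universe.decoys[code]:
            entries_a.append(by_id[gid].symbol)
            ledger.append(
                CurationDecision(
                    query=str(gid),
                    class_code=code,
                    verdict="exclude",
                    evidence_tag="uniprot_go_check",
                    note="single-source decoy; not confirmed",
                )
            )
        for k in range(spec.unmappable_per_class):
            entries_a.append(f"NOSUCHGENE_{code}_{k}")
        sources.append(
            SourceList(class_code=code, source_name=f"{code}_db",
                       entries=tuple(entries_a))
        )
        sources.append(
            SourceList(class_code=code, source_name=f"{code}_review",
                       entries=tuple(entries_b))
        )
    return sources, ledger


def simulate_snv_table(
    spec: FixtureSpec, universe: FixtureUniverse
) -> tuple[str, GroundTruth]:
    """Simulate the somatic mutation table; tally truth while sampling.

    Per patient the mutation count is Poisson(snv_rate); each mutation
    falls in a druggable gene with probability druggable_snv_fraction,
    uniformly within the pool. Rows alternate between carrying a numeric
    GeneID and a bare symbol (sometimes case-mangled) so both join paths
    are exercised. Updates and returns the universe's GroundTruth.
    """
    rng = np.random.default_rng(spec.seed + 2)
    truth = universe.truth
    by_id = universe.records_by_id
    druggable = sorted(universe.druggable_ids)
    non_druggable = sorted(set(by_id) - universe.druggable_ids)

    lines = ["#patient_id\tHugo_Symbol\tEntrez_Gene_Id\tProtein_Change"]
    druggable_rows = 0
    patients_per_gene: dict[int, set[str]] = {}
    total = 0
    for p in range(spec.n_patients):
        patient = f"PT{p + 1:03d}"
        n_mut = int(rng.poisson(spec.snv_rate))
        for _ in range(n_mut):
            is_druggable = rng.random() < spec.druggable_snv_fraction
            pool = druggable if is_druggable else non_druggable
            gid = int(pool[int(rng.integers(0, len(pool)))])
            rec = by_id[gid]
            total += 1
            if is_druggable:
                druggable_rows += 1
                patients_per_gene.setdefault(gid, set()).add(patient)
            variant = f"p.A{int(rng.integers(1, 900))}T"
            if rng.random() < 0.5:  # id-typed row (MAF convention: 0 = unknown)
                lines.append(f"{patient}\t{rec.symbol}\t{gid}\t{variant}")
            else:  # symbol-typed row, sometimes lower-cased
                sym = rec.symbol.lower() if rng.random() < 0.2 else rec.symbol
                lines.append(f"{patient}\t{sym}\t0\t{variant}")
    truth.snv_total_rows = total
    truth.druggable_snv_rows = druggable_rows
    truth.druggable_snv_genes = len(patients_per_gene)
    truth.recurrent_gene_ids_min2 = sorted(
        g for g, pats in patients_per_gene.items() if len(pats) >= 2
    )
    return "\n".join(lines) + "\n", truth


def simulate_cn_table(
    spec: FixtureSpec, universe: FixtureUniverse
) -> tuple[str, GroundTruth]:
    """Simulate the per-patient per-gene copy-number grid.

    Each patient x gene cell draws, with probability cn_outlier_fraction,
    an outlier ratio (half losses uniform on [0.35, 0.695], half gains
    uniform on [1.505, 3.0]) and otherwise a copy-neutral ratio strictly
    inside (0.7, 1.5) (lognormal, sigma 0.08, rejection-sampled into
    [0.71, 1.49]). Pass/gain/loss, druggable and family tallies are
    recorded per draw. Family loss/gain counts are tallied against the
    relaxed display cutoffs 0.85x / 1.15x.
    """
    rng = np.random.default_rng(spec.seed + 3)
    truth = universe.truth
    by_id = universe.records_by_id
    druggable = universe.druggable_ids
    family_ids = {
        gid: by_id[gid].symbol
        for gid in universe.class_members.get(truth.family_class, [])
    }
    gene_ids = sorted(by_id)

    lines = ["#patient_id\tgene\tcn_ratio"]
    pass_events = 0
    pass_genes: set[int] = set()
    drug_events = 0
    drug_genes: set[int] = set()
    gains = 0
    losses = 0
    family_loss: dict[str, int] = {s: 0 for s in family_ids.values()}
    family_gain: dict[str, int] = {s: 0 for s in family_ids.values()}
    total = 0
    for p in range(spec.n_cn_patients):
        patient = f"PT{p + 1:03d}"
        for gid in gene_ids:
            u = rng.random()
            if u < spec.cn_outlier_fraction / 2:
                ratio = float(rng.uniform(0.35, 0.695))
                outcome = "loss"
            elif u < spec.cn_outlier_fraction:
                ratio = float(rng.uniform(1.505, 3.0))
                outcome = "gain"
            else:
                while True:
                    ratio = float(np.exp(rng.normal(0.0, 0.08)))
                    if 0.71 <= ratio <= 1.49:
                        break
                outcome = "neutral"
            ratio = round(ratio, 4)
            total += 1
            if outcome != "neutral":
                pass_events += 1
                pass_genes.add(gid)
                if gid in druggable:
                    drug_events += 1
                    drug_genes.add(gid)
                    if outcome == "gain":
                        gains += 1
                    else:
                        losses += 1
            if gid in family_ids:
                sym = family_ids[gid]
                if ratio < 0.85:
                    family_loss[sym] += 1
                elif ratio > 1.15:
                    family_gain[sym] += 1
            # Rows alternate symbol / numeric id to exercise both joins.
            gene_field = str(gid) if (gid + p) % 2 == 0 else by_id[gid].symbol
            lines.append(f"{patient}\t{gene_field}\t{ratio}")
    truth.cn_total_events = total
    truth.cn_pass_events = pass_events
    truth.cn_pass_genes = len(pass_genes)
    truth.cn_druggable_events = drug_events
    truth.cn_druggable_genes = len(drug_genes)
    truth.cn_gains = gains
    truth.cn_losses = losses
    truth.family_loss_counts = family_loss
    truth.family_gain_counts = family_gain
    return "\n".join(lines) + "\n", truth


def make_fixture_bundle(spec: Optional[FixtureSpec] = None) -> dict:
    """Generate every fixture artifact in one call.

    Returns a dict with the universe, source lists, ledger, SNV and CN
    table texts, and the completed GroundTruth.
    """
    spec = spec or FixtureSpec()
    universe = make_gene_universe(spec)
    sources, ledger = make_catalog_sources(spec, universe)
    snv_text, truth = simulate_snv_table(spec, universe)
    cn_text, truth = simulate_cn_table(spec, universe)
    return {
        "spec": spec,
        "universe": universe,
        "sources": sources,
        "ledger": ledger,
        "snv_text": snv_text,
        "cn_text": cn_text,
        "truth": truth,
    }
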