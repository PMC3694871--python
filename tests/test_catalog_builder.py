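"""Source reconciliation, curation, catalog serialization and summaries."""

import io

import pytest

from dgene import (
    CatalogEntry,
    CurationDecision,
    IncompleteCurationError,
    SourceList,
    UnknownClassError,
    apply_curation,
    build_entries,
    build_symbol_index,
    catalog_summary,
    flag_single_source,
    merge_sources,
    read_catalog,
    summarize_counts,
    write_catalog,
)
from .test_ncbi_gene import make_record


def universe(n):
    return [make_record(i, f"GENE{i}", [f"ALT{i}"]) for i in range(1, n + 1)]


def source(code, name, entries):
    return SourceList(class_code=code, source_name=name, entries=tuple(entries))


class TestMergeSources:
    def test_overlapping_sources_union(self, ):
        recs = universe(12)
        index = build_symbol_index(recs)
        a = source("NHR", "A", [f"GENE{i}" for i in range(1, 11)])
        b = source("NHR", "B", [f"GENE{i}" for i in range(5, 13)])
        candidates, rejects = merge_sources([a, b], index)
        assert len(candidates) == 12
        assert sum(len(c.supporting_sources) == 2 for c in candidates) == 6
        assert rejects == []

    def test_single_source_candidates_all_singletons(self):
        recs = universe(5)
        index = build_symbol_index(recs)
        candidates, _ = merge_sources(
            [source("PTP", "only", [r.symbol for r in recs])], index
        )
        assert len(candidates) == 5
        assert all(c.supporting_sources == {"only"} for c in candidates)

    def test_unmappable_names_returned_not_dropped(self):
        recs = universe(3)
        index = build_symbol_index(recs)
        entries = [r.symbol for r in recs] + ["NOT_A_GENE"]
        candidates, rejects = merge_sources([source("NHR", "A", entries)], index)
        assert len(candidates) == 3
        assert [r.query for r in rejects] == ["NOT_A_GENE"]
        assert rejects[0].status == "unresolved"

    def test_synonym_spelling_merges_with_official(self):
        recs = universe(2)
        index = build_symbol_index(recs)
        a = source("NHR", "A", ["GENE1", "GENE2"])
        b = source("NHR", "B", ["ALT1", "ALT2"])  # same genes by synonym
        candidates, _ = merge_sources([a, b], index)
        assert len(candidates) == 2
        assert all(c.supporting_sources == {"A", "B"} for c in candidates)

    def test_empty_source_list_rejected(self):
        index = build_symbol_index(universe(1))
        with pytest.raises(ValueError):
            merge_sources([], index)

    def test_unknown_class_rejected(self):
        index = build_symbol_index(universe(1))
        with pytest.raises(UnknownClassError):
            merge_sources([source("NOT_A_CLASS", "A", ["GENE1"])], index)

    def test_conservation_of_inputs(self):
        """Candidates + rejects account for every distinct input identifier."""
        recs = universe(20)
        index = build_symbol_index(recs)
        entries = [f"GENE{i}" for i in range(1, 21)] + ["BAD1", "BAD2"]
        candidates, rejects = merge_sources([source("GPCR", "A", entries)], index)
        assert len(candidates) + len(rejects) == 22


class TestCuration:
    def _nhr_candidates(self, n_total=54, n_single=6):
        """Candidate set mirroring the nuclear-hormone-receptor workflow."""
        recs = universe(n_total)
        index = build_symbol_index(recs)
        multi = [f"GENE{i}" for i in range(1, n_total - n_single + 1)]
        single = [f"GENE{i}" for i in range(n_total - n_single + 1, n_total + 1)]
        a = source("NHR", "russ2005", multi + single)
        b = source("NHR", "nucleardb", multi)
        candidates, _ = merge_sources([a, b], index)
        return candidates, single

    def test_flag_single_source_finds_exactly_the_singletons(self):
        candidates, single = self._nhr_candidates()
        flagged = flag_single_source(candidates)
        assert len(flagged) == 6
        assert {c.resolution.query for c in flagged} == set(single)

    def test_flag_on_all_multi_source_is_empty(self):
        candidates, _ = self._nhr_candidates(n_total=10, n_single=0)
        assert flag_single_source(candidates) == []

    def test_excluding_all_flagged_leaves_48_members(self):
        candidates, single = self._nhr_candidates()
        ledger = [
            CurationDecision(query=q, class_code="NHR", verdict="exclude",
                             evidence_tag="uniprot_go_check")
            for q in single
        ]
        accepted = apply_curation(candidates, ledger)
        assert len(accepted) == 48

    def test_mixed_verdict_arithmetic(self):
        candidates, single = self._nhr_candidates(n_total=10, n_single=3)
        verdicts = ["include", "include", "exclude"]
        ledger = [
            CurationDecision(query=q, class_code="NHR", verdict=v)
            for q, v in zip(single, verdicts)
        ]
        assert len(apply_curation(candidates, ledger)) == 9

    def test_empty_ledger_identity_when_nothing_flagged(self):
        candidates, _ = self._nhr_candidates(n_total=10, n_single=0)
        accepted = apply_curation(candidates, [])
        assert len(accepted) == len(candidates)

    def test_strict_mode_requires_verdicts(self):
        candidates, _ = self._nhr_candidates()
        with pytest.raises(IncompleteCurationError):
            apply_curation(candidates, [])

    def test_non_strict_defaults_flagged_to_exclude(self):
        candidates, _ = self._nhr_candidates()
        assert len(apply_curation(candidates, [], strict=False)) == 48

    def test_exclusion_is_monotone(self):
        """Growing the exclude set never adds members."""
        candidates, single = self._nhr_candidates()
        ledger = [
            CurationDecision(query=q, class_code="NHR", verdict="exclude")
            for q in single
        ]
        sizes = [
            len(apply_curation(candidates, ledger[:k], strict=False))
            for k in range(len(ledger) + 1)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_ledger_can_exclude_multi_source_candidates(self):
        candidates, _ = self._nhr_candidates(n_total=10, n_single=0)
        gid = candidates[0].gene_id
        ledger = [CurationDecision(query=str(gid), class_code="NHR",
                                   verdict="exclude", evidence_tag="literature")]
        accepted = apply_curation(candidates, ledger)
        assert len(accepted) == 9
        assert (gid, "NHR") not in accepted


class TestSerialization:
    def _entries(self):
        recs = universe(3)
        return build_entries([(1, "GPCR"), (2, "GPCR"), (3, "PTEN")], recs)

    def test_rows_have_16_fields(self):
        buf = io.StringIO()
        write_catalog(self._entries(), buf)
        lines = buf.getvalue().strip().split("\n")
        assert len(lines) == 4  # header + 3
        assert all(len(line.split("\t")) == 16 for line in lines)

    def test_round_trip_identity(self):
        entries = self._entries()
        buf = io.StringIO()
        write_catalog(entries, buf)
        buf.seek(0)
        assert read_catalog(buf) == entries

    def test_round_trip_preserves_synonym_lists(self, catalog):
        buf = io.StringIO()
        write_catalog(catalog, buf)
        buf.seek(0)
        back = read_catalog(buf)
        assert [e.record.synonyms for e in back] == [
            e.record.synonyms for e in catalog
        ]

    def test_empty_catalog_round_trip(self):
        buf = io.StringIO()
        write_catalog([], buf)
        content = buf.getvalue()
        assert content.startswith("#") and content.count("\n") == 1
        assert read_catalog(io.StringIO(content)) == []

    def test_unknown_class_code_on_read(self):
        entries = self._entries()
        buf = io.StringIO()
        write_catalog(entries, buf)
        tampered = buf.getvalue().replace("\tPTEN", "\tMYSTERY")
        with pytest.raises(UnknownClassError):
            read_catalog(io.StringIO(tampered))


class TestSummary:
    def test_counts_and_total(self):
        recs = universe(8)
        entries = build_entries(
            [(i, "GPCR") for i in range(1, 4)] + [(i, "PTP") for i in range(4, 9)],
            recs,
        )
        s = catalog_summary(entries)
        assert s.per_class == {"GPCR": 3, "PTP": 5}
        assert s.total == 8

    def test_empty_catalog(self):
        s = catalog_summary([])
        assert s.per_class == {} and s.total == 0

    def test_total_equals_sum_of_classes(self, catalog):
        s = catalog_summary(catalog)
        assert s.total == sum(s.per_class.values())

    def test_summarize_pretabulated_counts(self):
        assert summarize_counts({"A": 2, "B": 3}).total == 5
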