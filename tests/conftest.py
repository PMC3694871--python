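import io

import pytest

from dgene import (
    FixtureSpec,
    apply_curation,
    build_entries,
    build_symbol_index,
    make_fixture_bundle,
    merge_sources,
    parse_gene_info,
)


@pytest.fixture(scope="session")
def bundle():
    """One seeded synthetic study shared across the suite."""
    return make_fixture_bundle(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def records(bundle):
    return parse_gene_info(io.StringIO(bundle["universe"].gene_info_text))


@pytest.fixture(scope="session")
def index(records):
    return build_symbol_index(records)


@pytest.fixture(scope="session")
def catalog(bundle, records, index):
    candidates, _ = merge_sources(bundle["sources"], index)
    accepted = apply_curation(candidates, bundle["ledger"])
    return build_entries(accepted, records)


@pytest.fixture()
def gene_info_lines():
    """Five human rows + two mouse rows, hand-written in gene_info dialect."""
    return [
        "#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms\tdbXrefs\tchromosome"
        "\tmap_location\tdescription\ttype_of_gene\tSymbol_from_nomenclature_authority"
        "\tFull_name_from_nomenclature_authority\tNomenclature_status"
        "\tOther_designations\tModification_date",
        "9606\t673\tBRAF\t-\tB-RAF1|BRAF1\t-\t7\t7q34\tB-Raf proto-oncogene"
        "\tprotein-coding\tBRAF\tB-Raf proto-oncogene\tO\t-\t20130101",
        "9606\t7157\tTP53\t-\tP53|LFS1\t-\t17\t17p13.1\ttumor protein p53"
        "\tprotein-coding\tTP53\ttumor protein p53\tO\t-\t20130101",
        "9606\t5728\tPTEN\t-\tBZS|MMAC1\t-\t10\t10q23.31\tphosphatase and tensin"
        "\tprotein-coding\tPTEN\tphosphatase and tensin homolog\tO\t-\t20130101",
        "9606\t207\tAKT1\t-\tAKT|PKB\t-\t14\t14q32.33\tAKT serine/threonine kinase"
        "\tprotein-coding\tAKT1\tAKT serine/threonine kinase 1\tO\t-\t20130101",
        "9606\t1111\tNOSYN\t-\t-\t-\t1\t-\tno synonyms here"
        "\tprotein-coding\tNOSYN\t-\tO\t-\t20130101",
        "10090\t109880\tBraf\t-\t-\t-\t6\t-\tmouse braf"
        "\tprotein-coding\tBraf\t-\tO\t-\t20130101",
        "10090\t22059\tTrp53\t-\t-\t-\t11\t-\tmouse p53"
        "\tprotein-coding\tTrp53\t-\tO\t-\t20130101",
    ]
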