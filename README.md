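# dgene

Druggable-gene catalog building and somatic variant prioritization for
cancer genome sequencing studies.

Cancer sequencing projects produce thousands of somatic single-nucleotide
variants (SNVs) and copy-number (CN) events per cohort — far more than can
be followed up experimentally. One rational first screen is *druggability*:
keep the alterations that fall in genes whose protein products belong to
classes historically tractable to small-molecule drugs. This package builds
and maintains such a catalog — ten classes (GPCRs, proteases, S/T kinases,
protease inhibitors, tyrosine kinases, phosphotyrosine phosphatases,
nuclear hormone receptors, myotubularin-related phosphatases, PI3-kinases,
and PTEN homologues) reconciled from specialized databases and reviews
through the NCBI gene authority — and applies it to mutation and
copy-number tables.

It is aimed at bioinformaticians triaging cohort-level somatic calls:
given a gene list, the catalog only *filters*; it makes no claim about a
mutation being gain- or loss-of-function, and large, frequently mutated
genes (titin, collagens) will pass the filter like any other.

## Method

1. **Symbol resolution.** The NCBI `gene_info` file (15 tab-delimited
   columns: GeneID, official symbol, a `|`-separated synonym list, ...)
   is the mapping authority. A query string resolves to an *official*
   symbol first; only non-official strings are searched against synonyms.
   A synonym claimed by ≥2 genes is reported as *ambiguous*, never
   assigned. Matching is exact, then case-folded.
2. **Catalog building.** Per-class source lists are resolved and merged;
   each candidate carries the set of sources supporting it. Candidates
   backed by a single source are flagged and must receive an
   include/exclude verdict from a curation ledger (a TSV of recorded
   manual judgments with evidence tags), making curation reproducible.
   Multi-source candidates are included unless explicitly excluded.
   The catalog is serialized as the 15 `gene_info` columns plus a 16th
   column, `class`.
3. **SNV annotation.** Mutation tables (minimal-MAF dialect: patient +
   gene symbol and/or Entrez GeneID) are joined to the catalog —
   numeric id first, symbol resolution as fallback — and the class term
   appended. Screens: druggable rows only; genes recurrent in ≥ *k*
   patients (a patient counts once per gene); patient × class and
   gene × patient matrices.
4. **CN screening.** One event is one patient × gene fold-change ratio
   (1.0 = neutral). Events strictly below a low cutoff or strictly above
   a high cutoff pass; cutoffs are absolute ratios (0.7× / 1.5×) or
   percentile ranks (20th / 80th) of the pooled ratio distribution
   (linear-interpolation quantiles). Passing events intersect the
   catalog and split into gains (> high) and losses (< low). A *family
   view* renders all catalog members of one class against relaxed
   display cutoffs (0.85× / 1.15×) so sub-threshold changes stay visible.

## Worked example

Everything below runs offline on a seeded synthetic study (400 genes, a
77-gene druggable core across the ten classes, 77 mutation patients, 46
copy-number patients) whose expected counts are recorded during
generation:

```
dgene make-fixtures --seed 11 --out fx
dgene build-catalog --gene-info fx/gene_info.tsv --sources fx/sources \
      --ledger fx/ledger.tsv --out cat
dgene summary --catalog cat/catalog.tsv
```

prints the per-class inventory and its total:

```
GPCR    22
NHR     3
PI3K    2
PROTEASES       15
PROT_INHIB      6
PTEN    7
PTP     4
PTP_MTMR        2
ST_KINASE       11
Y_KINASE        5
Total   77
```

Annotating the synthetic mutation and copy-number tables:

```
dgene annotate-snv --catalog cat/catalog.tsv --input fx/snv.tsv \
      --gene-info fx/gene_info.tsv --min-patients 2 --out snv_out
dgene annotate-cnv --catalog cat/catalog.tsv --input fx/cn.tsv \
      --gene-info fx/gene_info.tsv --low 0.7 --high 1.5 \
      --family PTEN --out cnv_out
```

logs (and records in each run's `manifest.json`):

```
INFO dgene: 361/2616 mutations druggable; 75 genes at >=2 patients
INFO dgene: 6605 events passed screen; 1263 druggable (617 gains / 646 losses)
```

i.e. 361 of 2616 mutation rows fell in druggable genes, 75 druggable genes
were hit in at least two patients, and of 18,400 copy-number measurements
6,605 passed the 0.7×/1.5× screen, 1,263 of those in druggable genes.
Every one of these counts equals the value in `fx/ground_truth.json`
planted by the generator. `cnv_out/family_PTEN_counts.tsv` holds per-gene
loss/gain patient counts for the PTEN-homologue family at the display
cutoffs.

Real analyses work identically: point `--gene-info` at the NCBI human
`Homo_sapiens.gene_info.gz`, `--sources` at your per-class lists, and the
annotators at your MAF-like and CN tables.

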