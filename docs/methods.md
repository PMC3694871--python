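# Methods

## The model

The package implements a druggability filter for cohort-level somatic
variation. Its core object is a curated catalog of human genes in ten
protein classes with a history of successful small-molecule targeting.
The catalog is not a prediction: class membership is the union of
specialized sources (class-specific databases and reviews), standardized
through the NCBI gene authority and corrected by recorded manual
curation. Applied to a cohort's mutation or copy-number table, the
catalog acts purely as a set-membership filter followed by simple
recurrence and magnitude screens. It deliberately says nothing about a
variant's functional direction; combining the filter with functional
impact scores is up to the user.

## Symbol resolution

All cross-source comparison happens in NCBI GeneID space. The resolver
indexes the official symbol and the synonym list of every `gene_info`
record and applies two fixed precedence rules:

* **Official beats synonym, always.** A string that is some gene's
  official symbol resolves there even if it is also another gene's
  synonym. Synonyms are only searched for strings that are not official
  symbols.
* **Exact beats case-folded.** Queries are first matched verbatim; only
  on a miss is an uppercase-folded match attempted, and the resolution
  records that folding was needed. Mutation tables vary in symbol
  casing, so pure exact matching loses real joins, while folding first
  would hide true spelling conflicts.

A synonym claimed by two or more genes yields an *ambiguous* resolution
carrying the candidate set. Downstream consumers decide; the annotators
exclude ambiguous rows from druggable output (with a logged warning)
rather than guessing, because a wrong class assignment is worse than a
missed one in a triage setting. Unresolvable and ambiguous source-list
entries are emitted to a rejects report and never enter the catalog.

The parser requires the first 15 tab-delimited columns, treats `-` as
the empty value, strips a record's own symbol from its synonym list, and
tolerates (with a warning) trailing columns appended in newer NCBI
releases. Duplicate GeneIDs and official-symbol collisions are hard
errors: the mapping authority must actually be one.

## Catalog construction and curation

Candidates are keyed by (GeneID, class); each carries the union of
sources naming it. The curation contract mirrors how the list was built:

* multi-source candidates are included unless a ledger entry excludes
  them — the construction bias is toward inclusion;
* single-source candidates are flagged and require an explicit verdict.
  In strict mode (the default) a missing verdict aborts the build; in
  non-strict mode unverdicted flagged candidates default to *exclude*,
  since the flag exists precisely because one source is insufficient
  evidence.

Verdicts are keyed by GeneID or by the raw query string, with an
evidence tag (`homology`, `experimental_function`, `uniprot_go_check`,
`literature`, `pseudogene_homolog` — pseudogenes showing homology may be
included). The ledger is an input file, not derived: the package records
judgments, it does not re-derive them (no homology computation, no
live database queries).

One catalog row is one (gene, class) pair; a gene may legitimately
appear under several classes, and such genes are surfaced in the build
report rather than forbidden, because the serialized format (one class
column) implies nothing about disjointness. The file format is the 15
`gene_info` columns plus `class`, UTF-8, tab-delimited, `#`-prefixed
header; write→read is the identity on valid catalogs.

## SNV annotation

Every input row is preserved through annotation. The join prefers a
positive numeric Entrez GeneID when the table carries one (cohort
pipelines typically emit current ids; id joins bypass symbol ambiguity
entirely) and falls back to symbol resolution. Recurrence counts
distinct patients per gene — a patient with several mutations in one
gene counts once — while the filtered table keeps every event, so
event-level and gene-level figures stay mutually consistent. The
patient × class matrix sums to the druggable event count; the
gene × patient presence matrix has row sums equal to per-gene patient
counts. Patients are exact `patient_id` strings; no sample collapsing.

## Copy-number screening

An event is one patient × gene ratio row; segment data must be projected
to genes upstream. Cutoffs are strict inequalities on both sides (an
event exactly at a cutoff fails), in absolute mode (defaults 0.7× and
1.5×) or percentile mode, where the stated ranks (e.g. 20/80) are taken
over the pooled ratio distribution across all patients and genes —
single global cutoffs, not per-patient ones. The quantile estimator is
linear interpolation between order statistics, declared in the run
manifest because different estimators give different cutoffs on small
inputs; reproductions of published absolute cutoffs should use absolute
mode and sidestep the estimator question. Gains (> high) and losses
(< low) partition the screened set exactly.

The family view intentionally takes *unscreened* events: its purpose is
to show every member of one gene family against relaxed display cutoffs
(defaults 0.85× / 1.15×) so biologically suggestive sub-threshold
changes — the kind the analysis screen would drop — remain visible.

## Synthetic studies and what they show

The fixtures module generates a complete, parseable input bundle:
a gene universe in valid `gene_info` syntax (reserved `GSYN`/`SYN`
symbol namespace, so no accidental collision with real gene names),
per-class source lists with single-source decoys and a matching exclude
ledger, a Poisson mutation table, and a full patient × gene ratio grid.
Defaults emulate the shape of a 77-tumour breast-cancer cohort at
reduced gene count: 400 genes with a 77-gene druggable core distributed
over the ten classes in roughly the published proportions (the PTEN
family keeps its real size, 7, because the family view is exercised on
it); 34 expected mutations per patient with a 14% druggable fraction;
a 46-patient copy-number grid with 36% of ratios outside 0.7×/1.5×
(losses uniform on [0.35, 0.695], gains on [1.505, 3.0], neutral ratios
rejection-sampled from a lognormal, σ = 0.08, strictly inside the
cutoffs).

Every expected count is tallied *while sampling* — which component a
draw came from, which genes were hit in which patients — never
recomputed from the emitted files, so a generator bug cannot cancel a
pipeline bug. Ratios are rounded to four decimals before writing and
compared after a full text round-trip.

Limits of the emulation: because the druggable core is small relative to
the mutation count, recurrence saturates (most druggable genes recur),
unlike the sparse published 37-of-255; mutation spectra, signatures, CN
segment structure and gene-length bias are not modeled. Passing fixture
tests therefore demonstrates exact bookkeeping of the filters and joins
on realistic file dialects, not statistical realism of cancer genomes.
Generation is deterministic under the seed (single `numpy` generator per
artifact, derived seed offsets per table).

## Numerical and degenerate-input choices

* Percentile ranks outside (0, 100), low ≥ high, or a resolved
  low ≥ high cutoff (e.g. an all-neutral ratio distribution) raise an
  invalid-threshold error rather than silently screening nothing.
* `min_patients < 1`, empty resolver queries, empty record sets, and
  empty source-list inputs are errors; empty mutation/CN *tables* are
  valid and produce empty outputs.
* Recurrence ties are broken by symbol after the patient-count sort, so
  output order is deterministic.
* `cn_ratio` must be strictly positive; 0 is treated as a data error,
  not a homozygous deletion code.

## Command-line layer

Subcommands (`build-catalog`, `annotate-snv`, `annotate-cnv`,
`make-fixtures`, `summary`) are a thin shell over the library. Every run
writes a `manifest.json` with inputs, parameters, a SHA-256 of the
catalog and the output counts, so any quoted number traces to files on
disk. Flags beat config-file values; data goes to files, logs to stderr.
The annotators can operate from the catalog alone (its rows are full
`gene_info` records, enough to build a resolver index), but then
official-symbol precedence is only guaranteed within the catalog;
supplying the full `gene_info` file via `--gene-info` restores the
genome-wide authority and is recommended for symbol-only tables.

## Known limitations

* Protein *names* (as opposed to symbol-like strings) are resolved only
  insofar as they appear in the synonym list; no free-text matching
  against descriptions is attempted.
* The catalog's quality is bounded by its sources; the package ships no
  source lists of its own.
* No network access anywhere in the library: `gene_info`, source lists
  and cohort tables are local files.
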