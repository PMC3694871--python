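"""Exception hierarchy shared across the package."""


class DgeneError(Exception):
    """Base class for all package-specific errors."""


class MalformedRecordError(DgeneError):
    """A gene_info data line does not carry the required 15 columns."""

    def __init__(self, line_number: int, n_fields: int):
        self.line_number = line_number
        self.n_fields = n_fields
        super().__init__(
            f"line {line_number}: expected 15 tab-separated fields, got {n_fields}"
        )


class DuplicateGeneIdError(DgeneError):
    """Two records in one file claim the same GeneID."""

    def __init__(self, gene_id: int, line_number: int):
        self.gene_id = gene_id
        super().__init__(f"line {line_number}: duplicate GeneID {gene_id}")


class SymbolCollisionError(DgeneError):
    """Two records share an official symbol after normalization."""

    def __init__(self, symbol: str, gene_ids):
        self.symbol = symbol
        self.gene_ids = sorted(gene_ids)
        super().__init__(
            f"official symbol {symbol!r} claimed by GeneIDs {self.gene_ids}"
        )


class InvalidQueryError(DgeneError):
    """Empty or whitespace-only symbol query."""


class UnknownClassError(DgeneError):
    """A class code not present in the class registry."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(f"unknown druggable class code: {code!r}")


class IncompleteCurationError(DgeneError):
    """Single-source candidates lack a curation verdict in strict mode."""

    def __init__(self, missing):
        self.missing = list(missing)
        genes = ", ".join(f"{g}/{c}" for g, c in self.missing)
        super().__init__(f"no curation verdict for flagged candidates: {genes}")


class InvalidThresholdError(DgeneError):
    """Copy-number threshold specification is out of range or degenerate."""


class FixtureSpecError(DgeneError):
    """Inconsistent synthetic-data specification."""
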