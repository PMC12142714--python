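"""Exception hierarchy for ingest and pipeline contract failures."""


class InvauditError(Exception):
    """Base class for all package errors."""


class SchemaError(InvauditError):
    """A required column/field is missing or structurally malformed."""


class IntegrityError(InvauditError):
    """Cross-row consistency violated (duplicate accessions, gazetteer clashes)."""


class ValidationError(InvauditError):
    """A single entry fails its value-level invariants."""


class ContractError(InvauditError):
    """An operation was called outside its stated precondition."""


class ConfigError(InvauditError):
    """A synthetic-cohort configuration is infeasible or inconsistent."""


class UndefinedPercentageError(InvauditError):
    """Percentage requested with a zero denominator."""
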