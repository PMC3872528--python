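"""Exception hierarchy for table parsing and validation."""


class NdbAuditError(Exception):
    """Base class for all package errors."""


class TableSchemaError(NdbAuditError):
    """Structural problem with a table: wrong header, missing or duplicate stratum."""


class TableValidationError(NdbAuditError):
    """A parsed row violates a domain invariant."""
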