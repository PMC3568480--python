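"""Exception hierarchy for adrmine.

All package errors derive from :class:`AdrMineError` so callers can catch a
single base class at the CLI boundary.
"""


class AdrMineError(Exception):
    """Base class for all adrmine errors."""


class SchemaError(AdrMineError):
    """Input data does not expose the columns the reader requires."""


class IntegrityError(AdrMineError):
    """Input data is internally inconsistent (e.g. one report id carries two
    different values for the same demographic attribute)."""


class QueryError(AdrMineError):
    """A query references unknown attributes, measures or malformed coordinates."""


class ParseError(AdrMineError):
    """A value could not be interpreted (e.g. non-numeric age during binning)."""


class ConfigError(AdrMineError):
    """A simulation or run configuration is infeasible or malformed."""
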