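"""Exception hierarchy.

All package-specific failures derive from :class:`HdxError` so callers can
catch one base class; subclasses distinguish file-format problems from
scientific/statistical ones (the CLI maps them to distinct exit codes).
"""


class HdxError(Exception):
    """Base class for all hdxdiff errors."""


class FormatError(HdxError):
    """A file does not conform to the declared dialect (missing column,
    wrong delimiter, empty data section)."""


class ParseError(HdxError):
    """A value inside an otherwise well-formed file could not be parsed;
    carries the offending row number in its message."""


class IntegrityError(HdxError):
    """Duplicate or internally inconsistent measurements."""


class ValidationError(HdxError):
    """A domain object violates one of its invariants."""


class ParameterError(HdxError):
    """An operation was called with scientifically invalid parameters."""


class CoverageError(HdxError):
    """A peptide is missing from one of the two compared states."""


class InsufficientDataError(HdxError):
    """Not enough replicate groups to estimate a significance threshold."""


class SelectionError(HdxError):
    """An atom/residue selection matched nothing or is missing members."""


class MappingError(HdxError):
    """Residue numbering of a structure cannot be reconciled with the
    classification map."""
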