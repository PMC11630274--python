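"""Exception hierarchy for tgkit.

All errors raised by the library derive from :class:`TgkitError` so callers
(and the CLI) can catch one base class.
"""

from __future__ import annotations


class TgkitError(Exception):
    """Base class for all tgkit errors."""


class TrjsonParseError(TgkitError):
    """The document is not parseable JSON (distinct from schema violations)."""


class TrjsonValidationError(TgkitError):
    """A trjson document or graph violates the schema.

    Carries the full :class:`~tgkit.model.ValidationReport` in ``report``.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class AttributeKindError(TgkitError):
    """An attribute holds values of irreconcilable kinds."""


class TableFormatError(TgkitError):
    """A delimited input table is malformed (shape, labels, cell contents)."""


class ConversionError(TgkitError):
    """A matrix/table cannot be converted under the requested settings."""


class DuplicateEdgeError(TgkitError):
    """Two rows address the same node pair under the graph's directedness."""


class SelfLoopError(TgkitError):
    """A row or edge links a sample to itself."""


class MergeError(TgkitError):
    """A metadata merge cannot proceed (missing column, duplicate id, collision)."""


class FilterSyntaxError(TgkitError):
    """A filter expression failed to parse.

    ``position`` is the 0-based character offset of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class FilterTypeError(TgkitError):
    """An ordering comparison was applied to a string literal."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MissingAttributeError(TgkitError):
    """Strict evaluation hit an attribute absent from the map."""


class UnknownNodeError(TgkitError):
    """An operation referenced node ids not present in the graph."""


class StyleError(TgkitError):
    """A style request referenced an unknown attribute or exceeded a limit."""


class SimulationParameterError(TgkitError):
    """Fixture generator parameters are infeasible."""
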