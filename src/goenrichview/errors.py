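"""Exception hierarchy shared across the package."""


class GoEnrichViewError(Exception):
    """Base class for all package errors."""


class OboParseError(GoEnrichViewError):
    """Malformed OBO input; carries the 1-based line number where parsing failed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StructuralError(GoEnrichViewError):
    """The parsed graph violates a structural invariant (e.g. a parent cycle)."""


class UnknownTermError(GoEnrichViewError, KeyError):
    """A GO id resolved neither as a primary id nor as an alt_id."""

    def __init__(self, go_id: str):
        self.go_id = go_id
        super().__init__(f"unknown GO id: {go_id}")

    def __str__(self) -> str:  # KeyError would repr() the message
        return self.args[0]


class DomainMixingError(GoEnrichViewError):
    """A query mixed terms from different GO namespaces."""


class PathExplosionError(GoEnrichViewError):
    """Path enumeration exceeded the configured hard cap."""


class TableFormatError(GoEnrichViewError):
    """An enrichment result table is missing columns or has unparseable rows."""


class UndefinedFoldError(GoEnrichViewError):
    """Fold change requested for a record with expected_count == 0."""


class StaleSelectionError(GoEnrichViewError):
    """A saved selection references edges absent from the loaded ontology.

    Attributes
    ----------
    failures : list of str
        Offending edges in ``"PARENT>CHILD"`` notation, one per broken step.
    selection :
        The still-valid subset of the selection (set by load_selection so
        callers can proceed partially).
    """

    def __init__(self, failures: list[str], selection=None):
        self.failures = list(failures)
        self.selection = selection
        super().__init__(
            "selection references edges absent from the ontology: "
            + ", ".join(self.failures)
        )


class SelectionVersionError(GoEnrichViewError):
    """A selection file declares an unsupported format version."""


class EmptyFigureError(GoEnrichViewError):
    """render_figure called with zero rows or zero analyses."""


class RasterizerUnavailableError(GoEnrichViewError):
    """No SVG rasterizer is importable; advise using the SVG output directly."""
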