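"""Exception hierarchy shared across the package."""


class HrssError(Exception):
    """Base class for all package errors."""


class OboParseError(HrssError):
    """The OBO flat file could not be parsed."""


class CycleError(HrssError):
    """The term graph contains a directed cycle."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"ontology graph is cyclic; cycle passes through {member!r}")


class UnknownTermError(HrssError, KeyError):
    """A term id is absent from the graph (after alt_id resolution)."""


class NamespaceMismatchError(HrssError):
    """The two terms belong to different ontology namespaces."""


class UnreachableError(HrssError):
    """No path exists between the two terms under the chosen convention."""


class GafParseError(HrssError):
    """A GAF row is structurally malformed."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class MissingICError(HrssError):
    """Information content is undefined (zero annotation count) for a term."""

    def __init__(self, term: str):
        self.term = term
        super().__init__(f"IC undefined for term {term!r} (no annotations)")


class UnannotatedGeneError(HrssError):
    """A gene has no usable annotations in the requested namespace."""


class DegenerateInputError(HrssError):
    """Labeled scores contain a single class, or a null distribution has zero spread."""


class GenerationError(HrssError):
    """A fixture specification cannot be satisfied."""
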