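"""Exception hierarchy shared across the package.

Everything raised by the library derives from :class:`FdgError`, so callers
(and the command-line wrapper) can distinguish domain failures from bugs.
"""


class FdgError(Exception):
    """Base class for all library errors."""


class MalformedIdError(FdgError):
    """A candidate SNOMED-style identifier fails the length / leading-zero /
    Verhoeff check-digit invariants."""


class UnknownConceptError(FdgError):
    """A concept reference does not resolve in the concept graph."""


class UnknownVocabularyError(FdgError):
    """An external reference names a vocabulary that is not attached."""


class DuplicateVocabularyError(FdgError):
    """A vocabulary key is attached twice to the same graph."""


class CycleError(FdgError):
    """The is-a relation of a concept graph contains a cycle."""


class GraphFormatError(FdgError):
    """A concept-graph file is malformed (dangling parent, bad row, ...)."""


class ExpressionSyntaxError(FdgError):
    """A compositional-grammar expression fails to parse.

    Carries the character position of the failure and the set of token
    descriptions that would have been acceptable there.
    """

    def __init__(self, message: str, position: int, expected: tuple = ()):
        self.position = position
        self.expected = tuple(expected)
        detail = f" at position {position}"
        if expected:
            detail += f" (expected {', '.join(expected)})"
        super().__init__(message + detail)


class ExternalRefError(ExpressionSyntaxError):
    """A tilde-delimited external reference is malformed (wrong segment
    count, empty segment, forbidden character)."""


class ConstraintSyntaxError(FdgError):
    """A textual MRCM constraint cannot be parsed."""


class RuleError(FdgError):
    """A rule-set operation is invalid (e.g. widening a nonexistent rule)."""


class CorpusFormatError(FdgError):
    """A corpus file row is malformed; carries the line number in the
    message."""
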