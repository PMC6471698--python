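"""Exception hierarchy.

Two failure modes are kept deliberately distinct: a :class:`StructureError`
signals a malformed input or a violated operator precondition (bad indices,
mismatched shared nucleotides, infeasible parameters), while a
:class:`NotWellDefinedError` signals the single semantic failure of the
algebra -- a nucleotide that would end up in two base pairs at once.
"""


class AspraError(ValueError):
    """Base class for all errors raised by this package."""


class StructureError(AspraError):
    """A secondary structure, input text or operator precondition is invalid."""


class ParseError(StructureError):
    """Input text could not be parsed in the requested format."""


class NotWellDefinedError(AspraError):
    """An overlay placed two base pairs on the same nucleotide."""
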