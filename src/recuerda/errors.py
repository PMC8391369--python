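"""Exception hierarchy for the recuerda package.

All package errors derive from :class:`RecuerdaError` so callers can catch
one base class at the CLI boundary.
"""


class RecuerdaError(Exception):
    """Base class for all recuerda errors."""


# -- profiles ---------------------------------------------------------------

class SchemaError(RecuerdaError):
    """The questionnaire schema violates its structural invariants."""


class UnknownSlotError(RecuerdaError):
    """An answer key does not name a slot of the questionnaire schema."""


class NotFoundError(RecuerdaError):
    """A requested profile (or other stored record) does not exist."""


# -- knowledge base ---------------------------------------------------------

class KBSyntaxError(RecuerdaError):
    """A knowledge-base file is malformed or uses a tag outside the dialect."""


class KBSlotError(RecuerdaError):
    """A template references a slot that the profile schema does not define."""


# -- dialogue ---------------------------------------------------------------

class SessionClosedError(RecuerdaError):
    """An operation was attempted on a session that has already ended."""


# -- evaluation -------------------------------------------------------------

class EmptyReferenceError(RecuerdaError):
    """The reference transcript normalizes to zero tokens."""


class EmptyInputError(RecuerdaError):
    """An aggregate was requested over an empty collection."""


class InvalidVoteError(RecuerdaError):
    """A vote names an out-of-range candidate or duplicates an evaluator."""


class LengthMismatchError(RecuerdaError):
    """Two paired sequences do not have the same length."""


class ConstantInputError(RecuerdaError):
    """A correlation was requested for a constant vector."""


class RangeError(RecuerdaError):
    """A numeric argument lies outside its documented range."""


# -- fixtures ---------------------------------------------------------------

class InsufficientKBError(RecuerdaError):
    """A dialogue context cannot sustain the requested number of turns."""
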