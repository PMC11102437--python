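"""Exception hierarchy."""


class SDMDError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SDMDError, ValueError):
    """An argument violates a documented precondition."""


class NumericalRankError(SDMDError, ValueError):
    """The data matrix has no usable singular values above the floor."""


class ConjugateClosureError(SDMDError, ValueError):
    """A mode set is not closed under complex conjugation (sDM would be complex)."""


class FormatError(SDMDError, ValueError):
    """A persisted container violates the on-disk schema."""
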