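"""Exception hierarchy for the ldg package."""


class LDGError(Exception):
    """Base class for all ldg-specific errors."""


class InvalidParameterError(LDGError, ValueError):
    """A hyperparameter or structural parameter is out of its valid range."""


class InvalidExemplarError(LDGError, ValueError):
    """The requested exemplar is not a positive sample."""


class DegenerateLabelsError(LDGError, ValueError):
    """The label vector lacks positives and/or negatives."""


class InvalidGraphError(LDGError, ValueError):
    """A graph weight matrix violates symmetry or nonnegativity."""


class DegenerateSignalError(LDGError, ValueError):
    """A signal window carries no variance in the requested band."""


class FormatError(LDGError, ValueError):
    """A feature table or model file does not match the expected format."""


class ProtocolError(LDGError, ValueError):
    """An evaluation protocol cannot be applied to the given data."""
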