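"""Exception hierarchy.

``ContractError`` signals caller mistakes (bad arguments, violated
preconditions); the remaining classes signal problems with the data
itself. The CLI maps the two groups onto distinct exit codes.
"""


class LucFlowError(Exception):
    """Base class for all package errors."""


class ContractError(LucFlowError, ValueError):
    """A precondition on an operation's inputs was violated."""


class FormatError(LucFlowError):
    """File is not in a supported format (e.g. unsupported FCS version)."""


class IntegrityError(LucFlowError):
    """File structure is internally inconsistent (e.g. truncated DATA)."""


class AmbiguityError(LucFlowError):
    """A channel-role pattern matched zero or more than one channel."""


class SchemaError(LucFlowError):
    """A CSV is missing a mandatory column for its dialect."""


class ParseError(LucFlowError):
    """A CSV field could not be parsed as the expected type."""


class NoValleyError(LucFlowError):
    """Automatic thresholding found no valley between two modes."""


class InsufficientDataError(LucFlowError):
    """Too few (or degenerate) values for automatic thresholding."""


class DegenerateSplitError(LucFlowError):
    """CFSE split produced an empty control or sample subpopulation."""


class DegenerateSpreadError(LucFlowError):
    """Negative-population spread is zero or negative (p84 <= median)."""


class ReferenceBackgroundError(LucFlowError):
    """Reference tube has no signal above its spiked background."""


class DegenerateSpikeError(LucFlowError):
    """Spike fluorescence does not exceed the estimated background."""


class UndefinedCorrelationError(LucFlowError):
    """Correlation undefined because one vector has zero variance."""
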