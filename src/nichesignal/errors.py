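"""Exception hierarchy for nichesignal."""


class NicheSignalError(Exception):
    """Base class for all package errors."""


class ValidationError(NicheSignalError, ValueError):
    """Input data failed validation."""


class NewickParseError(NicheSignalError, ValueError):
    """Malformed Newick input."""


class DegenerateInputError(NicheSignalError, ValueError):
    """Statistic undefined for this input (constant trait, empty group, ...)."""


class PipelineError(NicheSignalError, RuntimeError):
    """A pipeline stage failed; message names the stage and offending item."""
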