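"""Exception hierarchy shared by all pipeline stages."""


class MethgradError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MethgradError, ValueError):
    """A function argument violates its documented precondition."""


class InvalidScenarioError(MethgradError, ValueError):
    """A simulation scenario is internally inconsistent (e.g. density outside [0,1])."""


class InvalidDesignError(MethgradError, ValueError):
    """A statistical design is degenerate (empty cell, too few replicates, ...)."""


class InvalidInputError(MethgradError, ValueError):
    """An input table is structurally valid but semantically incomplete."""


class ParseError(MethgradError, ValueError):
    """A text input file could not be parsed; the message names the offending row."""


class EmptyRegionError(MethgradError, ValueError):
    """A genomic region query matched no sites."""
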