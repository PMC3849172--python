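"""Exception hierarchy shared by all prognosig stages."""


class PrognosigError(Exception):
    """Base class for all errors raised by prognosig."""


class ConfigurationError(PrognosigError):
    """A configuration value violates a documented invariant."""


class ParseError(PrognosigError):
    """An input file could not be parsed; the message names the offending line."""


class DataError(PrognosigError):
    """Input data are inconsistent or degenerate for the requested operation."""


class PipelineStageError(PrognosigError):
    """A pipeline stage failed; carries the stage name and a partial-results note."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
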