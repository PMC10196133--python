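"""Exception hierarchy shared across the package."""


class RetinergError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RetinergError, ValueError):
    """A model or configuration parameter is non-finite or out of range."""


class ConfigurationError(RetinergError, ValueError):
    """A processing configuration is inconsistent (e.g. filter corner >= Nyquist)."""


class ProtocolError(RetinergError, ValueError):
    """A stimulus protocol is malformed or a required flash energy is missing."""


class DegenerateFitError(RetinergError, RuntimeError):
    """The data contain no feature the model could describe (e.g. no a-wave)."""


class FitError(RetinergError, RuntimeError):
    """An optimizer failed to converge; carries diagnostics in ``args``."""


class SegmentationIntegrityError(RetinergError, ValueError):
    """Layer boundary surfaces cross; carries the offending pixel count."""


class UndefinedReferenceError(RetinergError, ValueError):
    """No usable reference group for percent-of-reference scaling."""


class StageError(RetinergError, RuntimeError):
    """Wraps a failure inside a pipeline stage, labelled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
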