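"""Exception hierarchy shared across the package."""


class EEGMarkersError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EEGMarkersError, ValueError):
    """A parameter violates an operation's precondition."""


class FormatError(EEGMarkersError, ValueError):
    """A file does not parse under the expected on-disk format."""


class MissingChannelError(EEGMarkersError, KeyError):
    """A required channel label is absent from a recording."""

    def __init__(self, label: str):
        super().__init__(label)
        self.label = label

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"required channel {self.label!r} not found"


class InsufficientDataError(EEGMarkersError, ValueError):
    """A recording or sample is too short/small for the requested operation."""


class DegenerateSignalError(EEGMarkersError, ValueError):
    """A signal has zero variance (or is otherwise statistically degenerate)."""


class UnrecoverableRecordingError(EEGMarkersError, ValueError):
    """No good channels remain to repair a recording from."""


class CollinearityError(EEGMarkersError, ValueError):
    """Predictor and mediator are (numerically) collinear."""
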