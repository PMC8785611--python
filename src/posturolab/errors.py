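"""Exception and warning types shared across the package."""


class PosturolabError(Exception):
    """Base class for all posturolab errors."""


class TrialParseError(PosturolabError):
    """A trial or event file violates the expected CSV dialect.

    ``row`` is the 1-based data-row number of the first offending sample,
    when one can be identified.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (data row {row})"
        super().__init__(message)
        self.row = row


class SignalGapError(PosturolabError):
    """Both force plates read (near-)zero load at the same sample.

    A standing protocol has no flight phase, so simultaneous unloading of
    both plates indicates a recording fault rather than a behaviour.
    """


class InsufficientDataError(PosturolabError):
    """A series or trial is too short for the requested computation."""


class UndefinedCostError(PosturolabError):
    """Dual-task cost requested with a zero single-task (or reference) score."""


class ConfigError(PosturolabError):
    """Invalid generator or analysis configuration."""


class DegenerateInputWarning(UserWarning):
    """Emitted when a computation degenerates (e.g. all CoP samples identical)."""
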