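"""Exception hierarchy shared across the pipeline stages."""


class TrialscapeError(Exception):
    """Base class for every error raised by this package."""


class ContractError(TrialscapeError, ValueError):
    """A value violates an input contract (empty query, bad enum, ...)."""


class ShapeError(TrialscapeError, ValueError):
    """A registry field does not have the expected list shape."""


class FieldParseError(TrialscapeError, ValueError):
    """A raw field value could not be parsed (age, date, ...)."""

    def __init__(self, message: str, raw: str | None = None):
        super().__init__(message)
        self.raw = raw


class FormatError(TrialscapeError, ValueError):
    """A snapshot / backup / CSV file is structurally malformed."""


class RetrievalError(TrialscapeError, RuntimeError):
    """A page request against the registry API failed."""


class NotFoundError(TrialscapeError, KeyError):
    """Lookup of an unknown trial or annotation."""


class BackupError(TrialscapeError, RuntimeError):
    """Backup dump could not be restored."""
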