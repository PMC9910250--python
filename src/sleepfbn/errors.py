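"""Exception hierarchy for the sleepfbn pipeline.

Every stage raises a subclass of :class:`SleepFBNError` so callers (and the
CLI) can catch pipeline failures without masking programming errors.
"""


class SleepFBNError(Exception):
    """Base class for all pipeline errors."""


class InvalidModelError(SleepFBNError):
    """A generative model violates its own invariants (e.g. asymmetric coupling)."""


class InvalidArgumentError(SleepFBNError):
    """An argument is outside its documented domain."""


class InvalidDesignError(SleepFBNError):
    """A trial design is inconsistent (unknown timepoint, bad sample size...)."""


class InvalidRegionError(SleepFBNError):
    """A regional-volume request names an unknown atlas region."""


class FormatError(SleepFBNError):
    """A file could not be parsed in its declared format."""


class ChannelMissingError(SleepFBNError):
    """A required EEG channel is absent from a recording."""

    def __init__(self, missing, available=None):
        self.missing = list(missing)
        self.available = list(available) if available is not None else None
        msg = f"required channel(s) missing: {', '.join(self.missing)}"
        if self.available is not None:
            msg += f" (available: {', '.join(self.available)})"
        super().__init__(msg)


class InvalidBandError(SleepFBNError):
    """Filter corner frequencies are outside the valid range."""


class InsufficientDataError(SleepFBNError):
    """Not enough data to perform the requested operation."""


class DegenerateChannelError(SleepFBNError):
    """A channel is constant (zero variance) so correlation is undefined."""


class InsufficientSamplesError(SleepFBNError):
    """Too few samples for a correlation estimate."""


class IncompatibleNetworkError(SleepFBNError):
    """Networks with different node labels cannot be aggregated."""


class InvariantViolationError(SleepFBNError):
    """A network object violates a structural invariant (symmetry, range...)."""


class UndefinedPathLengthError(SleepFBNError):
    """Characteristic path length is undefined (no finite node pair)."""


class DegenerateDataError(SleepFBNError):
    """Statistical contrast on degenerate data (zero variance everywhere)."""


class InvalidInputError(SleepFBNError):
    """Statistical input outside its domain (e.g. non-positive baseline)."""


class PairingError(SleepFBNError):
    """A paired table has an unpaired subject."""


class PipelineStageError(SleepFBNError):
    """Wraps an error with the pipeline stage and subject where it occurred."""

    def __init__(self, stage, subject_id, original):
        self.stage = stage
        self.subject_id = subject_id
        self.original = original
        super().__init__(f"stage '{stage}' failed for subject '{subject_id}': {original}")
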