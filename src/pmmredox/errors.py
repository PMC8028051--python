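"""Exception hierarchy shared across the pipeline."""


class PmmRedoxError(Exception):
    """Base class for all package errors."""


class StateSetParseError(PmmRedoxError):
    """A state-set file is malformed; the message names the offending field."""


class ValidationError(PmmRedoxError):
    """One or more invariants failed; the message lists each failure."""

    def __init__(self, failures):
        if isinstance(failures, str):
            failures = [failures]
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class NearSingularityError(PmmRedoxError):
    """An environment charge sits closer than d_min to an evaluation point."""

    def __init__(self, message, frame_index=None, charge_index=None):
        super().__init__(message)
        self.frame_index = frame_index
        self.charge_index = charge_index


class EmptySeriesError(PmmRedoxError):
    """Every frame of an ensemble was skipped; no series can be produced."""
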