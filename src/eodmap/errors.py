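"""Package-wide exception types."""


class EodmapError(Exception):
    """Base class for all eodmap errors."""


class ValidationError(EodmapError):
    """Input data violated a schema or invariant (non-monotone times, bad column...)."""


class InsufficientSpikesError(EodmapError):
    """A unit fired fewer spikes than the analysis minimum (default 10)."""


class UndefinedResultError(EodmapError):
    """The requested quantity is undefined for this input (e.g. zero mean rate,
    zero time in a swim state, an all-masked egocentric region)."""
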