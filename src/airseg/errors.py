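"""Package-specific exception types."""


class AirsegError(Exception):
    """Base class for all airseg errors."""


class DegenerateSegmentError(AirsegError):
    """Raised when a model is requested for data whose target has zero variance.

    A sub-range whose target values are all identical cannot support a
    regression model; callers that partition data should convert this into a
    degenerate marker rather than failing outright.
    """


class UnroutableModelError(AirsegError):
    """Raised when case routing is requested from a model that cannot route.

    Real-value-sorted ensembles cannot assign unseen cases to a sub-range
    because the sorting key (the true target) is unknown at prediction time.
    """


class SchemaError(AirsegError):
    """Raised for invalid input schemas or malformed monitoring files."""
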