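"""Exception types shared across the toolkit."""


class HaltError(Exception):
    """Base class for all toolkit errors."""


class UnmeasurableError(HaltError):
    """A level/loudness measure is undefined for this signal (e.g. silence,
    too short for the gating block, or fully gated out)."""


class ClippingError(HaltError):
    """A requested gain would push the signal past the digital ceiling."""


class LayoutError(HaltError):
    """Events cannot be scheduled under the gap/duration constraints."""


class InsufficientDataError(HaltError):
    """Too few data points for the requested fit or statistic."""
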