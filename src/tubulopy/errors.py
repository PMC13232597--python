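"""Exception types shared across the pipeline."""


class TubulopyError(Exception):
    """Base class for all pipeline errors."""


class CalibrationError(TubulopyError):
    """Missing or invalid pixel-size calibration."""


class ChannelMismatchError(TubulopyError):
    """Image channel set does not match what a model or rule expects."""


class CapabilityError(TubulopyError):
    """An optional backend (e.g. a star-convex detector plugin) is unavailable."""


class EmptySubsetError(TubulopyError):
    """A requested class/region subset contains no cells."""


class PackingError(TubulopyError):
    """Synthetic scene geometry could not be placed within the retry budget."""
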