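"""Package-specific exception types."""


class ConfigurationError(ValueError):
    """Invalid configuration value (band edges, montage size, grid geometry...)."""


class ChannelError(KeyError):
    """A required channel (e.g. a mastoid) is missing from the data."""


class EdgeContaminationError(ValueError):
    """A wavelet's temporal support does not fit inside the epoch."""


class DegenerateDataError(ValueError):
    """Data degenerate for the requested statistic (all-zero differences,
    constant input, class with too few samples)."""
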