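"""Exception types shared across the pipeline."""


class RankscreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RankscreenError):
    """A simulation or screen configuration is internally inconsistent."""


class DataError(RankscreenError):
    """Input data violate a precondition of an operation."""
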