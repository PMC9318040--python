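"""Exception hierarchy used across the pipeline."""


class MelifError(Exception):
    """Base class for all package errors."""


class ValidationError(MelifError):
    """Invalid input values (empty masks, nonpositive labs, bad config)."""


class GeometryError(MelifError):
    """Incompatible or degenerate image geometries."""


class ConfigurationError(MelifError):
    """Invalid acquisition or run configuration."""


class SegmentationError(MelifError):
    """Segmentation produced no usable foreground."""


class RegistrationError(MelifError):
    """Registration failed to improve the similarity metric."""
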