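"""Exception hierarchy shared across the toolkit."""


class GlottikitError(Exception):
    """Base class for all toolkit errors."""


class DimensionError(GlottikitError, ValueError):
    """Array shapes or channel counts incompatible with the operation."""


class GeometryError(GlottikitError, ValueError):
    """ROI / frame geometry violates a constraint (e.g. 32-divisibility)."""


class FormatError(GlottikitError, ValueError):
    """File is not a readable recording container."""


class ParseError(GlottikitError, ValueError):
    """Sidecar or manifest is malformed; ``missing`` lists absent keys."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class ConfigurationError(GlottikitError, ValueError):
    """Inconsistent or unsupported configuration values."""


class AliasingError(GlottikitError, ValueError):
    """Oscillation frequency violates the Nyquist limit of the frame rate."""


class EstimationError(GlottikitError, ValueError):
    """Too little data to estimate a statistical model."""
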