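"""Exception types shared across the package."""


class EntroscanError(ValueError):
    """Base class for all entroscan errors."""


class ConfigurationError(EntroscanError):
    """Missing or inconsistent acquisition / run configuration."""


class FormatError(EntroscanError):
    """Input file does not parse to the expected structure."""


class ZeroSpreadError(EntroscanError):
    """Sample has zero spread; the adaptive KDE bandwidth would vanish."""


class DegenerateSplitError(EntroscanError):
    """A binary split left one class empty."""
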