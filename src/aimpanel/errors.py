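"""Exception hierarchy shared across the package."""


class AimpanelError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AimpanelError, ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(AimpanelError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(AimpanelError, ValueError):
    """A numeric or configuration parameter is outside its domain."""


class ShortfallError(AimpanelError, RuntimeError):
    """A selection quota cannot be filled from the eligible SNPs."""


class LayoutError(AimpanelError, ValueError):
    """Feature layout of the input does not match the trained model."""
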