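"""Exception hierarchy shared across the package."""


class LenscatError(Exception):
    """Base class for all package errors."""


class FormatError(LenscatError):
    """Input file is structurally wrong (bad channels, duplicate wavelengths, bad LUT...)."""


class ParseError(FormatError):
    """A cell/row could not be parsed; message carries the location."""


class ValidationError(LenscatError):
    """Input parsed but violates a domain invariant."""


class ParameterError(LenscatError):
    """A caller-supplied parameter is out of its valid range."""


class SegmentationError(LenscatError):
    """Lens detection failed (no foreground, degenerate histogram, tiny component...)."""
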