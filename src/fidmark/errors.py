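"""Exception hierarchy shared across the package."""


class FidmarkError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FidmarkError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class MaterialLookupError(FidmarkError, KeyError):
    """A material name is not present in the material table."""


class GeometryError(FidmarkError, ValueError):
    """A geometric precondition is violated (point outside image, ring exits image, ...)."""


class ProtocolError(FidmarkError, ValueError):
    """An imaging protocol is inconsistent with the requested operation."""


class DataError(FidmarkError, ValueError):
    """Input data are degenerate or corrupt (NaNs in a sinogram, empty ROI, ...)."""


class UndefinedCNRError(FidmarkError, ZeroDivisionError):
    """CNR is undefined because the background SD is zero (noise-free image)."""
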