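"""Exception taxonomy shared across the package.

Each class maps onto one CLI exit code: validation problems (2), ROI
extraction failures (3) and numerical failures (4).
"""


class UnghostError(Exception):
    """Base class for all package errors."""


class ValidationError(UnghostError, ValueError):
    """A parameter or container violates its documented invariants.

    The message always names the offending field.
    """


class ShapeMismatchError(ValidationError):
    """Two containers that must share a grid do not."""


class ROIExtractionError(UnghostError, RuntimeError):
    """No usable region of interest could be extracted ("no ROI found")."""


class SidecarError(UnghostError, IOError):
    """A k-space file is missing or has an inconsistent JSON sidecar."""


class FormatError(UnghostError, IOError):
    """Unknown file extension or malformed on-disk content."""


class NumericalError(UnghostError, ArithmeticError):
    """NaN/Inf encountered mid-computation; message states the iteration."""
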