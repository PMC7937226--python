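"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`PelletmorphError`
so the command-line layer can map them onto stable exit codes
(validation -> 2, I/O -> 3).
"""


class PelletmorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PelletmorphError):
    """Input data violates a documented contract (bad manifest, bad CSV...)."""


class ParameterError(ValidationError):
    """A parameter value is outside its allowed range or inconsistent."""


class ImageFormatError(PelletmorphError):
    """An image file could not be read as a 2-D grayscale micrograph."""


class IOFailureError(PelletmorphError):
    """A file could not be read or written."""


class EmptyDistributionError(PelletmorphError):
    """A summary was requested for a distribution with no particles."""


class UndefinedCVError(PelletmorphError):
    """Coefficient of variation undefined (non-positive mean at a cycle)."""


class NoGrowthError(PelletmorphError):
    """No cycle of a backscatter series ever exceeded the limit of detection."""


class PlacementError(PelletmorphError):
    """Synthetic pellets could not be placed under the separation constraint."""
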