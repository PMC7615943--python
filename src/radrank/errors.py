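"""Exception hierarchy.

Every error raised by this package derives from :class:`RadrankError`
(except plain argument-validation errors, which raise ``ValueError``),
so pipeline drivers can catch one base class and attach case/arm context.
"""


class RadrankError(Exception):
    """Base class for all radrank-specific errors."""


class FormatError(RadrankError):
    """A file exists but its payload is not a valid 3D scalar volume."""


class AlignmentError(RadrankError):
    """A mask and its paired volume do not share the same grid."""


class ManifestError(RadrankError):
    """A cohort manifest is malformed (duplicates, missing columns, empty)."""


class EmptyROIError(RadrankError):
    """A region of interest contains no voxels (e.g. after thresholding)."""


class DegenerateGeometryError(RadrankError):
    """A requested lesion geometry produces an empty mask."""


class PairingError(RadrankError):
    """Two feature tables cannot be paired case-by-case."""


class RegistryError(RadrankError):
    """Two reports do not share the same feature registry."""


class IncompleteDesignError(RadrankError):
    """A classification was requested but required arm comparisons are missing."""


class InsufficientDataError(RadrankError):
    """Fewer than two valid cases are available for a rank correlation."""


class ConfigError(RadrankError):
    """A run configuration violates its invariants."""
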