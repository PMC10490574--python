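"""Exception hierarchy for the PFB pipeline.

Every stage raises a subclass of :class:`PfbError` so callers can catch
pipeline failures without masking programming errors.
"""


class PfbError(Exception):
    """Base class for all PFB pipeline errors."""


class FormatError(PfbError):
    """An input file could not be read or is not in the expected format."""


class ParameterError(PfbError, ValueError):
    """A parameter or spec object violates its invariants."""


class SeedNotFoundError(PfbError):
    """No usable seed point could be located in the image."""


class SegmentationFailure(PfbError):
    """A segmentation method produced an implausible or empty result."""


class EmptyMaskError(PfbError):
    """An operation requiring a nonempty mask received an empty one."""


class DegenerateCurveError(PfbError):
    """A boundary curve has too few raw samples to be meaningful."""


class UndefinedMetricError(PfbError):
    """A metric (DSC/IoU/SNR) is undefined for the given inputs."""


class BalanceError(PfbError):
    """Class-balance operation received a dataset without both classes."""


class AssemblyError(PfbError):
    """Feature assembly received a non-finite or missing value."""


class StratificationError(PfbError):
    """Cross-validation folds cannot be stratified as requested."""
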