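"""Exception hierarchy shared by all junctionkit modules."""


class JunctionKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(JunctionKitError, ValueError):
    """A generator or estimator parameter violates its documented invariant."""


class FormatError(JunctionKitError, IOError):
    """An on-disk stack cannot be interpreted (missing axes, bad metadata)."""


class LowSignalError(JunctionKitError):
    """A reference ROI does not rise above the estimated background."""


class IllConditionedError(JunctionKitError):
    """Reference spectra are too collinear for a stable unmixing solution."""


class BleachVerificationError(JunctionKitError):
    """Acceptor abundance did not drop enough inside the bleach ROI."""


class DegenerateDataError(JunctionKitError):
    """A quantity required for a ratio or fit is zero/empty (e.g. donor mean 0)."""


class NoContrastError(JunctionKitError):
    """Thresholding was requested on an image without intensity contrast."""


class NoCellsError(JunctionKitError):
    """Watershed seeding found no cells in the marker stack."""


class InsufficientCellsError(JunctionKitError):
    """Fewer than two cell centers are available for pair segmentation."""


class NoSpheroidError(JunctionKitError):
    """No connected component above the minimum size was found in a frame."""


class QualityError(JunctionKitError):
    """Too many frames of a movie failed detection to produce a trace."""
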