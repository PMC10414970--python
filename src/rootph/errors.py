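"""Exception hierarchy.

Input/format problems derive from :class:`InputError`; failures of the
analysis itself derive from :class:`AnalysisError`.  The CLI maps these to
exit codes 2 and 3 respectively.
"""


class RootPHError(Exception):
    """Base class for all package errors."""


class InputError(RootPHError):
    """The input file, table or configuration is unusable."""


class FormatError(InputError):
    """A file could not be parsed in the expected format."""


class StructuralError(InputError):
    """Parsed data has the wrong structure (channel count, shape mismatch)."""


class InsufficientStandardsError(InputError):
    """Fewer than three distinct pH standards supplied for calibration."""


class PhantomSpecError(InputError):
    """A synthetic phantom specification is invalid or infeasible."""


class AnalysisError(RootPHError):
    """An analysis stage failed on structurally valid input."""


class NoRootFoundError(AnalysisError):
    """Segmentation found no dark component above the minimum area."""


class StainingFailureError(AnalysisError):
    """Dark fraction of the image too large: the medium is not stained."""


class DegenerateTopologyError(AnalysisError):
    """Skeleton has no usable endpoint pair (loop or single point)."""


class ShortRootError(AnalysisError):
    """Midline too short for tip-tangent estimation."""


class MonotonicityError(AnalysisError):
    """Calibration standards are not monotone in ratio vs pH."""


class CalibrationFitError(AnalysisError):
    """Parametric calibration fit did not converge."""


class AlignmentError(AnalysisError):
    """Profiles have no overlapping position range."""


class TrackingLostError(AnalysisError):
    """More than the allowed number of consecutive frames failed tracking."""


class InsufficientSeriesError(AnalysisError):
    """Time series too short for the requested spectral analysis."""


class WindowError(AnalysisError):
    """A requested longitudinal window lies outside the measured range."""
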