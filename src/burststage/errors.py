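"""Exception hierarchy.

Invalid arguments raise :class:`ValueError` (builtin); everything that can
fail for data-dependent reasons gets its own class so pipelines can report a
machine-readable error code.
"""


class BurstStageError(Exception):
    """Base class for data-dependent failures."""

    code = "computation"


class SegmentationError(BurstStageError):
    """Two-step k-means could not produce valid cell/nuclear masks.

    Carries a ``diagnostics`` dict (cluster centres, component sizes).
    """

    code = "segmentation"

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConvergenceError(BurstStageError):
    code = "convergence"


class AlignmentError(BurstStageError):
    """Axis alignment failed: size profiles carry no usable signal."""

    code = "alignment"


class NoInflectionError(BurstStageError):
    """Duration-output curve has a flat/monotone gradient with no step."""

    code = "no-inflection"


class InsufficientDataError(BurstStageError):
    code = "insufficient-data"


class SingularFitError(BurstStageError):
    code = "singular-fit"


class CannotCalibrateError(BurstStageError):
    """No Low-ON cells available to calibrate the amplitude threshold."""

    code = "cannot-calibrate"


class ConfigurationError(BurstStageError):
    code = "configuration"


class ReportError(BurstStageError):
    code = "report"
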