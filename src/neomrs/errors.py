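"""Exception hierarchy shared across the package."""


class NeomrsError(Exception):
    """Base class for all package errors."""


class FormatError(NeomrsError):
    """A file or sidecar is malformed (missing field, bad header)."""


class IntegrityError(NeomrsError):
    """Data are self-inconsistent (length mismatch, orphan label, duplicate row)."""


class ConfigError(NeomrsError):
    """A configuration value or combination is invalid."""


class DomainError(NeomrsError, ValueError):
    """An argument is outside the mathematical/physical domain of the operation."""


class FitError(NeomrsError):
    """Model fitting failed to converge; carries the last residual."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class DegenerateInputError(NeomrsError):
    """Input carries no usable signal (all-zero data, empty window)."""


class LowConfidenceError(NeomrsError):
    """A peak needed for an estimate is below the confidence threshold.

    Carries the per-peak SNRs so the caller can report them.
    """

    def __init__(self, message, peak_snrs=None):
        super().__init__(message)
        self.peak_snrs = peak_snrs or {}


class PreprocessingError(NeomrsError):
    """Spectral-vector preprocessing failed (e.g. reference peak undetectable)."""


class UndefinedSNRError(NeomrsError):
    """SNR is undefined because the noise-window standard deviation is zero."""


class PipelineStageError(NeomrsError):
    """A pipeline stage failed; the message names the stage and the
    offending subject/region."""
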