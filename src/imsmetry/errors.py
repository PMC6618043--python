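"""Exception hierarchy.

Everything derives from :class:`ImsmetryError` so callers can catch the
package's own failures separately from programming errors.
"""


class ImsmetryError(Exception):
    """Base class for all imsmetry errors."""


class InvalidGasStateError(ImsmetryError, ValueError):
    """Gas state is unphysical (non-positive pressure, temperature or density)."""


class DomainError(ImsmetryError, ValueError):
    """An input is outside the physical domain of an equation."""


class CalibrationError(ImsmetryError, ValueError):
    """A calibration cannot be fitted or applied (rank deficiency, too few points,
    settings mismatch, unphysical transit time, ...)."""


class PropagationError(ImsmetryError, RuntimeError):
    """Monte-Carlo propagation produced non-finite model output."""


class WaveformError(ImsmetryError, ValueError):
    """A FAIMS waveform violates its contract (non-periodic, not normalized, zero)."""


class NoSolutionError(ImsmetryError, RuntimeError):
    """Root bracketing failed for the compensation-field solver."""


class ExtractionError(ImsmetryError, ValueError):
    """Alpha-function extraction is underdetermined."""


class ClassificationError(ImsmetryError, ValueError):
    """Too few points to classify a FAIMS curve."""


class NoPeakError(ImsmetryError, ValueError):
    """No local maximum in the requested window of a distribution."""


class FormattingError(ImsmetryError, ValueError):
    """A result lacks the provenance needed to format its notation."""


class ValidationError(ImsmetryError, ValueError):
    """Unknown platform or malformed record in report validation."""
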