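"""Exception hierarchy for marginspec."""


class MarginSpecError(Exception):
    """Base class for all marginspec errors."""


class FormatError(MarginSpecError, ValueError):
    """Malformed input file (non-monotone header, ragged rows, bad JCAMP)."""


class RangeError(MarginSpecError, ValueError):
    """A wavenumber window falls outside, or does not overlap, the axis."""


class ConfigError(MarginSpecError, ValueError):
    """Invalid processing configuration (even SG window, bad SNR window...)."""


class ModalityError(MarginSpecError, ValueError):
    """Operation applied to the wrong modality (e.g. despiking FT-IR data)."""


class SizeError(MarginSpecError, ValueError):
    """Too few points or spectra for the requested operation."""


class NormalizationError(MarginSpecError, ValueError):
    """Spectrum has (near-)zero integral and cannot be area-normalized."""


class DegeneracyError(MarginSpecError, ValueError):
    """Dataset has zero total variance; PCA is undefined."""


class LabelError(MarginSpecError, ValueError):
    """Class labels missing or single-class where two classes are required."""


class CalibrationError(MarginSpecError, RuntimeError):
    """Generator calibration failed to reach its targets."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
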