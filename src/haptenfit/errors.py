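"""Exception hierarchy.

Each pipeline stage raises its own subclass so that callers (and the CLI)
can name the failing stage in error messages.
"""


class HaptenfitError(Exception):
    """Base class for all package errors."""


class SpectrumIOError(HaptenfitError):
    """Unreadable, unwritable or malformed spectrum file."""


class CalibrationError(HaptenfitError):
    """Invalid or degenerate calibration input."""


class PeakShapeError(HaptenfitError):
    """A peak-shape measurement (e.g. FWHM) is undefined for the input."""


class PreprocessError(HaptenfitError):
    """Invalid smoothing / baseline parameters for the given spectrum."""


class FitError(HaptenfitError):
    """Ladder deconvolution could not be performed or did not converge."""


class ChemistryError(HaptenfitError):
    """Invalid peptide design or conjugation-chemistry input."""


class SimulationError(HaptenfitError):
    """Invalid simulation configuration."""
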