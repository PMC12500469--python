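"""Exception hierarchy for mrselect.

All package errors derive from :class:`MRSelectError` so callers can catch a
single base class at the CLI boundary.
"""


class MRSelectError(Exception):
    """Base class for all mrselect errors."""


class ConfigurationError(MRSelectError):
    """Invalid user configuration (bad threshold, missing column, ...)."""


class InputError(MRSelectError):
    """Structurally valid configuration but unusable input data."""


class EmptyInstrumentError(InputError):
    """No variant survives instrument selection."""


class HarmonizationError(InputError):
    """Fewer than two variants survive allele harmonization."""


class EstimationError(MRSelectError):
    """An estimator cannot be computed on the given instrument set."""


class InsufficientInstrumentsError(EstimationError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(EstimationError):
    """A single-instrument quantity is undefined (e.g. gamma == 0)."""


class CollinearExposuresError(EstimationError):
    """Exposure association columns are (numerically) linearly dependent."""

    def __init__(self, message, exposures=None):
        super().__init__(message)
        self.exposures = list(exposures) if exposures else []


class ConvergenceError(EstimationError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
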