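"""Exception hierarchy shared across the package."""


class OscillabError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(OscillabError, ValueError):
    """A mechanical model violates its physical constraints."""


class FrequencyDomainError(OscillabError, ValueError):
    """A frequency is outside the domain where the model is defined."""


class UndefinedResonanceError(OscillabError, ValueError):
    """Resonance is undefined (e.g. zero inertance)."""


class UnsupportedModelError(OscillabError, ValueError):
    """The requested operation is not defined for this model variant."""


class ExcitationSpecError(OscillabError, ValueError):
    """Invalid multisine excitation specification."""


class SingularModelError(OscillabError, ValueError):
    """The model impedance vanishes at an excitation component."""


class GenerationError(OscillabError, RuntimeError):
    """Cohort ground-truth generation failed (infeasible draws)."""


class RecordLengthError(OscillabError, ValueError):
    """A signal record is shorter than one analysis block."""


class GridError(OscillabError, ValueError):
    """A component frequency does not coincide with an FFT bin."""


class DegenerateSignalError(OscillabError, ValueError):
    """Auto-spectrum is zero at a component frequency."""


class ExamQCError(OscillabError, RuntimeError):
    """No exam passed the coherence quality gate for a subject."""


class InsufficientDataError(OscillabError, ValueError):
    """Too few usable observations for the requested operation."""


class UndefinedCorrelationError(OscillabError, ValueError):
    """Correlation undefined (zero variance in a variable)."""


class ClassBalanceError(OscillabError, ValueError):
    """A required class is absent from the data."""


class OrientationError(OscillabError, ValueError):
    """AUC below 0.5 passed where an oriented curve is required."""


class CombinatorialLimitError(OscillabError, ValueError):
    """Too many candidate features for exhaustive enumeration."""


class ConfigError(OscillabError, ValueError):
    """Pipeline configuration failed schema validation."""
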