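"""Exception hierarchy for amentrain."""


class AmentrainError(Exception):
    """Base class for all amentrain errors."""


class InvalidInputError(AmentrainError):
    """Input data violates a precondition (empty, unsorted, constant, ...)."""


class ConfigurationError(AmentrainError):
    """A configuration value is inconsistent (band above Nyquist, bad edges, ...)."""


class InsufficientDataError(AmentrainError):
    """Too few observations for the requested statistic."""


class UndefinedPhaseError(AmentrainError):
    """Instantaneous phase requested for a signal with no oscillation (all zeros)."""
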