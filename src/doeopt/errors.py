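"""Exception hierarchy for doeopt."""


class DoeoptError(Exception):
    """Base class for all doeopt errors."""


class ValidationError(DoeoptError):
    """Invalid user input: factor/response declarations, design arguments."""


class ResolutionError(ValidationError):
    """Screening resolution too fine for an ordinal factor (duplicate levels)."""


class ConfigError(DoeoptError):
    """Malformed or inconsistent configuration document."""


class ScoringError(DoeoptError):
    """A response value could not be scored (non-finite, missing)."""


class FitError(DoeoptError):
    """OLS fit impossible (rank deficiency, too few runs)."""


class SelectionError(DoeoptError):
    """No candidate model could be fitted."""


class RenderError(DoeoptError):
    """A command template could not be fully rendered."""


class ExecutionError(DoeoptError):
    """Pipeline execution failed at the phase level."""


class ScreeningError(DoeoptError):
    """The screening phase produced no usable runs."""


class IterationError(DoeoptError):
    """An optimization iteration failed (too many failed runs)."""
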