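"""Exception hierarchy shared across the package."""


class PlaidChoiceError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PlaidChoiceError):
    """A required column or header element is missing from an input file."""


class ValidationError(PlaidChoiceError):
    """An input value violates a hard domain invariant."""


class ConfigError(PlaidChoiceError):
    """A simulation or pipeline configuration value is invalid."""


class InputError(PlaidChoiceError):
    """An analysis operation received data it cannot act on."""


class UndefinedCorrelationError(InputError):
    """A correlation is undefined because one input has zero variance."""


class DegenerateFitError(PlaidChoiceError):
    """A fit hit a boundary or the data carry no information about a parameter.

    Carries the best bounded fit found, so callers can inspect or report it.
    """

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit
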