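"""Exception hierarchy shared across the package."""


class SynrecruitError(Exception):
    """Base class for all package errors."""


class ValidationError(SynrecruitError, ValueError):
    """Malformed or inconsistent input data."""


class MissingTaxonError(SynrecruitError, KeyError):
    """A strain or genome identifier is not present in the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return str(self.args[0]) if self.args else ""


class ConfigurationError(SynrecruitError):
    """A required input, column or parameter is missing or out of range."""


class InsufficientDataError(SynrecruitError):
    """Too few observations to perform the requested estimation."""


class UnfittableError(SynrecruitError):
    """The data carry no signal the model could be fitted to (e.g. all-zero rates)."""


class FitError(SynrecruitError):
    """Optimization failed to converge from every starting point."""
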