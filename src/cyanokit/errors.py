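"""Exception hierarchy shared across the package."""


class CyanokitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CyanokitError):
    """A standard-format input (FASTA, GFF3, tabular) could not be parsed.

    Carries the offending file and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class DomainError(CyanokitError):
    """An argument is outside the mathematical domain of an operation."""


class SpecError(CyanokitError):
    """A synthetic-data specification is internally inconsistent."""


class FitError(CyanokitError):
    """A model fit failed to converge or left the admissible parameter region.

    ``diagnostics`` holds whatever the optimiser reported (message, final
    parameters, residual) so that failures are never silent.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class EstimationError(CyanokitError):
    """A signal-processing estimate (baseline, plateau, half-time) is undefined
    for the supplied trace."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class ConfigError(CyanokitError):
    """Invalid run configuration (unknown key, bad pattern, missing input)."""
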