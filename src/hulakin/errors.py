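"""Exception hierarchy shared across the package."""


class HulakinError(Exception):
    """Base class for all package errors."""


class ValidationError(HulakinError, ValueError):
    """Invalid input data or parameters."""


class FormatError(HulakinError, ValueError):
    """Malformed input file (bad header, wrong columns, unparseable values)."""


class ConvergenceError(HulakinError, RuntimeError):
    """An iterative numerical procedure failed to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
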