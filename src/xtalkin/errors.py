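"""Exception hierarchy shared across the estimation stages."""


class XtalkinError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(XtalkinError, ValueError):
    """An argument violates a physical or mathematical precondition."""


class InsufficientDataError(XtalkinError, ValueError):
    """Too few observations to perform the requested estimate."""


class FitFailureError(XtalkinError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ValidationError(XtalkinError, ValueError):
    """Tabular input failed schema validation; lists all failures."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))
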