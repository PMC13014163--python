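"""Exception types shared across the package."""


class AppersistError(Exception):
    """Base class for all package errors."""


class ConfigError(AppersistError, ValueError):
    """A configuration value failed validation; the message names the field."""


class DataInconsistencyError(AppersistError, ValueError):
    """Input records contradict each other (e.g. death before initiation)."""


class ConvergenceError(AppersistError, RuntimeError):
    """Model fitting failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RankDeficiencyError(AppersistError, ValueError):
    """Design matrix is rank deficient for the requested model."""
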