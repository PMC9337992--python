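"""Exception hierarchy for the pipeline."""


class VmError(Exception):
    """Base class for all pipeline errors."""


class DataError(VmError):
    """Input data violates a contract (e.g. non-positive DMSO confluence)."""


class FitError(VmError):
    """Curve fitting failed from every start; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(VmError):
    """Run configuration is invalid; message lists all problems at once."""
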