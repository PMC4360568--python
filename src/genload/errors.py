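"""Exception hierarchy shared across the package.

Every user-facing failure maps onto one of these so the CLI can translate
them into stable exit codes.
"""


class GenloadError(Exception):
    """Base class for all package errors."""


class ParameterError(GenloadError, ValueError):
    """A parameter is outside its mathematical domain (negative rate, etc.)."""


class InfeasibleParametersError(ParameterError):
    """Parameters are individually valid but jointly inconsistent
    (e.g. a relative risk too small to explain the observed sex ratio)."""


class ContractError(GenloadError, ValueError):
    """Two objects passed together do not belong together
    (mismatched architectures, a selection solution for a different pmf)."""


class ConvergenceError(GenloadError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ExtinctionError(GenloadError, RuntimeError):
    """A simulated population lost all individuals; partial statistics are
    attached so the run up to extinction can still be inspected."""

    def __init__(self, message: str, partial_stats=None):
        super().__init__(message)
        self.partial_stats = partial_stats
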