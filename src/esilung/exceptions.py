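"""Exception types raised across the package."""


class DomainError(ValueError):
    """An input value lies outside the domain of an operation."""


class MalformedInputError(ValueError):
    """Structurally invalid input (bad shapes, unparseable files, ...)."""


class DegenerateCurveError(DomainError):
    """A flow-volume curve has no usable descending limb."""


class FitFailureError(RuntimeError):
    """Every optimisation start failed; carries partial diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
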