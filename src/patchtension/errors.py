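"""Exception hierarchy shared across the package."""


class PatchTensionError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PatchTensionError, ValueError):
    """An argument violates a documented precondition."""


class InvalidGeometryError(PatchTensionError, ValueError):
    """A geometric quantity (radius, arc placement) is physically invalid."""


class DegenerateGeometryError(InvalidGeometryError):
    """Collinear / rank-deficient input where a circle is required."""


class InsufficientPointsError(PatchTensionError, ValueError):
    """Fewer points survive than the downstream operation needs."""


class OutOfRangeError(PatchTensionError, ValueError):
    """A time or index falls outside the data it addresses."""


class FitFailureError(PatchTensionError, RuntimeError):
    """Nonlinear fit failed to converge from every start point."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NormalizationError(PatchTensionError, ValueError):
    """Normalization undefined (e.g. all peak currents are zero)."""
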