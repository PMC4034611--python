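"""Exceptions shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition or file schema."""


class DegenerateGeometryError(ValidationError):
    """Raised for geometrically degenerate inputs (duplicate points, zero
    perimeter, collinear outlines) that signal a broken digitization."""
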