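"""Exception hierarchy shared across the package."""


class ConftorError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ConftorError):
    """A structure, annotation, or PQR file could not be parsed."""


class AnnotationError(ConftorError):
    """A region annotation is missing, malformed, or inconsistent."""


class MembraneError(ConftorError):
    """A membrane model could not be constructed or is missing."""


class GeometryError(ConftorError):
    """Degenerate or invalid geometry (zero vectors, collinear sets...)."""


class AnchorError(ConftorError):
    """A conftor anchor could not be resolved on the structure."""
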