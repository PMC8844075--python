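"""Categorized exception hierarchy.

Every error raised by the package derives from :class:`PocketframeError` and
carries a stable ``category`` string (input / annotation / geometry / pairing)
so shell pipelines can dispatch on it.
"""


class PocketframeError(Exception):
    """Base class for all package errors."""

    category = "error"


class InputError(PocketframeError):
    """Malformed, unreadable or empty input (files, arrays, parameters)."""

    category = "input"


class AnnotationError(PocketframeError):
    """Inconsistent TM-helix ranges or generic-numbering tables."""

    category = "annotation"


class GeometryError(PocketframeError):
    """Degenerate or contradictory geometry (collinear points, inverted bounds)."""

    category = "geometry"


class PairingError(PocketframeError):
    """No common residues between two structures to be compared."""

    category = "pairing"
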