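"""Exception hierarchy for the AFM pipeline."""


class AFMError(Exception):
    """Base class for all AFM-specific errors."""


class AnnotationError(AFMError):
    """Malformed, unsupported, or unlabelled annotation input."""


class InvalidPolygonError(AnnotationError):
    """Polygon fails the tubule-annotation invariants (< 3 vertices, zero area, ...)."""


class UnsupportedGeometryError(AnnotationError):
    """GeoJSON geometry that is not a (single-part) Polygon."""


class LabellingError(AnnotationError):
    """Feature without a recognizable distal/proximal class label in strict mode."""


class ImageError(AFMError):
    """Unreadable or unsupported image input."""


class UnsupportedDepthError(ImageError):
    """Image bit depth other than 8-bit; no silent rescaling is performed."""


class OutOfBoundsError(AFMError):
    """Tubule centroid outside the image bounds."""


class DegenerateInputError(AFMError):
    """Empty tile, zero denominator, or otherwise degenerate numeric input."""


class InsufficientGroupsError(AFMError):
    """Fewer than two classes (or too few values per class) for a group comparison."""


class PlacementError(AFMError):
    """Synthetic tubule placement failed within the retry budget."""


class ConfigError(AFMError):
    """Invalid run configuration (mismatched pairing, bad parameter ranges)."""
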