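"""Exception hierarchy shared by all neuroseg stages.

Exit-code mapping used by the CLI: usage errors → 2, :class:`DetectionError`
→ 3, :class:`DegenerateClusteringError` → 4, anything else → 1.
"""


class NeurosegError(Exception):
    """Base class for all neuroseg errors."""


class FormatError(NeurosegError):
    """Unreadable or unsupported image format."""


class BoundsError(NeurosegError):
    """Index (e.g. slice_index) out of range."""


class ShapeError(NeurosegError):
    """Mismatched array dimensions between operands."""


class ArgumentError(NeurosegError):
    """Invalid parameter value for an operation."""


class GeometryError(NeurosegError):
    """Infeasible geometric configuration (nesting, degenerate ellipse...)."""


class DetectionError(NeurosegError):
    """Skull-outline detection failed (insufficient accumulator support)."""


class DegenerateClusteringError(NeurosegError):
    """Clustering collapsed (coincident centers, too few tissues)."""


class EmptyRegionError(NeurosegError):
    """An operation that requires a nonempty region received none."""


class UndefinedMeasureError(NeurosegError):
    """A similarity measure is undefined for the given inputs."""
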