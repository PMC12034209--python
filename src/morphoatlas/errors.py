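"""Exception types raised across the package."""


class MorphoAtlasError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(MorphoAtlasError):
    """A mesh file could not be parsed (malformed header, unsupported elements)."""


class MeshIndexError(MorphoAtlasError):
    """A face references a vertex index outside the vertex table."""


class MeshTopologyError(MorphoAtlasError):
    """An operation could not preserve or produce the required topology."""


class AlignmentError(MorphoAtlasError):
    """Landmark-based alignment is underdetermined (too few or collinear points)."""


class LandmarkSchemeError(MorphoAtlasError):
    """A landmark configuration violates its scheme (ordering, curves, counts)."""


class AtlasDivergenceError(MorphoAtlasError):
    """Atlas estimation produced a non-finite loss."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


class PhylogenyError(MorphoAtlasError):
    """A tree is unusable (duplicate tips, non-positive branch lengths)."""
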