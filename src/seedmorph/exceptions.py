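"""Exception hierarchy for seedmorph.

All package errors derive from :class:`SeedmorphError` so callers can catch
one type at a CLI boundary while tests discriminate the specific failure.
"""


class SeedmorphError(Exception):
    """Base class for all seedmorph errors."""


class InvalidParamsError(SeedmorphError, ValueError):
    """Seed shape parameters violate their invariants."""


class SelfOverlapError(InvalidParamsError):
    """The requested arc band would self-intersect (curvature radius <= width/2)."""


class InvalidSilhouetteError(SeedmorphError, ValueError):
    """A silhouette violates its invariants (empty mask, multiple components, ...)."""


class MissingLatticeError(SeedmorphError):
    """Pit counting requested on a silhouette without a pit lattice."""


class SkeletonError(SeedmorphError):
    """No usable single medial path could be extracted from the mask."""


class DegenerateContourError(SeedmorphError, ValueError):
    """Contour is collinear/degenerate; no enclosing rectangle exists."""


class SingularScatterError(SeedmorphError, ValueError):
    """Within-group scatter is singular; remove redundant traits (see tolerance)."""


class InvalidCardError(SeedmorphError, ValueError):
    """A species range card violates quartet monotonicity or units."""


class TraitTableError(SeedmorphError, ValueError):
    """A trait table is malformed (missing columns, NaNs, bad rows)."""


class EmptyTableError(TraitTableError):
    """A trait table file contained no data rows."""


class KeyTraversalError(SeedmorphError, ValueError):
    """A trait vector is missing a field required by the identification key."""
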