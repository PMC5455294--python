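"""Core silhouette containers.

A seed is measured from its binary silhouette. The silhouette carries both a
raster mask (what an SEM-image pipeline would produce) and the closed polygon
contour in physical micrometre coordinates; synthetic silhouettes additionally
carry the generating parameters and the pit lattice of the reticulate seed
coat. Coordinate convention: contour vertices are (x, y) in µm, origin at the
mask corner, y increasing downward (row direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from .exceptions import InvalidParamsError, InvalidSilhouetteError

PIT_SHAPES = ("rectangular", "hexagonal", "round", "network")


@dataclass(frozen=True)
class SeedShapeParams:
    """Generative ground truth for one synthetic seed.

    Parameters
    ----------
    axis_length : float
        Length of the medial axis (the curved long axis of the seed), µm.
    width : float
        Band width (seed thickness transverse to the medial axis), µm.
    curvature_angle : float
        Total angular bending γ of the medial axis in degrees: 0 for a
        straight seed, up to ~350 for horseshoe-shaped seeds.
    n_pits : int
        Number of seed-coat pits along the middle row (the row traversed by
        the medial axis).
    pit_shape : str
        Categorical coat character, one of ``PIT_SHAPES``.
    membrane : bool
        Presence of the semilunar membrane on the concave side.
    seed_id : str
        Opaque label.
    """

    axis_length: float
    width: float
    curvature_angle: float = 0.0
    n_pits: int = 20
    pit_shape: str = "rectangular"
    membrane: bool = False
    seed_id: str = ""

    def __post_init__(self) -> None:
        if not (self.axis_length > self.width > 0):
            raise InvalidParamsError(
                f"require axis_length > width > 0, got "
                f"axis_length={self.axis_length}, width={self.width}"
            )
        if not (0.0 <= self.curvature_angle <= 350.0):
            raise InvalidParamsError(
                f"curvature_angle must be in [0, 350], got {self.curvature_angle}"
            )
        if int(self.n_pits) != self.n_pits or self.n_pits < 1:
            raise InvalidParamsError(f"n_pits must be a positive integer, got {self.n_pits}")
        if self.pit_shape not in PIT_SHAPES:
            raise InvalidParamsError(
                f"pit_shape must be one of {PIT_SHAPES}, got {self.pit_shape!r}"
            )

    @property
    def curvature_radius(self) -> float:
        """Radius of the medial arc in µm (inf for a straight seed)."""
        if self.curvature_angle < 1.0:
            return float("inf")
        return self.axis_length * 180.0 / (self.curvature_angle * np.pi)


@dataclass
class SeedSilhouette:
    """Binary silhouette of one seed plus physical scale.

    Attributes
    ----------
    mask : ndarray of bool, shape (rows, cols)
        Foreground = seed. Exactly one connected component, no holes.
    pixel_size : float
        µm per pixel (isotropic).
    contour : ndarray of float, shape (n, 2)
        Closed simple polygon in µm, positively oriented (counter-clockwise
        in the y-down convention used by shapely with plain coordinates).
    pit_lattice : list of ndarray, optional
        Polyline cell boundaries of the seed-coat reticulum, µm coordinates.
    provenance : SeedShapeParams, optional
        Generating parameters when synthetic.
    """

    mask: np.ndarray
    pixel_size: float
    contour: np.ndarray
    pit_lattice: list[np.ndarray] | None = None
    provenance: SeedShapeParams | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.contour = np.asarray(self.contour, dtype=float)
        if self.pixel_size <= 0:
            raise InvalidSilhouetteError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.mask.ndim != 2 or not self.mask.any():
            raise InvalidSilhouetteError("mask must be a non-empty 2-D binary image")
        if self.contour.ndim != 2 or self.contour.shape[1] != 2 or len(self.contour) < 3:
            raise InvalidSilhouetteError("contour must be an (n>=3, 2) array of µm coordinates")
        poly = Polygon(self.contour)
        if not poly.is_valid:
            raise InvalidSilhouetteError("contour polygon is self-intersecting or invalid")
        if _signed_area(self.contour) < 0:
            # normalize to positive orientation
            self.contour = self.contour[::-1].copy()

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.contour)

    def validate_topology(self) -> None:
        """Raise unless the mask has exactly one hole-free foreground component."""
        from scipy import ndimage

        n_fg = ndimage.label(self.mask)[1]
        if n_fg != 1:
            raise InvalidSilhouetteError(f"mask has {n_fg} foreground components, expected 1")
        filled = ndimage.binary_fill_holes(self.mask)
        if (filled ^ self.mask).any():
            raise InvalidSilhouetteError("mask foreground contains holes")

    def rotated(self, angle_deg: float) -> "SeedSilhouette":
        """Return the same physical seed rotated by `angle_deg` (re-rasterized)."""
        from .synthetic import rasterize_contour

        theta = np.radians(angle_deg)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        contour = self.contour @ rot.T
        lattice = None
        if self.pit_lattice is not None:
            lattice = [np.asarray(p, float) @ rot.T for p in self.pit_lattice]
        pad = 2.0 * self.pixel_size
        offset = contour.min(axis=0) - pad
        contour = contour - offset
        if lattice is not None:
            lattice = [p - offset for p in lattice]
        mask = rasterize_contour(contour, self.pixel_size)
        public_meta = {k: v for k, v in self.meta.items() if not k.startswith("_")}
        return replace(
            self, mask=mask, contour=contour, pit_lattice=lattice,
            meta={**public_meta, "rotated_deg": angle_deg},
        )


def _signed_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
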