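"""Analysis regions: disc ellipse and diagonal/anti-diagonal quadrants.

Each en-face segment image is analysed over five regions: the whole
segment plus four triangular quadrants (superior, inferior, nasal,
temporal) formed by the diagonal and anti-diagonal lines through the
analysis center. For macular scans the center is the image center; for
optic-disc scans it is the center of the ellipse inscribed in a manually
annotated bounding box of the disc. Nasal/temporal labels mirror between
right (OD) and left (OS) eyes.

Coordinate convention: 0-based pixel indices, pixel centers at integer
coordinates, x along columns, y along rows and increasing downward (so the
top sector of the image is anatomically superior).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .preprocess import EnFaceImage

__all__ = [
    "DiscAnnotation",
    "EllipseGeometry",
    "RegionSet",
    "ellipse_from_bbox",
    "ellipse_mask",
    "quadrant_masks",
    "build_region_set",
]

QUADRANT_NAMES = ("superior", "inferior", "nasal", "temporal")


@dataclass(frozen=True)
class DiscAnnotation:
    """Axis-aligned bounding box of the optic disc, (x_min, y_min, x_max, y_max).

    Coordinates are 0-based pixel positions, inclusive on min and exclusive
    on max.
    """

    bbox: Tuple[float, float, float, float]

    def __post_init__(self) -> None:
        x_min, y_min, x_max, y_max = self.bbox
        if not (x_min < x_max and y_min < y_max):
            raise ValueError("degenerate bounding box")


@dataclass(frozen=True)
class EllipseGeometry:
    """Axis-aligned ellipse inscribed in a disc bounding box."""

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("semi-axes must be > 0")


@dataclass
class RegionSet:
    """Named binary masks over one image grid: segment + four quadrants."""

    segment_mask: np.ndarray
    quadrant_masks: Dict[str, np.ndarray]
    center_used: Tuple[float, float]
    laterality: str
    ellipse: Optional[EllipseGeometry] = None

    def pixel_counts(self) -> Dict[str, int]:
        counts = {"segment": int(self.segment_mask.sum())}
        counts.update({name: int(m.sum()) for name, m in self.quadrant_masks.items()})
        return counts


def ellipse_from_bbox(annotation: DiscAnnotation) -> EllipseGeometry:
    """Inscribe an axis-aligned ellipse in the disc bounding box."""
    x_min, y_min, x_max, y_max = annotation.bbox
    return EllipseGeometry(
        center=((x_min + x_max) / 2.0, (y_min + y_max) / 2.0),
        semi_axes=((x_max - x_min) / 2.0, (y_max - y_min) / 2.0),
    )


def ellipse_mask(geometry: EllipseGeometry, shape: Tuple[int, int]) -> np.ndarray:
    """Rasterise the ellipse interior (boundary inclusive) on a pixel grid."""
    h, w = shape
    cx, cy = geometry.center
    a, b = geometry.semi_axes
    y, x = np.mgrid[0:h, 0:w]
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def quadrant_masks(shape: Tuple[int, int], center: Tuple[float, float],
                   laterality: str, od_nasal_side: str = "right",
                   ) -> Dict[str, np.ndarray]:
    """Split a grid into four quadrants by the diagonals through ``center``.

    The lines ``y - cy = +/-(x - cx)`` divide the grid into four triangular
    sectors. The top sector (smaller y) is superior and the bottom
    inferior; the left/right sectors map to nasal/temporal according to eye
    laterality and the ``od_nasal_side`` convention (image orientation of
    device exports is not guaranteed, so the side is configurable; OS is
    always the mirror of OD).

    Tie rule: a pixel exactly on the anti-diagonal joins the vertically
    adjacent sector of its ray (superior above the center, inferior
    below); a pixel exactly on the diagonal joins the horizontally
    adjacent sector of its ray (right/left of the center); a pixel at the
    center joins superior. This keeps the tiling exact and — because each
    line's two rays split evenly between opposite sectors — yields exactly
    equal quadrant pixel counts for half-integer centers of even-sized
    grids, where both full diagonals of pixels lie on the dividing lines.
    """
    h, w = shape
    cx, cy = center
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise ValueError("center must lie inside the grid")
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    if od_nasal_side not in ("right", "left"):
        raise ValueError("od_nasal_side must be 'right' or 'left'")

    y, x = np.mgrid[0:h, 0:w]
    dx = x - cx
    dy = y - cy
    s = dx + dy   # zero on the anti-diagonal
    t = dy - dx   # zero on the diagonal
    on_anti = s == 0  # includes a pixel exactly at the center
    on_diag = (t == 0) & ~on_anti
    superior = ((t < 0) & (s < 0)) | (on_anti & (dy <= 0))
    inferior = ((t > 0) & (s > 0)) | (on_anti & (dy > 0))
    right = ((t < 0) & (s > 0)) | (on_diag & (dx > 0))
    left = ((t > 0) & (s < 0)) | (on_diag & (dx < 0))

    nasal_is_right = (od_nasal_side == "right") == (laterality == "OD")
    return {
        "superior": superior,
        "inferior": inferior,
        "nasal": right if nasal_is_right else left,
        "temporal": left if nasal_is_right else right,
    }


def build_region_set(image: EnFaceImage,
                     disc_annotation: Optional[DiscAnnotation] = None,
                     disc_interior: str = "include",
                     od_nasal_side: str = "right") -> RegionSet:
    """Construct the five analysis regions for one segment image.

    Macular scans use the image center and the full frame; optic-disc
    scans require a disc bounding-box annotation, center the quadrants on
    the inscribed-ellipse center, and honour ``disc_interior``:

    * ``include`` — whole frame (macular convention; default),
    * ``exclude_inside_ellipse`` — frame minus the disc interior,
    * ``only_inside_ellipse`` — disc interior only.

    The ellipse is always computed and stored for provenance. The exact
    tiling of the segment by the quadrants is asserted on every call.
    """
    if disc_interior not in ("include", "exclude_inside_ellipse", "only_inside_ellipse"):
        raise ValueError(f"unknown disc_interior option {disc_interior!r}")
    shape = image.pixels.shape
    h, w = shape
    ellipse: Optional[EllipseGeometry] = None

    if image.scan_type == "macula":
        if disc_annotation is not None:
            raise ValueError("macula scans must not carry a disc annotation")
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        segment = np.ones(shape, dtype=bool)
    else:  # disc
        if disc_annotation is None:
            raise ValueError("disc scans require a disc annotation")
        ellipse = ellipse_from_bbox(disc_annotation)
        center = ellipse.center
        if disc_interior == "include":
            segment = np.ones(shape, dtype=bool)
        elif disc_interior == "exclude_inside_ellipse":
            segment = ~ellipse_mask(ellipse, shape)
        else:
            segment = ellipse_mask(ellipse, shape)

    quads = quadrant_masks(shape, center, image.laterality, od_nasal_side)
    quads = {name: m & segment for name, m in quads.items()}

    total = sum(int(m.sum()) for m in quads.values())
    if total != int(segment.sum()):
        raise RuntimeError(
            f"quadrants do not tile the segment: {total} != {int(segment.sum())}")
    return RegionSet(segment_mask=segment, quadrant_masks=quads,
                     center_used=center, laterality=image.laterality,
                     ellipse=ellipse)
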