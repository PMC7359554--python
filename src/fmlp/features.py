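"""Border-irregularity measures: box-counting fractal dimension and convexity.

The irregularity of a lesion is summarized by a two-value vector:

* fractal dimension D — the slope of log N(e) against log(1/e), where
  N(e) is the number of cells of an e x e lattice (anchored at the image
  origin) that contain at least one border pixel.  A straight border gives
  D = 1; space-filling, highly indented borders push D toward 2.
  D is measured on the *border image* (the detected edge pixels).

* convexity — the perimeter of the convex hull of the lesion divided by
  the lesion's own boundary perimeter, both measured as polygon arc
  lengths (contour steps weighted 1 axially and sqrt(2) diagonally).
  Convex lesions score 1; indentations lengthen the boundary without
  lengthening the hull, pushing the ratio below 1.  Convexity is measured
  on the *segmentation mask*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .exceptions import ValidationError
from .fuzzedge import contour_perimeter, extract_border

__all__ = [
    "IrregularityVector",
    "box_count",
    "default_box_sizes",
    "fractal_dimension",
    "convexity",
    "extract_features",
]

#: discretization allowance on convexity: pixelated hulls can exceed the
#: continuous bound of 1 by a small margin
CONVEXITY_EPS = 0.05


@dataclass(frozen=True)
class IrregularityVector:
    """The two-value border irregularity measure for one lesion."""

    fractal_dimension: float
    convexity: float
    source_id: str = ""


def box_count(border: np.ndarray, e: int) -> int:
    """Number of cells of an e x e lattice (anchored at (0, 0)) containing
    at least one border pixel."""
    if e < 1:
        raise ValidationError("box side e must be >= 1")
    coords = np.argwhere(np.asarray(border, dtype=bool))
    if coords.size == 0:
        raise ValidationError("border is empty")
    cells = coords // e
    return int(np.unique(cells, axis=0).shape[0])


def default_box_sizes(side: int) -> list[int]:
    """Powers of 2 from 2 up to side // 8 (at least {2, 4, 8}).

    Box sizes above ~1/8 of the image hold so few cells that the additive
    small-count bias of closed borders dominates the slope, so the ladder
    stays below that.
    """
    sizes = []
    e = 2
    while e <= max(8, side // 8):
        sizes.append(e)
        e *= 2
    return sizes


def fractal_dimension(
    border: np.ndarray, sizes: Sequence[int] | None = None
) -> float:
    """Box-counting dimension: least-squares slope of log N(e) vs log(1/e).

    The default size ladder is powers of 2 from 2 up to a quarter of the
    image side; the fit uses every point on the ladder.
    """
    border = np.asarray(border, dtype=bool)
    if not border.any():
        raise ValidationError("border is empty")
    if sizes is None:
        sizes = default_box_sizes(max(border.shape))
    sizes = [int(e) for e in sizes]
    if len(sizes) < 3:
        raise ValidationError("need at least 3 box sizes for a stable slope")
    counts = np.array([box_count(border, e) for e in sizes], dtype=float)
    if np.any(counts == 0):
        raise ValidationError("box count of zero encountered")
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                          np.log(counts), 1)
    return float(slope)


def convexity(mask: np.ndarray) -> float:
    """Convex-hull perimeter divided by lesion boundary perimeter.

    The hull is computed over the foreground pixel coordinates; the
    lesion perimeter is the traced-contour arc length.  Multi-component
    masks fall back to the largest component with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3)))
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} components; using the largest", stacklevel=2
        )
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    coords = np.argwhere(mask).astype(float)
    try:
        hull = ConvexHull(coords)
    except QhullError as exc:
        raise ValidationError(f"degenerate (line-like) mask: {exc}") from None
    hull_perimeter = float(hull.area)  # in 2-D, .area is the perimeter
    contour = extract_border(mask)
    lesion_perimeter = contour_perimeter(contour)
    if lesion_perimeter <= 0:
        raise ValidationError("lesion perimeter is zero")
    return hull_perimeter / lesion_perimeter


def extract_features(
    mask: np.ndarray, border: np.ndarray, source_id: str = ""
) -> IrregularityVector:
    """Assemble the irregularity vector for one lesion: fractal dimension
    from the border image, convexity from the segmentation mask."""
    return IrregularityVector(
        fractal_dimension=fractal_dimension(border),
        convexity=convexity(mask),
        source_id=source_id,
    )
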