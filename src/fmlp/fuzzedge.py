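"""Fuzzy border detection (FuzzEdge).

The filter derives three fuzzy gray-level concepts — Dark, Median, Bright —
from the image histogram.  The gray range [0, L-1] is cut into N_f equal
intervals (optionally overlapping); within each interval the histogram mode
becomes the concept center m and the distances to the interval ends the
spreads (alpha, beta) of a triangular membership function.

For every pixel, three membership-weighted standard deviations of its 3x3
neighborhood are computed (one per concept, deviations taken from the plain
neighborhood mean), together with a fuzzy estimator: the standard deviation
under a uniform interval membership over the occupied gray range, i.e. the
plain neighborhood standard deviation.  The filter output is the concept
deviation closest to the estimator, which is zero on flat regions and
positive across gray-level transitions — so thresholding the response
yields the lesion border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .exceptions import NoBorderError, ValidationError

__all__ = [
    "FuzzyConcept",
    "FuzzyConceptSet",
    "create_concepts",
    "membership",
    "fuzzedge_filter",
    "extract_border",
    "contour_perimeter",
]

CONCEPT_ORDER = ("Dark", "Median", "Bright")


@dataclass(frozen=True)
class FuzzyConcept:
    """One triangular fuzzy concept on the gray axis.

    Membership is 1 at the center m, falls linearly to 0 at m - alpha and
    m + beta, and is 0 outside [begin, end].
    """

    name: str
    begin: int
    end: int
    m: int
    alpha: int
    beta: int

    def membership(self, g) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        out = np.zeros_like(g)
        left = self.alpha if self.alpha > 0 else np.inf  # degenerate -> step at m
        right = self.beta if self.beta > 0 else np.inf
        rising = (g >= self.m - self.alpha) & (g < self.m)
        falling = (g > self.m) & (g <= self.m + self.beta)
        out[rising] = 1.0 - (self.m - g[rising]) / left
        out[falling] = 1.0 - (g[falling] - self.m) / right
        out[g == self.m] = 1.0
        return out


@dataclass(frozen=True)
class FuzzyConceptSet:
    """The Dark/Median/Bright concept triple for one image."""

    dark: FuzzyConcept
    median: FuzzyConcept
    bright: FuzzyConcept
    n_f: int
    L: int
    overlaps: tuple[int, int]

    def __iter__(self):
        return iter((self.dark, self.median, self.bright))


def membership(g, concept: FuzzyConcept) -> np.ndarray:
    """Degree of membership of gray level(s) g in a concept."""
    return concept.membership(g)


def _mode_in(hist: np.ndarray, begin: int, end: int, name: str) -> int:
    """Histogram mode within [begin, end]; interval midpoint if empty."""
    window = hist[begin : end + 1]
    if window.sum() == 0:
        warnings.warn(
            f"no pixels in the {name} interval [{begin}, {end}]; "
            "concept center set to the interval midpoint",
            stacklevel=3,
        )
        return (begin + end) // 2
    return begin + int(np.argmax(window))


def create_concepts(
    image: np.ndarray,
    n_f: int = 3,
    overlaps: tuple[int, int] = (0, 0),
    L: int = 256,
) -> FuzzyConceptSet:
    """Build the Dark/Median/Bright concepts from an image histogram.

    Interval bounds: Dark_end = floor((L-1)/N_f),
    Bright_begin = (N_f-1)*floor((L-1)/N_f), Median spans between them
    (widened by the overlap amounts).  Dark_begin / Bright_end shrink to
    the first / last occupied gray level.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValidationError("image must contain at least one pixel")
    if n_f != 3:
        raise ValidationError("the concept triple is defined for N_f = 3")
    left_overlap, right_overlap = overlaps
    gray = np.clip(np.rint(img).astype(int), 0, L - 1)
    hist = np.bincount(gray.ravel(), minlength=L).astype(float)
    hist /= hist.sum()

    step = (L - 1) // n_f
    dark_end = step
    bright_begin = (n_f - 1) * step
    median_begin = dark_end - left_overlap
    median_end = bright_begin + right_overlap

    occupied = np.nonzero(hist)[0]
    in_dark = occupied[occupied <= dark_end]
    dark_begin = int(in_dark[0]) if in_dark.size else 0
    in_bright = occupied[occupied >= bright_begin]
    bright_end = int(in_bright[-1]) if in_bright.size else L - 1

    concepts = []
    for name, begin, end in (
        ("Dark", dark_begin, dark_end),
        ("Median", median_begin, median_end),
        ("Bright", bright_begin, bright_end),
    ):
        m = _mode_in(hist, begin, end, name)
        concepts.append(
            FuzzyConcept(
                name=name, begin=begin, end=end, m=m, alpha=m - begin, beta=end - m
            )
        )
    dark, median_c, bright = concepts
    return FuzzyConceptSet(
        dark=dark,
        median=median_c,
        bright=bright,
        n_f=n_f,
        L=L,
        overlaps=(left_overlap, right_overlap),
    )


def fuzzedge_filter(
    image: np.ndarray, concepts: FuzzyConceptSet | None = None
) -> np.ndarray:
    """Run the fuzzy border filter over an image.

    Frame pixels are handled by edge replication.  For each pixel the
    three concept-weighted standard deviations of the 3x3 neighborhood
    are formed (deviations from the plain neighborhood mean, weighted by
    the concept membership of each neighbor); the output is the one
    nearest the fuzzy estimator (the plain neighborhood standard
    deviation), ties resolved in the order Dark < Median < Bright.
    Constant neighborhoods respond 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValidationError("image must be 2-D and at least 3x3")
    if concepts is None:
        concepts = create_concepts(img)

    padded = np.pad(img, 1, mode="edge")
    win = sliding_window_view(padded, (3, 3)).reshape(*img.shape, 9)

    mean = win.mean(axis=-1, keepdims=True)
    sq_dev = (win - mean) ** 2
    estimator = np.sqrt(sq_dev.mean(axis=-1))

    gray = np.clip(np.rint(win).astype(int), 0, concepts.L - 1)
    levels = np.arange(concepts.L)
    responses = []
    for concept in concepts:
        lut = concept.membership(levels)
        w = lut[gray]
        wsum = w.sum(axis=-1)
        num = (w * sq_dev).sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            resp = np.sqrt(np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1), 0.0))
        responses.append(resp)
    responses = np.stack(responses)  # Dark, Median, Bright

    nearest = np.argmin(np.abs(responses - estimator[None]), axis=0)
    return np.take_along_axis(responses, nearest[None], axis=0)[0]


# 8-neighborhood in clockwise order (image coordinates, row increases down)
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _moore_step(padded: np.ndarray, cur: tuple[int, int], backtrack: int):
    """One step of the Moore trace: scan the 8-neighborhood clockwise
    starting just after the backtrack direction; return the next boundary
    pixel and the new backtrack index, or None for an isolated pixel."""
    for k in range(1, 9):
        idx = (backtrack + k) % 8
        dr, dc = _MOORE[idx]
        nxt = (cur[0] + dr, cur[1] + dc)
        if padded[nxt]:
            prev_idx = (backtrack + k - 1) % 8
            pdr, pdc = _MOORE[prev_idx]
            # new backtrack = last background pixel scanned, relative to nxt
            rel = (cur[0] + pdr - nxt[0], cur[1] + pdc - nxt[1])
            return nxt, _MOORE.index(rel)
    return None


def _trace_moore(component: np.ndarray) -> np.ndarray:
    """Moore-neighbor boundary trace of a connected component.

    Starts at the topmost-then-leftmost foreground pixel and walks the
    outer boundary clockwise (in image coordinates); stops when the trace
    re-enters the start pixel and repeats its first move (Jacob's
    stopping criterion), so spurs visited twice are handled correctly.
    """
    rows, cols = np.nonzero(component)
    top = rows.min()
    start = (int(top) + 1, int(cols[rows == top].min()) + 1)  # +1: padding offset
    padded = np.pad(component, 1)

    contour = [start]
    backtrack = 6  # index of (0, -1): scanning begins pointing west
    cur = start
    first_move = None
    for _ in range(4 * int(component.sum()) + 8):
        step = _moore_step(padded, cur, backtrack)
        if step is None:  # isolated pixel
            break
        nxt, backtrack = step
        if first_move is None:
            first_move = (nxt, backtrack)
        elif cur == start and (nxt, backtrack) == first_move:
            break
        contour.append(nxt)
        cur = nxt
    if len(contour) > 1 and contour[-1] == contour[0]:
        contour.pop()
    return np.asarray(contour) - 1  # undo padding offset


def extract_border(mask_or_image: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Ordered closed contour of the largest border component.

    Works on boolean masks and on filter-response images (binarized with
    ``response > threshold``).  Returns an (n, 2) array of (row, col)
    pixel coordinates, starting at the topmost-then-leftmost boundary
    pixel, clockwise in image coordinates; closure (last -> first) is
    implied.
    """
    arr = np.asarray(mask_or_image)
    binary = arr if arr.dtype == bool else arr > threshold
    if not binary.any():
        raise NoBorderError("image contains no foreground")
    labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n_comp + 1))
    largest = int(np.argmax(sizes)) + 1
    component = labels == largest
    if component.sum() < 4:
        raise NoBorderError("largest component too small to form a closed border")
    contour = _trace_moore(component)
    if contour.shape[0] < 4:
        raise NoBorderError("no closed boundary could be traced")
    return contour


def contour_perimeter(contour: np.ndarray) -> float:
    """Arc length of a closed pixel contour: steps weighted 1 (axial) or
    sqrt(2) (diagonal), including the implicit last->first closure."""
    pts = np.asarray(contour, dtype=float)
    if pts.shape[0] < 2:
        raise ValidationError("contour needs at least 2 points")
    diffs = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
    if np.any(diffs > 1):
        # non-adjacent consecutive points: fall back to Euclidean steps
        return float(np.sum(np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)))
    steps = diffs.sum(axis=1)
    return float(np.sum(np.where(steps == 2, np.sqrt(2.0), steps)))
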