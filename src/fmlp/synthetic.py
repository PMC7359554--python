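"""Synthetic lesion masks and analytic test curves.

Real dermoscopy pipelines start from segmented lesion masks.  This module
generates stand-ins with known ground truth: smooth elliptical "regular"
lesions, star-convex "irregular" lesions whose boundary is perturbed by a
sum of random-phase radial sinusoids, and analytic curves (straight line,
Koch curve) whose box-counting dimension is known in closed form.  Every
generator is deterministic for a fixed seed so that downstream stages can
be tested end to end without external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .exceptions import InvalidSpecError, ValidationError

__all__ = [
    "ShapeSpec",
    "MaskDataset",
    "make_mask",
    "make_curve",
    "make_dataset",
    "augment",
    "AUGMENT_OPS",
    "write_dataset",
]

MASK_KINDS = ("regular", "irregular", "line", "koch", "square")

#: isometries used for augmentation; multiples of 90 degrees only, so no
#: interpolation is involved and foreground area is preserved exactly.
AUGMENT_OPS = ("rot90", "rot180", "rot270", "flip_h", "flip_v")


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic shape.

    roughness is the relative amplitude of the radial perturbation
    (0 = perfectly smooth); harmonics is the number of sinusoidal
    frequency components summed along the boundary.
    """

    kind: str
    image_side: int = 128
    base_radius: int = 30
    roughness: float = 0.0
    harmonics: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MASK_KINDS:
            raise InvalidSpecError(f"unknown shape kind {self.kind!r}")
        if self.image_side < 4 or self.base_radius < 1:
            raise InvalidSpecError("image_side and base_radius must be positive")
        if self.roughness < 0:
            raise InvalidSpecError("roughness must be >= 0")
        if self.kind == "regular" and self.roughness != 0:
            raise InvalidSpecError("regular shapes must have roughness 0")
        if self.kind == "irregular":
            if self.image_side < 4 * self.base_radius:
                raise InvalidSpecError(
                    "irregular shapes need image_side >= 4*base_radius "
                    "so the perturbed boundary cannot clip"
                )
            if self.roughness >= 1.0:
                raise InvalidSpecError(
                    "roughness >= 1 can drive the radius non-positive"
                )
            if self.harmonics < 1:
                raise InvalidSpecError("harmonics must be >= 1")


@dataclass
class MaskDataset:
    """A labeled collection of masks (regular = 1, irregular = 0)."""

    masks: list[np.ndarray]
    labels: np.ndarray
    ids: list[str]
    specs: list[ShapeSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.masks)


def _radial_profile(spec: ShapeSpec, rng: np.random.Generator):
    """Random radial perturbation s(theta) with max|s| = 1.

    Frequencies 2..harmonics+1 (frequency 1 would only shift the center);
    amplitudes fall off as 1/sqrt(k), a slow power-law decay that leaves
    substantial energy in the high harmonics.  The slow decay matters:
    it gives the boundary fine-scale raggedness (which raises the measured
    box-counting dimension) on top of the coarse indentations and
    protrusions (which lower convexity), mimicking how irregular lesion
    borders differ from smooth naevi in both measures at once.
    """
    freqs = np.arange(2, spec.harmonics + 2)
    amps = rng.uniform(0.3, 1.0, size=freqs.size) / np.sqrt(freqs)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)

    theta_dense = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    dense = np.sum(
        amps[:, None] * np.cos(freqs[:, None] * theta_dense[None, :] + phases[:, None]),
        axis=0,
    )
    scale = np.max(np.abs(dense))

    def s(theta: np.ndarray) -> np.ndarray:
        vals = np.sum(
            amps[:, None] * np.cos(freqs[:, None] * theta[None, :] + phases[:, None]),
            axis=0,
        )
        return vals / scale

    return s


def _fill_star_convex(spec: ShapeSpec, radius_fn) -> np.ndarray:
    n = spec.image_side
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r = radius_fn(theta.ravel()).reshape(theta.shape)
    if np.any(r <= 0):
        raise InvalidSpecError("perturbation drives the boundary radius non-positive")
    return dist <= r


def _check_lesion_mask(mask: np.ndarray) -> np.ndarray:
    """Enforce the lesion-mask invariants: one 4-connected component that
    does not touch the image frame."""
    if not mask.any():
        raise InvalidSpecError("generated mask is empty")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise InvalidSpecError("generated mask touches the image border")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n_comp = ndimage.label(mask, structure=structure)
    if n_comp != 1:
        raise InvalidSpecError(
            f"generated mask has {n_comp} 4-connected components, expected 1"
        )
    return mask


def make_mask(spec: ShapeSpec) -> np.ndarray:
    """Rasterize one shape to a boolean mask.

    regular   -> randomly oriented ellipse (convex, smooth boundary)
    irregular -> star-convex region r(theta) = R * (1 + roughness * s(theta))
    square    -> centered filled square with side 2*base_radius
    line/koch -> delegated to :func:`make_curve` at a default level
    """
    if spec.kind == "line":
        return make_curve("line", level=1, image_side=spec.image_side)
    if spec.kind == "koch":
        return make_curve("koch", level=4, image_side=spec.image_side)

    rng = np.random.default_rng(spec.seed)
    n, R = spec.image_side, spec.base_radius

    if spec.kind == "square":
        half = R
        lo = n // 2 - half
        hi = n // 2 + half
        if lo < 1 or hi > n - 1:
            raise InvalidSpecError("square does not fit inside the image frame")
        mask = np.zeros((n, n), dtype=bool)
        mask[lo:hi, lo:hi] = True
        return _check_lesion_mask(mask)

    if spec.kind == "regular":
        aspect = rng.uniform(0.75, 1.0)
        phi = rng.uniform(0, np.pi)
        a, b = R, R * aspect

        def radius_fn(theta: np.ndarray) -> np.ndarray:
            # polar radius of an ellipse with semi-axes (a, b) rotated by phi
            t = theta - phi
            return (a * b) / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)

        return _check_lesion_mask(_fill_star_convex(spec, radius_fn))

    # irregular
    s = _radial_profile(spec, rng)

    def radius_fn(theta: np.ndarray) -> np.ndarray:
        return R * (1.0 + spec.roughness * s(theta))

    return _check_lesion_mask(_fill_star_convex(spec, radius_fn))


def _koch_points(level: int) -> np.ndarray:
    """Vertices of the Koch curve on the unit segment (x in [0,1], y >= 0)."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    rot = np.array(
        [[np.cos(-np.pi / 3), -np.sin(-np.pi / 3)],
         [np.sin(-np.pi / 3), np.cos(-np.pi / 3)]]
    )
    for _ in range(level):
        out = [pts[0]]
        for p, q in zip(pts[:-1], pts[1:]):
            v = q - p
            a = p + v / 3.0
            c = p + 2.0 * v / 3.0
            b = a + rot @ (v / 3.0)
            out.extend([a, b, c, q])
        pts = np.asarray(out)
    pts[:, 1] *= -1  # bump points upward in mathematical coords; flipped below
    return pts


def _raster_polyline(points_rc: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polyline (row, col vertices) with Bresenham segments."""
    from skimage.draw import line as draw_line

    mask = np.zeros(shape, dtype=bool)
    rr_cc = np.rint(points_rc).astype(int)
    for (r0, c0), (r1, c1) in zip(rr_cc[:-1], rr_cc[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def make_curve(kind: str, level: int = 1, image_side: int = 64) -> np.ndarray:
    """Rasterize an analytic curve of known fractal dimension.

    line -> a 1-pixel-thick horizontal segment spanning the full width
    (box-counting dimension exactly 1); koch -> the Koch curve at the given
    recursion level (analytic dimension log 4 / log 3 ~ 1.262).
    """
    if kind == "line":
        mask = np.zeros((image_side, image_side), dtype=bool)
        mask[image_side // 2, :] = True
        return mask
    if kind != "koch":
        raise InvalidSpecError(f"unknown curve kind {kind!r}")
    if level < 1:
        raise InvalidSpecError("koch level must be >= 1")
    seg_len = (image_side - 1) / 3.0**level
    if seg_len < 1.0:
        raise InvalidSpecError(
            f"koch level {level} at side {image_side} yields segments shorter "
            "than one pixel"
        )
    pts = _koch_points(level)  # x in [0,1], y in [-h, 0]
    x = pts[:, 0] * (image_side - 1)
    # curve height is sqrt(3)/6 of the width; park the baseline low enough
    height = np.sqrt(3) / 6 * (image_side - 1)
    rows = pts[:, 1] * (image_side - 1) + min(
        image_side - 2, (image_side + height) / 2
    )
    points_rc = np.column_stack([rows, x])
    return _raster_polyline(points_rc, (image_side, image_side))


def augment(mask: np.ndarray, ops: Iterable[str]) -> list[np.ndarray]:
    """Apply a set of 90-degree rotations / flips; returns [original] + one
    mask per op, in canonical op order.  All ops are isometries of the pixel
    grid, so foreground area is preserved exactly."""
    ops = set(ops)
    unknown = ops - set(AUGMENT_OPS)
    if unknown:
        raise ValidationError(f"unknown augmentation ops: {sorted(unknown)}")
    if not np.asarray(mask).any():
        raise ValidationError("cannot augment an empty mask")
    transforms = {
        "rot90": lambda m: np.rot90(m, 1),
        "rot180": lambda m: np.rot90(m, 2),
        "rot270": lambda m: np.rot90(m, 3),
        "flip_h": np.fliplr,
        "flip_v": np.flipud,
    }
    out = [np.asarray(mask).copy()]
    for name in AUGMENT_OPS:
        if name in ops:
            out.append(transforms[name](mask).copy())
    return out


def make_dataset(
    n_regular: int,
    n_irregular: int,
    seed: int,
    *,
    image_side: int = 128,
    base_radius: int = 30,
    roughness: float = 0.4,
    harmonics: int = 24,
) -> MaskDataset:
    """Generate a labeled mask collection (regular = 1, irregular = 0).

    The default roughness of 0.4 produces clearly indented/protruded
    boundaries while keeping every shape star-convex and connected.
    """
    if n_regular < 1 or n_irregular < 1:
        raise ValidationError("both class counts must be >= 1")
    rng = np.random.default_rng(seed)
    masks: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    specs: list[ShapeSpec] = []
    for i in range(n_regular):
        spec = ShapeSpec(
            kind="regular",
            image_side=image_side,
            base_radius=base_radius,
            seed=int(rng.integers(2**31)),
        )
        masks.append(make_mask(spec))
        labels.append(1)
        ids.append(f"regular_{i:04d}")
        specs.append(spec)
    for i in range(n_irregular):
        spec = ShapeSpec(
            kind="irregular",
            image_side=image_side,
            base_radius=base_radius,
            roughness=roughness,
            harmonics=harmonics,
            seed=int(rng.integers(2**31)),
        )
        masks.append(make_mask(spec))
        labels.append(0)
        ids.append(f"irregular_{i:04d}")
        specs.append(spec)
    return MaskDataset(masks=masks, labels=np.asarray(labels), ids=ids, specs=specs)


def write_dataset(dataset: MaskDataset, out_dir: str | Path) -> Path:
    """Write masks as 8-bit PNGs (0 background / 255 foreground) and the
    labels as ``labels.csv`` with columns id,label."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mask, mask_id in zip(dataset.masks, dataset.ids):
        img = Image.fromarray((mask.astype(np.uint8)) * 255)
        img.save(out / f"{mask_id}.png")
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        for mask_id, label in zip(dataset.ids, dataset.labels):
            writer.writerow([mask_id, int(label)])
    return out
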