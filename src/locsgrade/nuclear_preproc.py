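"""Slit-beam preprocessing: bright-spot suppression, binarization and lens
localization by maximum inscribed white-ellipse search.

Slit-beam photographs show the optical cross-section of the lens as a bright,
roughly elliptical slab on a dark background, corrupted by saturated corneal
flash reflections and yellow peri-ocular skin spots.  The preprocessing chain
is:

1. blacken saturated bright spots (all three channels above a threshold),
2. grayscale + dynamic (Otsu) binarization,
3. coarse lens bounding box = tight box of the largest white component,
4. exact localization: the axis-aligned inscribed ellipse of maximal area
   that is *completely filled with white* pixels, searched over all candidate
   rectangles inside the coarse box,
5. slight expansion of that ellipse (the lens is not perfectly elliptical)
   and cropping of the lens region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .imgcore import (
    BinaryImage,
    GrayImage,
    NoLensFoundError,
    RgbImage,
    as_binary,
    as_gray,
    as_rgb,
)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box: (x, y) is the top-left corner (col, row)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError("bounding box must have w >= 1 and h >= 1")


@dataclass(frozen=True)
class EllipseRegion:
    """Axis-aligned ellipse in sub-pixel image coordinates.

    The inscribed ellipse of a :class:`BoundingBox` has its centre at
    ``(x + w/2 - 0.5, y + h/2 - 0.5)`` (pixel-centre convention) and
    semi-axes ``(w/2, h/2)``.
    """

    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float

    def __post_init__(self):
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("semi-axes must be positive")

    @classmethod
    def inscribed_in(cls, box: BoundingBox) -> "EllipseRegion":
        return cls(box.x + box.w / 2 - 0.5, box.y + box.h / 2 - 0.5,
                   box.w / 2, box.h / 2)

    @property
    def area(self) -> float:
        return math.pi * self.semi_axis_x * self.semi_axis_y

    def bounding_box(self) -> BoundingBox:
        """Smallest integer pixel box whose inscribed ellipse this is."""
        w = int(math.ceil(2 * self.semi_axis_x))
        h = int(math.ceil(2 * self.semi_axis_y))
        x = int(round(self.center_x - self.semi_axis_x + 0.5))
        y = int(round(self.center_y - self.semi_axis_y + 0.5))
        return BoundingBox(x, y, w, h)

    def contains(self, px, py) -> np.ndarray:
        """Strict interior test on pixel centres."""
        dx = (np.asarray(px, dtype=float) - self.center_x) / self.semi_axis_x
        dy = (np.asarray(py, dtype=float) - self.center_y) / self.semi_axis_y
        return dx * dx + dy * dy < 1.0


# ---------------------------------------------------------------------------
# bright-spot suppression & binarization
# ---------------------------------------------------------------------------

def suppress_bright_spots(img: RgbImage, threshold: int = 250) -> RgbImage:
    """Draw black dots over saturated bright areas.

    A pixel is blackened iff *all three* channels exceed ``threshold``
    (strictly: value >= threshold + 1).  All other pixels are unchanged.
    Idempotent: black pixels never satisfy the condition again.
    """
    img = as_rgb(img)
    out = img.copy()
    out[(img > threshold).all(axis=2)] = 0
    return out


def dynamic_threshold_binarize(gray: GrayImage, threshold=None) -> BinaryImage:
    """Binarize with a dynamic global threshold (Otsu's method).

    ``pixel > t`` maps to white (255), else black.  A constant image has a
    degenerate histogram and maps to all black.  ``threshold`` overrides the
    Otsu choice when given.
    """
    gray = as_gray(gray)
    if threshold is None:
        if gray.min() == gray.max():
            return np.zeros_like(gray)
        threshold = threshold_otsu(gray)
    return ((gray > threshold) * 255).astype(np.uint8)


def approximate_lens_bbox(binary: BinaryImage) -> BoundingBox:
    """Tight bounding box of the largest 8-connected white component.

    Ties in component area are broken toward the component whose first pixel
    in raster order comes first (scikit-image labels components in raster
    order, so the smallest label wins).
    """
    binary = as_binary(binary)
    labels = measure.label(binary > 0, connectivity=2)
    n = labels.max()
    if n == 0:
        raise NoLensFoundError("no lens candidate: image contains no white pixel")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1  # argmax returns first max -> raster tie-break
    rows, cols = np.nonzero(labels == best)
    return BoundingBox(int(cols.min()), int(rows.min()),
                       int(cols.max() - cols.min() + 1),
                       int(rows.max() - rows.min() + 1))


# ---------------------------------------------------------------------------
# maximum inscribed white ellipse
# ---------------------------------------------------------------------------

def _row_spans(w: int, h: int):
    """Strict-interior column spans of the inscribed ellipse of a w x h box.

    For each row offset ``dr`` in ``0..h-1`` returns ``(lo, cnt)``: interior
    pixel centres of that row are columns ``lo .. lo+cnt-1`` (relative to the
    box).  ``cnt`` may be 0 near the top/bottom of flat ellipses.
    """
    a, b = w / 2.0, h / 2.0
    rcx, rcy = a - 0.5, b - 0.5
    spans = []
    for dr in range(h):
        t = 1.0 - ((dr - rcy) / b) ** 2
        if t <= 0:
            spans.append((0, 0))
            continue
        half = a * math.sqrt(t)
        lo = int(math.floor(rcx - half)) + 1          # strict interior
        hi = int(math.ceil(rcx + half)) - 1
        lo = max(lo, 0)
        hi = min(hi, w - 1)
        spans.append((lo, max(hi - lo + 1, 0)))
    return spans


def _search_rects(white: np.ndarray, prefix: np.ndarray,
                  widths, heights, xstride: int, ystride: int):
    """Best all-white inscribed ellipse over the given size/position grid.

    ``prefix[r, c]`` is the count of white pixels in ``white[r, :c]``.
    Returns ``(w, h, x, y)`` of the winning rectangle or ``None``.  The
    winner maximizes ellipse area (== w*h up to the constant pi/4), with ties
    broken by larger semi-axis a (larger w), then smaller (y, x).
    """
    H, W = white.shape
    shapes = sorted(
        ((wi, hi) for wi in widths for hi in heights if wi <= W and hi <= H),
        key=lambda s: (-(s[0] * s[1]), -s[0]),
    )
    for wi, hi in shapes:
        ys = np.arange(0, H - hi + 1, ystride)
        xs = np.arange(0, W - wi + 1, xstride)
        ok = np.ones((len(ys), len(xs)), dtype=bool)
        for dr, (lo, cnt) in enumerate(_row_spans(wi, hi)):
            if cnt == 0:
                continue
            rows = prefix[ys + dr]
            counts = rows[:, xs + lo + cnt] - rows[:, xs + lo]
            ok &= counts == cnt
            if not ok.any():
                break
        else:
            iy, ix = np.argwhere(ok)[0]  # smallest (y, x) first
            return wi, hi, int(xs[ix]), int(ys[iy])
    return None


def max_inscribed_white_ellipse(binary: BinaryImage, bbox: BoundingBox,
                                stride: int = 2) -> EllipseRegion:
    """Largest axis-aligned ellipse completely filled with white pixels.

    Among all axis-aligned rectangles inside ``bbox``, finds the one whose
    inscribed ellipse has maximal area subject to every integer pixel centre
    strictly inside the ellipse being white.  Ties go to the larger
    horizontal semi-axis, then the smaller (y, x) rectangle corner.

    ``stride`` (>= 1) coarsens the enumeration over rectangle sizes and
    positions; a stride-1 hill-climbing refinement (window +- stride) around
    the incumbent follows.  The result at stride > 1 is near-optimal but may
    fall short of the true maximum on rare tie configurations; ``stride=1``
    is the exact exhaustive search.
    """
    binary = as_binary(binary)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sub = (binary[bbox.y:bbox.y + bbox.h, bbox.x:bbox.x + bbox.w] > 0)
    H, W = sub.shape
    prefix = np.zeros((H, W + 1), dtype=np.int32)
    np.cumsum(sub, axis=1, out=prefix[:, 1:])

    best = _search_rects(sub, prefix,
                         range(2, W + 1, stride), range(2, H + 1, stride),
                         stride, stride)
    if best is None and stride > 1:
        best = _search_rects(sub, prefix, range(2, W + 1), range(2, H + 1), 1, 1)
    if best is None:
        raise NoLensFoundError("no lens found: no all-white ellipse with "
                               "semi-axes >= 1 inside the candidate box")

    if stride > 1:
        # local refinement at stride 1 around the incumbent until stable
        while True:
            wi, hi, x, y = best
            ws = [w for w in range(wi - stride, wi + stride + 1) if 2 <= w <= W]
            hs = [h for h in range(hi - stride, hi + stride + 1) if 2 <= h <= H]
            cand = _search_rects(sub, prefix, ws, hs, 1, 1)
            if cand is None or cand == best:
                break
            cw, ch, _, _ = cand
            bw, bh, _, _ = best
            if (cw * ch, cw) <= (bw * bh, bw):
                break
            best = cand

    wi, hi, x, y = best
    return EllipseRegion.inscribed_in(BoundingBox(bbox.x + x, bbox.y + y, wi, hi))


def expand_ellipse(e: EllipseRegion, factor: float,
                   image_shape=None) -> EllipseRegion:
    """Fine-tune the ellipse size: scale both semi-axes by ``factor``.

    The centre is unchanged.  When ``image_shape = (H, W)`` is given, each
    semi-axis is clipped so the ellipse stays inside the pixel extent of the
    image (from -0.5 to size - 0.5 in each direction).
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    a = e.semi_axis_x * factor
    b = e.semi_axis_y * factor
    if image_shape is not None:
        h, w = image_shape[:2]
        a = min(a, e.center_x + 0.5, w - 0.5 - e.center_x)
        b = min(b, e.center_y + 0.5, h - 0.5 - e.center_y)
    return EllipseRegion(e.center_x, e.center_y, a, b)


def crop_lens(img: RgbImage, e: EllipseRegion):
    """Cut out the lens: bounding-box crop plus an interior mask.

    Returns ``(crop, mask)`` where ``crop`` is the ``ceil(2a) x ceil(2b)``
    bounding-box crop (clipped at image borders) with pixels outside the
    ellipse set to black, and ``mask`` is a binary image marking pixel
    centres strictly inside the ellipse.
    """
    img = as_rgb(img)
    H, W = img.shape[:2]
    box = e.bounding_box()
    x0, y0 = max(box.x, 0), max(box.y, 0)
    x1, y1 = min(box.x + box.w, W), min(box.y + box.h, H)
    crop = img[y0:y1, x0:x1].copy()
    rows, cols = np.mgrid[y0:y1, x0:x1]
    inside = e.contains(cols, rows)
    crop[~inside] = 0
    mask = (inside * 255).astype(np.uint8)
    return crop, mask
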