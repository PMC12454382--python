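"""Lesion-preserving binarization and feature extraction on retro images.

Opacities block the red fundus reflex, so cortical spokes and posterior
subcapsular plaques appear as *dark* structures on the bright pupil disc.
Binarization is therefore local (adaptive): a pixel inside the pupil circle
is lesion foreground iff its intensity falls below the local box mean by more
than a constant, which is robust to the smooth illumination gradient across
the three-dimensional eyeball.

Cortical cataract is summarized by probabilistic Hough line segments (radial
spokes) and posterior subcapsular cataract by external contour statistics of
the lesion components, both reduced to fixed-length, order-invariant
aggregate vectors for the grading network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import probabilistic_hough_line

from .imgcore import BinaryImage, FeatureVector, GrayImage, as_binary, as_gray
from .retro_preproc import CircleRegion


@dataclass(frozen=True)
class LineFeature:
    """One detected line segment, with its relation to the pupil circle."""

    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def length(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)

    @property
    def midpoint(self):
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def angle(self) -> float:
        """Orientation in degrees, folded into [0, 180)."""
        return math.degrees(math.atan2(self.y1 - self.y0,
                                       self.x1 - self.x0)) % 180.0

    def center_distance(self, circle: CircleRegion) -> float:
        """Perpendicular distance from the circle centre to the segment."""
        px, py = circle.center_x, circle.center_y
        vx, vy = self.x1 - self.x0, self.y1 - self.y0
        denom = vx * vx + vy * vy
        if denom == 0:
            return math.hypot(px - self.x0, py - self.y0)
        t = np.clip(((px - self.x0) * vx + (py - self.y0) * vy) / denom, 0.0, 1.0)
        return math.hypot(px - (self.x0 + t * vx), py - (self.y0 + t * vy))


@dataclass(frozen=True)
class ContourFeature:
    area_ratio: float        # lesion area / circle area
    perimeter_ratio: float   # lesion perimeter / circle perimeter
    centroid_offset: float   # centroid distance from centre, / radius

    def __post_init__(self):
        if not 0.0 <= self.area_ratio <= 1.0:
            raise ValueError("area_ratio must be in [0, 1]")


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def default_block(width: int) -> int:
    """Default adaptive block: image width / 8, rounded up to odd, >= 3."""
    b = max(3, int(round(width / 8)))
    return b if b % 2 == 1 else b + 1


def lesion_binarize(gray: GrayImage, circle: CircleRegion,
                    block: Optional[int] = None,
                    offset_c: float = 5.0,
                    fill_holes: bool = True) -> BinaryImage:
    """Adaptive binarization keeping dark opacities inside the pupil circle.

    Foreground iff ``intensity < local_mean(block) - offset_c`` and the pixel
    centre lies inside the circle; everything outside the circle is
    background.  ``block`` must be odd and >= 3.

    A lesion wider than the averaging block darkens its own neighbourhood, so
    the local rule keeps only its rim; ``fill_holes`` closes such hollow
    interiors so large plaques are recovered as filled regions.
    """
    gray = as_gray(gray)
    if block is None:
        block = default_block(gray.shape[1])
    if block < 3 or block % 2 == 0:
        raise ValueError(f"block must be odd and >= 3, got {block}")
    local_mean = ndimage.uniform_filter(gray.astype(np.float64), size=block,
                                        mode="reflect")
    fg = (gray.astype(np.float64) < local_mean - offset_c)
    fg &= circle.pixel_mask(gray.shape)
    if fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    return (fg * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cortical: Hough line aggregates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoughLineConfig:
    vote_threshold: int = 20
    min_length_frac: float = 0.2   # of the circle radius
    max_gap_frac: float = 0.05     # of the circle radius
    seed: int = 0


def detect_lines(binary: BinaryImage, circle: CircleRegion,
                 cfg: HoughLineConfig = HoughLineConfig()):
    """Probabilistic Hough line segments in the lesion binary image."""
    binary = as_binary(binary)
    min_len = max(3, int(round(cfg.min_length_frac * circle.radius)))
    max_gap = max(1, int(round(cfg.max_gap_frac * circle.radius)))
    segs = probabilistic_hough_line(binary > 0, threshold=cfg.vote_threshold,
                                    line_length=min_len, line_gap=max_gap,
                                    rng=cfg.seed)
    return [LineFeature(float(p0[0]), float(p0[1]), float(p1[0]), float(p1[1]))
            for p0, p1 in segs]


CORTICAL_FEATURE_NAMES = (
    "line_count", "total_length", "mean_length",
    "mean_center_distance", "min_center_distance", "foreground_fraction",
)


def cortical_line_features(binary: BinaryImage, circle: CircleRegion,
                           cfg: HoughLineConfig = HoughLineConfig()
                           ) -> FeatureVector:
    """Fixed-length aggregate of the detected spoke segments.

    Vector: [count, total length / r, mean length / r, mean centre-distance /
    r, min centre-distance / r, foreground fraction inside the circle].  An
    empty detection yields the zero vector.
    """
    lines = detect_lines(binary, circle, cfg)
    if not lines:
        return FeatureVector("cortical", (0.0,) * 6)
    r = circle.radius
    lengths = np.array([ln.length for ln in lines])
    dists = np.array([ln.center_distance(circle) for ln in lines])
    inside = circle.pixel_mask(binary.shape)
    fg_frac = float((binary[inside] > 0).mean()) if inside.any() else 0.0
    return FeatureVector("cortical", (
        float(len(lines)),
        float(lengths.sum() / r),
        float(lengths.mean() / r),
        float(dists.mean() / r),
        float(dists.min() / r),
        fg_frac,
    ))


# ---------------------------------------------------------------------------
# posterior: contour aggregates
# ---------------------------------------------------------------------------

POSTERIOR_FEATURE_NAMES = (
    "area_ratio", "perimeter_ratio", "centroid_offset", "contour_count",
)


def posterior_contour_features(binary: BinaryImage, circle: CircleRegion,
                               min_area: int = 8) -> FeatureVector:
    """Fixed-length aggregate of the lesion component contours.

    Vector: [sum(area) / circle area, sum(perimeter) / circle perimeter,
    area-weighted centroid offset / radius, contour count].  Components
    smaller than ``min_area`` pixels are treated as noise.  No contour yields
    [0, 0, 0, 0].
    """
    binary = as_binary(binary)
    labels = measure.label(binary > 0, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    if not props:
        return FeatureVector("posterior", (0.0, 0.0, 0.0, 0.0))
    areas = np.array([p.area for p in props], dtype=float)
    perims = np.array([p.perimeter_crofton for p in props], dtype=float)
    cents = np.array([p.centroid for p in props], dtype=float)  # (row, col)
    weighted = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    offset = math.hypot(weighted[1] - circle.center_x,
                        weighted[0] - circle.center_y)
    r = circle.radius
    return FeatureVector("posterior", (
        float(min(areas.sum() / (math.pi * r * r), 1.0)),
        float(perims.sum() / (2 * math.pi * r)),
        float(offset / r),
        float(len(props)),
    ))
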