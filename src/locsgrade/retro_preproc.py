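"""Retro-illumination preprocessing: minimum-circumcircle segmentation,
flash-highlight filling by 3-way colour clustering, and Hough-circle pupil
localization.

Retro-illumination photographs show the pupil as an orange-red disc (the red
fundus reflex) on a dark background.  Flash highlights saturate small patches
and an illumination gradient shades the disc, so pupil localization proceeds
coarse-to-fine:

1. coarse foreground (Otsu on grayscale, largest component) and its minimum
   enclosing circle,
2. flash-highlight detection inside that circle and filling: the circle's
   pixels are clustered into three colour categories (yellow/orange, white,
   black) by greedy agglomerative merging of the closest cluster-mean pair,
   and highlight pixels are painted with the mean colour of the yellow
   cluster,
3. precise localization with a circular Hough transform on a fixed-threshold
   edge map of the filled image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import shapely
from scipy import ndimage
from skimage.transform import hough_circle as _sk_hough_circle
from skimage.transform import hough_circle_peaks

from .imgcore import (
    BinaryImage,
    GrayImage,
    NoCircleFoundError,
    RgbImage,
    as_binary,
    as_gray,
    as_rgb,
    to_gray,
)
from .nuclear_preproc import approximate_lens_bbox, dynamic_threshold_binarize

logger = logging.getLogger("locsgrade")


@dataclass(frozen=True)
class CircleRegion:
    """Circle in sub-pixel image coordinates (x = col, y = row)."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be non-negative")

    def pixel_mask(self, shape) -> np.ndarray:
        h, w = shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        return ((xx - self.center_x) ** 2 + (yy - self.center_y) ** 2
                <= self.radius ** 2)


def min_enclosing_circle(points_or_binary) -> CircleRegion:
    """Smallest circle containing all foreground pixel centres / points.

    Accepts either an (n, 2) array of (x, y) points or a binary image whose
    white pixel centres are taken as points.  The minimum enclosing circle is
    unique; every input point lies within ``radius + 1e-6``.
    """
    arr = np.asarray(points_or_binary)
    if arr.ndim == 2 and not (arr.shape[1] == 2 and arr.dtype.kind == "f"):
        if set(np.unique(arr)) <= {0, 255}:
            rows, cols = np.nonzero(arr)
            pts = np.column_stack([cols, rows]).astype(float)
        else:
            pts = arr.astype(float)
    else:
        pts = arr.astype(float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("need at least one foreground point")
    mp = shapely.MultiPoint(pts)
    radius = float(shapely.minimum_bounding_radius(mp))
    if radius == 0.0:
        cx, cy = pts[0]
        return CircleRegion(float(cx), float(cy), 0.0)
    center = shapely.minimum_bounding_circle(mp).centroid
    return CircleRegion(float(center.x), float(center.y), radius)


# ---------------------------------------------------------------------------
# bright spots
# ---------------------------------------------------------------------------

def detect_bright_spots(img: RgbImage, region: CircleRegion,
                        threshold: int = 240) -> BinaryImage:
    """Mask of flash highlights: saturated pixels inside the circle.

    A pixel is a highlight candidate iff ``min(R, G, B) > threshold``; the
    candidate set is dilated by one pixel to catch the halo ring and
    intersected back with the circular region.
    """
    img = as_rgb(img)
    inside = region.pixel_mask(img.shape)
    cand = (img.min(axis=2) > threshold) & inside
    grown = ndimage.binary_dilation(cand, structure=np.ones((3, 3), bool))
    return ((grown & inside) * 255).astype(np.uint8)


class ClusterState:
    """Greedy agglomerative clustering of sampled RGB colours.

    Every sampled pixel starts as its own cluster; the pair of clusters whose
    mean colours are closest (Euclidean distance in RGB space) is repeatedly
    merged into one cluster at their member-weighted mean, until exactly
    ``n_clusters`` remain.  ``merged_flags`` records which cluster slots have
    been absorbed and ``categories`` the final cluster id per sample.
    """

    def __init__(self, colors: np.ndarray, n_clusters: int = 3):
        colors = np.asarray(colors, dtype=float)
        if colors.ndim != 2 or colors.shape[1] != 3:
            raise ValueError("colors must be an (n, 3) array")
        self.n_clusters = n_clusters
        # identical colours merge first at distance 0 and leave every centroid
        # unchanged, so collapsing duplicates up front is behaviour-equivalent
        uniq, inv, counts = np.unique(colors, axis=0, return_inverse=True,
                                      return_counts=True)
        self._sample_to_start = inv
        self._fit(uniq, counts.astype(float))

    def _fit(self, colors: np.ndarray, counts: np.ndarray) -> None:
        n = len(colors)
        centers = colors.copy()
        sizes = counts.copy()
        parent = np.arange(n)
        active = np.ones(n, dtype=bool)
        # cached nearest neighbour per active cluster
        nn_dist = np.full(n, np.inf)
        nn_idx = np.full(n, -1)

        def recompute_nn(i):
            others = active.copy()
            others[i] = False
            if not others.any():
                nn_dist[i], nn_idx[i] = np.inf, -1
                return
            idx = np.nonzero(others)[0]
            d = np.linalg.norm(centers[idx] - centers[i], axis=1)
            k = int(np.argmin(d))
            nn_dist[i], nn_idx[i] = d[k], idx[k]

        for i in range(n):
            recompute_nn(i)

        k = n
        while k > self.n_clusters:
            i = int(np.argmin(np.where(active, nn_dist, np.inf)))
            j = int(nn_idx[i])
            # merge j into i at the member-weighted mean
            w = sizes[i] + sizes[j]
            centers[i] = (sizes[i] * centers[i] + sizes[j] * centers[j]) / w
            sizes[i] = w
            active[j] = False
            parent[j] = i
            k -= 1
            recompute_nn(i)
            stale = active & ((nn_idx == i) | (nn_idx == j))
            stale[i] = False
            for s in np.nonzero(stale)[0]:
                recompute_nn(s)

        # path-compress sample assignments to surviving cluster slots
        roots = parent.copy()
        changed = True
        while changed:
            nxt = roots[roots]
            changed = bool((nxt != roots).any())
            roots = nxt
        self.merged_flags = ~active
        live = np.nonzero(active)[0]
        remap = {int(r): c for c, r in enumerate(live)}
        start_cat = np.array([remap[int(r)] for r in roots])
        self.categories = start_cat[self._sample_to_start]
        self.cluster_means = centers[live]
        self.cluster_sizes = sizes[live]

    def yellow_cluster(self, score=None) -> int:
        """Index of the yellow category: maximal (R + G)/2 - B by default."""
        if score is None:
            score = lambda m: (m[0] + m[1]) / 2.0 - m[2]
        return int(np.argmax([score(m) for m in self.cluster_means]))

    @property
    def yellow_mean(self) -> np.ndarray:
        return self.cluster_means[self.yellow_cluster()]


def cluster_fill_bright_spots(img: RgbImage, region: CircleRegion,
                              mask: BinaryImage, sample_n: int = 2000,
                              seed: int = 0) -> RgbImage:
    """Fill highlight pixels with the mean colour of the yellow cluster.

    All pixels inside the circular region (bright spots included — they form
    the white category) are sampled uniformly (seeded, up to ``sample_n``)
    and agglomeratively clustered into the three colour categories; every
    mask pixel is then assigned the rounded mean RGB of the yellow cluster.
    Pixels outside the mask are never modified.

    Degenerate case: with fewer than three distinct sampled colours no
    3-way clustering exists and the fill falls back to the mean of the
    unmasked pixels inside the region (logged).
    """
    img = as_rgb(img)
    mask = as_binary(mask)
    out = img.copy()
    if not (mask > 0).any():
        return out
    inside = region.pixel_mask(img.shape)
    donors = img[inside].astype(float)
    if donors.shape[0] == 0:
        return out
    if donors.shape[0] > sample_n:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(donors.shape[0], size=sample_n, replace=False))
        donors = donors[pick]
    if np.unique(donors, axis=0).shape[0] < 3:
        logger.warning("cluster fill: fewer than 3 distinct sampled colours; "
                       "falling back to the mean of the unmasked region")
        surround = img[inside & (mask == 0)].astype(float)
        if surround.shape[0] == 0:
            surround = donors
        fill = np.clip(np.floor(surround.mean(axis=0) + 0.5), 0, 255)
    else:
        state = ClusterState(donors, n_clusters=3)
        fill = np.clip(np.floor(state.yellow_mean + 0.5), 0, 255)
    out[mask > 0] = fill.astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Hough circle
# ---------------------------------------------------------------------------

def _edge_map(gray: GrayImage, threshold: Optional[int]) -> np.ndarray:
    """Fixed-threshold edge map: boundary of the thresholded foreground."""
    binary = dynamic_threshold_binarize(gray, threshold=threshold) > 0
    eroded = ndimage.binary_erosion(binary, structure=np.ones((3, 3), bool))
    return binary & ~eroded


def hough_circle(gray: GrayImage, radius_range: Tuple[int, int],
                 edge_threshold: Optional[int] = None,
                 min_vote_frac: float = 0.25) -> CircleRegion:
    """Highest-accumulator circle over a fixed-threshold edge map.

    ``radius_range = (r_min, r_max)`` in pixels.  The normalized accumulator
    peak must reach ``min_vote_frac`` (fraction of the circle perimeter
    voting), otherwise no circle is reported.
    """
    gray = as_gray(gray)
    r0, r1 = int(radius_range[0]), int(radius_range[1])
    diag = math.hypot(*gray.shape)
    if not 1 <= r0 <= r1 <= diag:
        raise ValueError("radius_range must lie within the image diagonal")
    edges = _edge_map(gray, edge_threshold)
    if not edges.any():
        raise NoCircleFoundError("no circle: empty edge map")
    radii = np.arange(r0, r1 + 1)
    accum = _sk_hough_circle(edges, radii, normalize=True)
    accums, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] < min_vote_frac:
        raise NoCircleFoundError(
            f"no circle: best accumulator peak "
            f"{accums[0] if len(accums) else 0.0:.3f} below {min_vote_frac}")
    return CircleRegion(float(cx[0]), float(cy[0]), float(rad[0]))


# ---------------------------------------------------------------------------
# composed segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetroPreprocConfig:
    spot_threshold: int = 240
    sample_n: int = 2000
    seed: int = 0
    edge_threshold: Optional[int] = None   # None -> Otsu
    min_vote_frac: float = 0.25
    radius_frac: Tuple[float, float] = (0.55, 1.15)  # of the coarse radius


@dataclass(frozen=True)
class RetroSegmentation:
    crop: RgbImage                 # filled image cropped to the circle's box
    circle: CircleRegion           # in crop coordinates
    circle_global: CircleRegion    # in original image coordinates
    filled: RgbImage               # full-frame filled image
    bright_mask: BinaryImage


def segment_eyeball(img: RgbImage,
                    cfg: RetroPreprocConfig = RetroPreprocConfig()
                    ) -> RetroSegmentation:
    """Coarse circle -> highlight fill -> precise Hough circle -> crop."""
    img = as_rgb(img)
    gray = to_gray(img)
    binary = dynamic_threshold_binarize(gray)
    box = approximate_lens_bbox(binary)  # largest bright component
    comp = np.zeros_like(binary)
    comp[box.y:box.y + box.h, box.x:box.x + box.w] = \
        binary[box.y:box.y + box.h, box.x:box.x + box.w]
    coarse = min_enclosing_circle(comp)

    spots = detect_bright_spots(img, coarse, threshold=cfg.spot_threshold)
    filled = cluster_fill_bright_spots(img, coarse, spots,
                                       sample_n=cfg.sample_n, seed=cfg.seed)

    r0 = max(2, int(math.floor(cfg.radius_frac[0] * coarse.radius)))
    r1 = max(r0, int(math.ceil(cfg.radius_frac[1] * coarse.radius)))
    diag = math.hypot(*gray.shape)
    circle = hough_circle(to_gray(filled), (r0, min(r1, int(diag) - 1)),
                          edge_threshold=cfg.edge_threshold,
                          min_vote_frac=cfg.min_vote_frac)

    H, W = img.shape[:2]
    x0 = max(int(math.floor(circle.center_x - circle.radius)), 0)
    y0 = max(int(math.floor(circle.center_y - circle.radius)), 0)
    x1 = min(int(math.ceil(circle.center_x + circle.radius)) + 1, W)
    y1 = min(int(math.ceil(circle.center_y + circle.radius)) + 1, H)
    crop = filled[y0:y1, x0:x1].copy()
    local = CircleRegion(circle.center_x - x0, circle.center_y - y0,
                         circle.radius)
    return RetroSegmentation(crop, local, circle, filled, spots)
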