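"""Independent brute-force oracles used to validate the implementation.

Each oracle re-derives the quantity from its definition (exhaustive
enumeration, per-pixel scans, closed forms) without sharing code with the
package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.distance import cdist


# ---------------------------------------------------------------------------
# maximum inscribed white ellipse: exhaustive enumeration of all rectangles
# ---------------------------------------------------------------------------

def max_ellipse_oracle(mask: np.ndarray):
    """Exhaustive search over every rectangle at stride 1.

    ``mask`` is boolean.  Returns ``(w, h)`` of the best rectangle (maximal
    ellipse area = pi/4 * w * h) or ``None`` when no all-white ellipse with
    both semi-axes >= 1 exists.  Only the area is authoritative (ties are
    arbitrary here).
    """
    H, W = mask.shape
    best = None
    for w in range(2, W + 1):
        for h in range(2, H + 1):
            if best is not None and w * h <= best[0] * best[1]:
                continue
            a, b = w / 2.0, h / 2.0
            cx, cy = a - 0.5, b - 0.5
            offs = [(dr, dc)
                    for dr in range(h) for dc in range(w)
                    if ((dc - cx) / a) ** 2 + ((dr - cy) / b) ** 2 < 1.0]
            rows = np.array([o[0] for o in offs])
            cols = np.array([o[1] for o in offs])
            for y in range(H - h + 1):
                found = False
                for x in range(W - w + 1):
                    if mask[rows + y, cols + x].all():
                        best = (w, h)
                        found = True
                        break
                if found:
                    break
    return best


# ---------------------------------------------------------------------------
# largest connected component bounding box by flood fill
# ---------------------------------------------------------------------------

def largest_component_bbox_oracle(mask: np.ndarray):
    """8-connected flood fill; returns (x, y, w, h) of the largest component."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    best = None
    for r0 in range(H):
        for c0 in range(W):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            pix = []
            while stack:
                r, c = stack.pop()
                pix.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < H and 0 <= cc < W and mask[rr, cc]
                                and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if best is None or len(pix) > len(best):
                best = pix
    rows = [p[0] for p in best]
    cols = [p[1] for p in best]
    return (min(cols), min(rows),
            max(cols) - min(cols) + 1, max(rows) - min(rows) + 1)


# ---------------------------------------------------------------------------
# minimum enclosing circle: O(n^3) over all pairs and triples
# ---------------------------------------------------------------------------

def _circumcircle(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    return ux, uy, math.hypot(ax - ux, ay - uy)


def min_circle_oracle(points: np.ndarray):
    """Smallest circle over all pair-diameter and triple-circumscribed
    candidates that contain every point.  Returns (cx, cy, r)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    cands = []
    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2.0
        cands.append((c[0], c[1], np.linalg.norm(pts[i] - pts[j]) / 2.0))
    for i, j, k in itertools.combinations(range(n), 3):
        cc = _circumcircle(pts[i], pts[j], pts[k])
        if cc is not None:
            cands.append(cc)
    if not cands:  # single point
        return float(pts[0, 0]), float(pts[0, 1]), 0.0
    centers = np.array([(c[0], c[1]) for c in cands])
    radii = np.array([c[2] for c in cands])
    d = cdist(centers, pts)
    valid = (d <= radii[:, None] + 1e-9).all(axis=1)
    idx = np.nonzero(valid)[0]
    best = idx[np.argmin(radii[idx])]
    return float(centers[best, 0]), float(centers[best, 1]), float(radii[best])


# ---------------------------------------------------------------------------
# greedy 3-cluster agglomeration, naive full-recompute version
# ---------------------------------------------------------------------------

def agglomerate3_oracle(colors: np.ndarray):
    """Merge the closest centroid pair (full pairwise recompute every step)
    until three clusters remain.  Returns (means, sizes) lists."""
    clusters = [(np.asarray(c, dtype=float), 1) for c in colors]
    # collapse exact duplicates first (distance-0 merges, order-free)
    uniq = {}
    for c, _ in clusters:
        key = tuple(c)
        uniq[key] = uniq.get(key, 0) + 1
    clusters = [(np.array(k), n) for k, n in sorted(uniq.items())]
    while len(clusters) > 3:
        means = np.array([c[0] for c in clusters])
        d = cdist(means, means)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if i > j:
            i, j = j, i
        (mi, ni), (mj, nj) = clusters[i], clusters[j]
        merged = ((mi * ni + mj * nj) / (ni + nj), ni + nj)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return ([c[0] for c in clusters], [c[1] for c in clusters])


def yellow_mean_oracle(colors: np.ndarray):
    """Rounded mean of the yellowest cluster ((R+G)/2 - B score)."""
    means, _ = agglomerate3_oracle(colors)
    scores = [(m[0] + m[1]) / 2.0 - m[2] for m in means]
    m = means[int(np.argmax(scores))]
    return np.floor(m + 0.5)


# ---------------------------------------------------------------------------
# misc pixel-level oracles
# ---------------------------------------------------------------------------

def bright_pixel_count_oracle(img: np.ndarray, threshold: int) -> int:
    """Per-pixel scan: all three channels strictly above threshold."""
    n = 0
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            rgb = img[r, c]
            if rgb[0] > threshold and rgb[1] > threshold and rgb[2] > threshold:
                n += 1
    return n


def color_proportion_oracle(img, mask, standard, offset) -> float:
    """Per-pixel scan with explicit inequalities, inclusive endpoints."""
    hits = total = 0
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if mask[r, c] == 0:
                continue
            total += 1
            ok = all(standard[k] - offset <= int(img[r, c, k])
                     <= standard[k] + offset for k in range(3))
            hits += ok
    return hits / total


def box_mean_oracle(gray: np.ndarray, block: int) -> np.ndarray:
    """Direct local box mean with edge-reflected borders.

    numpy's ``symmetric`` padding duplicates the edge sample, matching the
    border convention used by the implementation.
    """
    pad = block // 2
    padded = np.pad(gray.astype(float), pad, mode="symmetric")
    out = np.empty_like(gray, dtype=float)
    for r in range(gray.shape[0]):
        for c in range(gray.shape[1]):
            out[r, c] = padded[r:r + block, c:c + block].mean()
    return out


def ellipse_interior_count_oracle(shape, cx, cy, a, b) -> int:
    """Integer pixel centres strictly inside the ellipse."""
    n = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            if ((c - cx) / a) ** 2 + ((r - cy) / b) ** 2 < 1.0:
                n += 1
    return n
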