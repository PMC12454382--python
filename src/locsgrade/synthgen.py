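"""Grade-controlled synthetic slit-beam and retro-illumination images.

Clinical anterior-segment photograph collections are rarely shareable, so
this module renders the two modalities with known ground truth and serves as
the package's test fixture and desk-scale benchmark:

* **Slit-beam** (nuclear branch): a bright, roughly elliptical lens slice on
  a dark background.  The NO grade drives the fraction of lens pixels tinted
  cyan and the NC grade the fraction tinted yellow, both linearly in grade
  (the simplest monotone map).  Saturated white corneal reflections (all
  channels >= 252) and small yellow peri-ocular skin spots corrupt the frame.
* **Retro-illumination** (cortical/posterior branch): a circular orange-red
  pupil (red fundus reflex) on a dark background with a multiplicative
  illumination gradient.  The C grade drives the number and length of dark
  radial spokes, the P grade the area of a dark central plaque; flash
  highlights and Gaussian pixel noise are added.

Every image is deterministic given its spec (including the seed), and each
generated image carries a sidecar ground-truth record (lens ellipse or pupil
circle, spoke angles, plaque mask) so detection accuracy can be scored
exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .grader import GRADE_RANGES, GradeLabel
from .imgcore import RgbImage, write_image

# linear grade -> target signal maps (fraction at the maximal grade)
MAX_CYAN_FRACTION = 0.8     # NO6: 80% of lens pixels cyan-tinted
MAX_YELLOW_FRACTION = 0.8   # NC6
SPOKES_PER_GRADE = 2        # C grade g -> 2*g spokes
PLAQUE_AREA_PER_GRADE = 0.03  # P grade g -> plaque covers 3g% of the pupil


@dataclass(frozen=True)
class SlitBeamSpec:
    """Rendering parameters of one slit-beam image."""

    no_grade: int = 0
    nc_grade: int = 0
    height: int = 112
    width: int = 144
    lens_center: Tuple[float, float] = (72.0, 56.0)   # (x, y)
    lens_axes: Tuple[float, float] = (40.0, 28.0)     # (semi_x, semi_y)
    white_spot_count: int = 2
    white_spot_radius: int = 3
    yellow_spot_count: int = 2
    yellow_spot_radius: int = 3
    grade_jitter_sd: float = 0.025   # sd of the target-fraction jitter
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for t, g in (("NO", self.no_grade), ("NC", self.nc_grade)):
            lo, hi = GRADE_RANGES[t]
            if not lo <= g <= hi:
                raise ValueError(f"{t} grade {g} outside [{lo}, {hi}]")

    def target_cyan(self) -> float:
        return MAX_CYAN_FRACTION * self.no_grade / GRADE_RANGES["NO"][1]

    def target_yellow(self) -> float:
        return MAX_YELLOW_FRACTION * self.nc_grade / GRADE_RANGES["NC"][1]


@dataclass(frozen=True)
class RetroSpec:
    """Rendering parameters of one retro-illumination image."""

    c_grade: int = 0
    p_grade: int = 0
    size: int = 160
    pupil_center: Tuple[float, float] = (80.0, 80.0)
    pupil_radius: float = 52.0
    center_jitter: float = 4.0
    radius_jitter: float = 3.0
    gradient_amplitude: float = 0.15
    flash_spot_count: int = 2
    flash_spot_radius: int = 3
    spoke_width: float = 3.0
    plaque_area_jitter: float = 0.10   # relative sd of the plaque area
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for t, g in (("C", self.c_grade), ("P", self.p_grade)):
            lo, hi = GRADE_RANGES[t]
            if not lo <= g <= hi:
                raise ValueError(f"{t} grade {g} outside [{lo}, {hi}]")

    def spoke_count(self) -> int:
        return SPOKES_PER_GRADE * self.c_grade

    def target_plaque_fraction(self) -> float:
        return PLAQUE_AREA_PER_GRADE * self.p_grade


def _disc(shape, cx, cy, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


# ---------------------------------------------------------------------------
# slit-beam rendering
# ---------------------------------------------------------------------------

def gen_slit_beam(spec: SlitBeamSpec):
    """Render one slit-beam image.

    Returns ``(image, no_label, nc_label, truth)`` where ``truth`` records
    the rendered lens ellipse and realized colour fractions.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.clip(rng.normal(12.0, 4.0, (h, w, 1)) +
                  rng.normal(0.0, 2.0, (h, w, 3)), 0, 255)

    cx, cy = spec.lens_center
    ax, ay = spec.lens_axes
    yy, xx = np.mgrid[0:h, 0:w]
    lens = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    n_lens = int(lens.sum())

    p_cyan = float(np.clip(spec.target_cyan() +
                           rng.normal(0.0, spec.grade_jitter_sd), 0.0, 0.95))
    p_yellow = float(np.clip(spec.target_yellow() +
                             rng.normal(0.0, spec.grade_jitter_sd), 0.0,
                             0.95 - p_cyan))
    u = rng.random(n_lens)
    colors = np.empty((n_lens, 3))
    cyan_sel = u < p_cyan
    yellow_sel = (~cyan_sel) & (u < p_cyan + p_yellow)
    neutral_sel = ~(cyan_sel | yellow_sel)
    colors[cyan_sel] = rng.normal([20.0, 235.0, 235.0], [10.0, 8.0, 8.0],
                                  (int(cyan_sel.sum()), 3))
    colors[yellow_sel] = rng.normal([235.0, 235.0, 20.0], [8.0, 8.0, 10.0],
                                    (int(yellow_sel.sum()), 3))
    colors[neutral_sel] = (rng.normal(150.0, 12.0, (int(neutral_sel.sum()), 1))
                           + rng.normal(0.0, 4.0, (int(neutral_sel.sum()), 3)))
    img[lens] = np.clip(colors, 0, 255)

    # peri-ocular yellow skin spots, outside the lens, near the frame corners
    for _ in range(spec.yellow_spot_count):
        for _try in range(20):
            sx = rng.uniform(spec.yellow_spot_radius,
                             w - spec.yellow_spot_radius)
            sy = rng.uniform(spec.yellow_spot_radius,
                             h - spec.yellow_spot_radius)
            if (((sx - cx) / ax) ** 2 + ((sy - cy) / ay) ** 2
                    > (1.35) ** 2):
                break
        spot = _disc((h, w), sx, sy, spec.yellow_spot_radius)
        img[spot] = rng.normal([210.0, 185.0, 60.0], 6.0,
                               (int(spot.sum()), 3))

    # saturated corneal reflections: all channels >= 252, rendered last
    for _ in range(spec.white_spot_count):
        for _try in range(20):
            sx = rng.uniform(spec.white_spot_radius, w - spec.white_spot_radius)
            sy = rng.uniform(spec.white_spot_radius, h - spec.white_spot_radius)
            if (((sx - cx) / ax) ** 2 + ((sy - cy) / ay) ** 2
                    > (1.35) ** 2):
                break
        spot = _disc((h, w), sx, sy, spec.white_spot_radius)
        img[spot] = rng.integers(252, 256, (int(spot.sum()), 3))

    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    truth = {
        "lens_center_x": cx, "lens_center_y": cy,
        "lens_semi_x": ax, "lens_semi_y": ay,
        "p_cyan": p_cyan, "p_yellow": p_yellow,
    }
    return (img, GradeLabel("NO", spec.no_grade),
            GradeLabel("NC", spec.nc_grade), truth)


# ---------------------------------------------------------------------------
# retro-illumination rendering
# ---------------------------------------------------------------------------

def gen_retro(spec: RetroSpec):
    """Render one retro-illumination image.

    Returns ``(image, c_label, p_label, truth)``; ``truth`` records the
    rendered pupil circle, spoke angles, and the spoke/plaque ground-truth
    masks (as pixel counts plus boolean arrays).
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    cx = spec.pupil_center[0] + rng.uniform(-spec.center_jitter,
                                            spec.center_jitter)
    cy = spec.pupil_center[1] + rng.uniform(-spec.center_jitter,
                                            spec.center_jitter)
    R = spec.pupil_radius + rng.uniform(-spec.radius_jitter,
                                        spec.radius_jitter)

    img = np.clip(rng.normal(8.0, 3.0, (s, s, 1)) +
                  rng.normal(0.0, 1.5, (s, s, 3)), 0, 255)
    yy, xx = np.mgrid[0:s, 0:s]
    pupil = (xx - cx) ** 2 + (yy - cy) ** 2 <= R * R

    theta = rng.uniform(0, 2 * math.pi)
    proj = ((xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)) / R
    shade = 1.0 + spec.gradient_amplitude * proj
    base = np.array([205.0, 120.0, 55.0])
    fill = base[None, :] * shade[pupil][:, None]
    fill += rng.normal(0.0, 3.0, fill.shape)
    img[pupil] = np.clip(fill, 0, 255)

    # cortical spokes: dark radial wedges from the mid-zone outward
    n_spokes = spec.spoke_count()
    spoke_angles: List[float] = []
    spoke_mask = np.zeros((s, s), dtype=bool)
    if n_spokes:
        base_ang = rng.uniform(0, 2 * math.pi)
        length_frac = 0.55 + 0.07 * spec.c_grade
        for k in range(n_spokes):
            ang = base_ang + 2 * math.pi * k / n_spokes \
                + rng.normal(0.0, math.radians(3.0))
            spoke_angles.append(math.degrees(ang) % 360.0)
            r0 = (0.25 + rng.normal(0.0, 0.02)) * R
            r1 = (length_frac + rng.normal(0.0, 0.03)) * R
            x0, y0 = cx + r0 * math.cos(ang), cy + r0 * math.sin(ang)
            x1, y1 = cx + r1 * math.cos(ang), cy + r1 * math.sin(ang)
            # distance of each pixel to the segment
            vx, vy = x1 - x0, y1 - y0
            denom = vx * vx + vy * vy
            t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / denom, 0, 1)
            d2 = (xx - (x0 + t * vx)) ** 2 + (yy - (y0 + t * vy)) ** 2
            spoke_mask |= d2 <= (spec.spoke_width / 2.0) ** 2
        spoke_mask &= pupil
        img[spoke_mask] = np.clip(
            rng.normal([45.0, 25.0, 20.0], 4.0, (int(spoke_mask.sum()), 3)),
            0, 255)

    # posterior plaque: dark central disc with a jittered radius
    plaque_mask = np.zeros((s, s), dtype=bool)
    frac = spec.target_plaque_fraction()
    if frac > 0:
        frac = max(frac * (1.0 + rng.normal(0.0, spec.plaque_area_jitter)),
                   0.005)
        r_p = R * math.sqrt(frac)
        px = cx + rng.normal(0.0, 0.02 * R)
        py = cy + rng.normal(0.0, 0.02 * R)
        plaque_mask = _disc((s, s), px, py, r_p) & pupil
        img[plaque_mask] = np.clip(
            rng.normal([50.0, 28.0, 22.0], 4.0, (int(plaque_mask.sum()), 3)),
            0, 255)

    # flash highlights: small saturated discs inside the pupil
    for _ in range(spec.flash_spot_count):
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0.15, 0.8) * R
        fx, fy = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
        spot = _disc((s, s), fx, fy, spec.flash_spot_radius) & pupil
        img[spot] = rng.integers(250, 256, (int(spot.sum()), 3))

    img = np.clip(np.floor(img + rng.normal(0.0, spec.noise_sigma,
                                            img.shape) + 0.5),
                  0, 255).astype(np.uint8)
    truth = {
        "pupil_cx": cx, "pupil_cy": cy, "pupil_r": R,
        "spoke_angles_deg": spoke_angles,
        "spoke_pixels": int(spoke_mask.sum()),
        "plaque_pixels": int(plaque_mask.sum()),
        "plaque_area_fraction": float(plaque_mask.sum() / pupil.sum()),
        "spoke_mask": spoke_mask,
        "plaque_mask": plaque_mask,
    }
    return (img, GradeLabel("C", spec.c_grade),
            GradeLabel("P", spec.p_grade), truth)


# ---------------------------------------------------------------------------
# balanced dataset
# ---------------------------------------------------------------------------

@dataclass
class DatasetItem:
    item_id: str
    label: GradeLabel
    seed: int
    image: RgbImage
    truth: Dict

    @property
    def modality(self) -> str:
        return "slit" if self.label.cataract_type in ("NO", "NC") else "retro"


_TYPE_ORDER = ("NO", "NC", "C", "P")


def _item_seed(seed: int, type_idx: int, grade: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(seed), type_idx, grade, rep])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def gen_dataset(n_per_grade: int, seed: int = 0,
                slit_spec: SlitBeamSpec = SlitBeamSpec(),
                retro_spec: RetroSpec = RetroSpec()) -> List[DatasetItem]:
    """Balanced dataset over every grade of every cataract type.

    For each type the varied grade is the item's label and the co-occurring
    type in the same modality is held at grade 0 (types are graded
    separately).  Item seeds derive deterministically from ``seed``.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    items: List[DatasetItem] = []
    for ti, ctype in enumerate(_TYPE_ORDER):
        lo, hi = GRADE_RANGES[ctype]
        for grade in range(lo, hi + 1):
            for rep in range(n_per_grade):
                s = _item_seed(seed, ti, grade, rep)
                item_id = f"{ctype}_g{grade}_r{rep:03d}"
                if ctype == "NO":
                    img, lab, _, truth = gen_slit_beam(
                        replace(slit_spec, no_grade=grade, nc_grade=0, seed=s))
                elif ctype == "NC":
                    img, _, lab, truth = gen_slit_beam(
                        replace(slit_spec, no_grade=0, nc_grade=grade, seed=s))
                elif ctype == "C":
                    img, lab, _, truth = gen_retro(
                        replace(retro_spec, c_grade=grade, p_grade=0, seed=s))
                else:
                    img, _, lab, truth = gen_retro(
                        replace(retro_spec, c_grade=0, p_grade=grade, seed=s))
                items.append(DatasetItem(item_id, lab, s, img, truth))
    return items


def write_dataset(items: List[DatasetItem], out_dir) -> Path:
    """Write images as PNG plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for it in items:
        fname = f"{it.item_id}.png"
        write_image(it.image, out_dir / fname)
        geom = {k: v for k, v in it.truth.items()
                if not isinstance(v, np.ndarray)}
        rows.append({
            "path": fname,
            "type": it.label.cataract_type,
            "grade": it.label.grade,
            "seed": it.seed,
            "geometry": json.dumps(geom, sort_keys=True),
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
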