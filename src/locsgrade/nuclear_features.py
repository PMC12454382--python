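"""Fuzzy-interval colour-proportion features for nuclear grading.

Nuclear opalescence (NO) shows as a cyan/grey haze of the lens nucleus and
nuclear colour (NC) as a yellow-brown discolouration, so the grading features
are the proportions of lens pixels whose RGB values fall inside a *fuzzy
interval* around a standard cyan or standard yellow.  For a standard colour
``(r, g, b)`` and scalar ``offset`` the interval is the axis-aligned RGB box

    R in [r - offset, r + offset],
    G in [g - offset, g + offset],
    B in [b - offset, b + offset]   (endpoints inclusive).

Proportions are computed over the elliptical lens mask only, so the black
background of the rectangular crop does not dilute them; an
``include_background`` flag restores counting over the whole crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .imgcore import (
    BinaryImage,
    EmptyMaskError,
    FeatureVector,
    RgbImage,
    as_binary,
    as_rgb,
)


@dataclass(frozen=True)
class FuzzyColorInterval:
    """Symmetric per-channel interval around a standard colour."""

    standard_color: Tuple[int, int, int]
    offset: int

    def __post_init__(self):
        if not all(0 <= c <= 255 for c in self.standard_color):
            raise ValueError("standard colour channels must be in [0, 255]")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")

    @property
    def lower(self) -> np.ndarray:
        # endpoints are not clamped: pixel values in [0,255] clamp implicitly
        return np.asarray(self.standard_color, dtype=np.int64) - self.offset

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.standard_color, dtype=np.int64) + self.offset

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        """Inclusive membership test for an (..., 3) pixel array."""
        p = np.asarray(pixels, dtype=np.int64)
        return ((p >= self.lower) & (p <= self.upper)).all(axis=-1)


@dataclass(frozen=True)
class ColorFeature:
    proportion: float
    channel_tag: str  # e.g. "cyan_NO" | "yellow_NC"

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must be in [0, 1]")


def make_interval(standard_color, offset: int) -> FuzzyColorInterval:
    """Build the fuzzy interval for a standard colour and offset."""
    return FuzzyColorInterval(tuple(int(c) for c in standard_color), int(offset))


def color_proportion(img: RgbImage, mask: BinaryImage,
                     interval: FuzzyColorInterval,
                     channel_tag: str = "") -> ColorFeature:
    """Fraction of masked pixels whose RGB value lies in the fuzzy interval."""
    img = as_rgb(img)
    mask = as_binary(mask)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask dimensions must equal image dimensions")
    sel = img[mask > 0]
    if sel.shape[0] == 0:
        raise EmptyMaskError("colour proportion is undefined on an empty mask")
    return ColorFeature(float(interval.contains(sel).mean()), channel_tag)


DEFAULT_CYAN = (0, 255, 255)
DEFAULT_YELLOW = (255, 255, 0)
DEFAULT_OFFSETS = (40, 80)


@dataclass(frozen=True)
class NuclearFeatureConfig:
    """Standard colours and offsets for the nuclear feature vector.

    Two offsets per colour give a crude radial profile of the fuzzy-interval
    membership; the vector is [cyan@o1, cyan@o2, ..., yellow@o1, ...].
    """

    standard_cyan: Tuple[int, int, int] = DEFAULT_CYAN
    standard_yellow: Tuple[int, int, int] = DEFAULT_YELLOW
    offsets: Tuple[int, ...] = DEFAULT_OFFSETS
    include_background: bool = False


def nuclear_feature_vector(img: RgbImage, mask: BinaryImage,
                           cfg: NuclearFeatureConfig = NuclearFeatureConfig()
                           ) -> FeatureVector:
    """Ordered cyan-then-yellow proportion vector for one lens crop."""
    if cfg.include_background:
        mask = np.full(np.asarray(img).shape[:2], 255, dtype=np.uint8)
    values = []
    for color, tag in ((cfg.standard_cyan, "cyan_NO"),
                       (cfg.standard_yellow, "yellow_NC")):
        for off in cfg.offsets:
            values.append(color_proportion(img, mask, make_interval(color, off),
                                           tag).proportion)
    return FeatureVector("nuclear", tuple(values))
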