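"""Interpretable vulvar features: bounding-box aspect ratio and dual-threshold
HSV red saturation.

During estrus, vulvar congestion deepens the mucosal red (higher HSV
saturation inside the red hue band) and edema rounds the outline (lower
height/width aspect ratio).  Both features are computed from the detected
bounding box alone, which makes the downstream classifier's decisions
directly inspectable.

Hue uses the 0-180 integer convention so the two red windows are
H in [0, 10] (deep red) and H in [160, 180] (magenta), each additionally
gated by S >= 50 and V >= 50 to suppress shadows and washed-out pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .scenegen import BoundingBox

__all__ = [
    "RedThresholds",
    "FeatureVector",
    "crop_region",
    "to_hsv",
    "red_saturation",
    "aspect_ratio",
    "extract_features",
]


@dataclass(frozen=True)
class RedThresholds:
    """Dual red-hue window with minimum saturation/value gates."""

    low_red: tuple = (0.0, 10.0)
    high_red: tuple = (160.0, 180.0)
    s_min: float = 50.0
    v_min: float = 50.0

    def __post_init__(self):
        for lo, hi in (self.low_red, self.high_red):
            if not (0.0 <= lo <= hi <= 180.0):
                raise ValueError("hue interval outside the 0-180 scale")
        if not (0.0 <= self.s_min <= 255.0 and 0.0 <= self.v_min <= 255.0):
            raise ValueError("s_min/v_min outside [0, 255]")


@dataclass
class FeatureVector:
    aspect_ratio: float
    red_saturation: float
    n_red_pixels: int
    no_red_flag: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.aspect_ratio, self.red_saturation], dtype=float)


def crop_region(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop the box from an (H, W, 3) RGB array with rounded half-open bounds."""
    if image.shape[0] != box.image_height or image.shape[1] != box.image_width:
        raise ValueError("box image dimensions do not match the image")
    x0, y0, x1, y1 = box.to_pixels()
    if x1 <= x0 or y1 <= y0:
        raise ValueError("zero-area crop after clipping")
    return image[y0:y1, x0:x1]


def to_hsv(region: np.ndarray) -> np.ndarray:
    """RGB (uint8 or float 0-255) -> HSV on the 0-180 / 0-255 / 0-255 scale."""
    rgb = np.asarray(region, dtype=float) / 255.0
    hsv = rgb2hsv(rgb)
    hsv[..., 0] *= 180.0
    hsv[..., 1] *= 255.0
    hsv[..., 2] *= 255.0
    return hsv


def red_mask(hsv: np.ndarray, thr: RedThresholds) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    in_low = (h >= thr.low_red[0]) & (h <= thr.low_red[1])
    in_high = (h >= thr.high_red[0]) & (h <= thr.high_red[1])
    return (in_low | in_high) & (s >= thr.s_min) & (v >= thr.v_min)


def red_saturation(
    region: np.ndarray, thr: RedThresholds = RedThresholds()
) -> tuple:
    """Mean S over red-masked pixels and the masked pixel count.

    Returns (0.0, 0) when no pixel passes the mask; callers distinguish
    that case by the zero count (see FeatureVector.no_red_flag).
    """
    if region.size == 0:
        raise ValueError("empty region")
    hsv = to_hsv(region)
    mask = red_mask(hsv, thr)
    n = int(mask.sum())
    if n == 0:
        return 0.0, 0
    return float(hsv[..., 1][mask].mean()), n


def aspect_ratio(box: BoundingBox) -> float:
    """Pixel height over pixel width of the detection box."""
    w_px = box.pixel_width()
    if w_px == 0:
        raise ValueError("zero-width box")
    return box.pixel_height() / w_px


def extract_features(
    image: np.ndarray,
    box: BoundingBox,
    thr: RedThresholds = RedThresholds(),
) -> FeatureVector:
    """Compose crop -> red saturation + aspect ratio into one feature vector."""
    region = crop_region(image, box)
    sat, n = red_saturation(region, thr)
    return FeatureVector(
        aspect_ratio=aspect_ratio(box),
        red_saturation=sat,
        n_red_pixels=n,
        no_red_flag=(n == 0),
    )
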