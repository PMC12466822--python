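"""Synthetic pig-pen scene generator with exact ground truth.

Real vulva imagery from commercial farms is restricted, so every stage of
the pipeline is exercised on rendered scenes instead: a single filled
ellipse (the "vulva") over low-saturation gray-brown clutter, with
occlusion bars, Gaussian blur and lighting variation as nuisance factors.
The two discriminative quantities — bounding-box aspect ratio and red
HSV saturation — are sampled from the published estrus / non-estrus group
statistics (estrus: AR 0.682 +/- 0.272, saturation 87.010 +/- 9.777;
non-estrus: AR 0.973 +/- 0.314, saturation 73.621 +/- 11.661), so the
synthetic task has the same feature-level separability as the real one.

Colors follow the OpenCV integer HSV convention (H in [0, 180], S and V in
[0, 255]) so the dual red-hue thresholds apply verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy import ndimage as ndi

ESTRUS = "estrus"
NON_ESTRUS = "non_estrus"

#: group statistics (mean, SD) of the two vulvar features
FEATURE_STATS = {
    ESTRUS: {"aspect_ratio": (0.682, 0.272), "saturation": (87.010, 9.777)},
    NON_ESTRUS: {"aspect_ratio": (0.973, 0.314), "saturation": (73.621, 11.661)},
}

AR_BOUNDS = (0.1, 3.0)


@dataclass
class SceneSpec:
    """Parametric description of one synthetic scene."""

    image_width: int
    image_height: int
    ellipse_center: tuple  # (x, y) pixels
    ellipse_axes: tuple  # (semi_x, semi_y) pixels
    rotation: float  # degrees, CCW
    region_hue: float  # 0-180
    region_saturation: float  # 0-255
    region_value: float  # 0-255
    background_value: float  # 0-255
    occlusion_bars: int
    blur_sigma: float
    label: str
    sow_id: str

    def __post_init__(self):
        if self.label not in (ESTRUS, NON_ESTRUS):
            raise ValueError(f"unknown label {self.label!r}")
        if not (0 <= self.region_hue <= 180):
            raise ValueError("region_hue outside [0, 180]")
        for name in ("region_saturation", "region_value", "background_value"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} outside [0, 255]")
        if min(self.ellipse_axes) <= 0:
            raise ValueError("degenerate ellipse (non-positive semi-axis)")


@dataclass
class BoundingBox:
    """Normalized center-format box tied to pixel image dimensions."""

    cx: float
    cy: float
    w: float
    h: float
    image_width: int
    image_height: int

    def __post_init__(self):
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError("box center outside [0, 1]")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError("box size outside (0, 1]")

    def to_pixels(self) -> tuple:
        """Half-open pixel corners (x0, y0, x1, y1), rounded and clipped."""
        x0 = int(round((self.cx - self.w / 2) * self.image_width))
        y0 = int(round((self.cy - self.h / 2) * self.image_height))
        x1 = int(round((self.cx + self.w / 2) * self.image_width))
        y1 = int(round((self.cy + self.h / 2) * self.image_height))
        x0, x1 = max(0, x0), min(self.image_width, x1)
        y0, y1 = max(0, y0), min(self.image_height, y1)
        return x0, y0, x1, y1

    def pixel_width(self) -> float:
        return self.w * self.image_width

    def pixel_height(self) -> float:
        return self.h * self.image_height


@dataclass
class GroundTruth:
    box: BoundingBox
    label: str
    sow_id: str
    true_aspect_ratio: float
    true_saturation: float


@dataclass
class DatasetManifest:
    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("image", "label_file", "sow_id", "split", "label")

    def to_csv(self, path):
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    """Resample-until-valid truncated normal draw."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("truncated-normal sampling failed to converge")


def _rotated_extent(semi_x: float, semi_y: float, theta_deg: float) -> tuple:
    """Half-extents (ex, ey) of the tight bounding box of a rotated ellipse."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    ex = math.sqrt((semi_x * c) ** 2 + (semi_y * s) ** 2)
    ey = math.sqrt((semi_x * s) ** 2 + (semi_y * c) ** 2)
    return ex, ey


def _axes_for_aspect(ar: float, scale: float, theta_deg: float) -> tuple:
    """Choose semi-axes so the rotated bounding box has aspect ratio `ar`.

    `scale` fixes sqrt(ex*ey) of the box half-extents.  Falls back to zero
    rotation when the requested (ar, theta) combination is infeasible.
    """
    th = math.radians(theta_deg)
    c2, s2 = math.cos(th) ** 2, math.sin(th) ** 2
    num = c2 - ar**2 * s2
    den = ar**2 * c2 - s2
    if num <= 0 or den <= 0:
        return scale / math.sqrt(ar), scale * math.sqrt(ar), 0.0
    u = math.sqrt(num / den)  # semi_x / semi_y
    ex, ey = _rotated_extent(u, 1.0, theta_deg)
    k = scale / math.sqrt(ex * ey)
    return k * u, k, theta_deg


def sample_spec(
    label: str,
    rng: np.random.Generator,
    image_size: tuple = (128, 128),
    sow_id: str = "sow_000",
    blur_choices=(0.0, 1.0, 2.0),
    bar_choices=(0, 1, 2),
) -> SceneSpec:
    """Draw one scene spec with label-conditional feature distributions."""
    if label not in FEATURE_STATS:
        raise ValueError(f"unknown label {label!r}")
    width, height = image_size
    stats = FEATURE_STATS[label]
    ar = _truncated_normal(rng, *stats["aspect_ratio"], *AR_BOUNDS)
    sat = _truncated_normal(rng, *stats["saturation"], 0.0, 255.0)

    # geometric scale: box covers roughly 4-10% of the frame area
    scale = rng.uniform(0.10, 0.16) * math.sqrt(width * height)
    theta = rng.uniform(-12.0, 12.0)
    semi_x, semi_y, theta = _axes_for_aspect(ar, scale, theta)
    ex, ey = _rotated_extent(semi_x, semi_y, theta)

    margin = 2.0
    # extreme aspect ratios on small frames: shrink (AR-preserving) to fit
    fit = min(
        (width - 2 * margin - 1) / (2 * ex), (height - 2 * margin - 1) / (2 * ey), 1.0
    )
    if fit < 1.0:
        semi_x, semi_y = semi_x * fit, semi_y * fit
        ex, ey = ex * fit, ey * fit
    cx = rng.uniform(ex + margin, width - ex - margin)
    cy = rng.uniform(ey + margin, height - ey - margin)

    hue = rng.uniform(0.0, 10.0) if rng.random() < 0.5 else rng.uniform(170.0, 180.0)
    value = rng.uniform(140.0, 220.0)
    return SceneSpec(
        image_width=width,
        image_height=height,
        ellipse_center=(cx, cy),
        ellipse_axes=(semi_x, semi_y),
        rotation=theta,
        region_hue=hue,
        region_saturation=sat,
        region_value=value,
        background_value=rng.uniform(90.0, 150.0),
        occlusion_bars=int(rng.choice(bar_choices)),
        blur_sigma=float(rng.choice(blur_choices)),
        label=label,
        sow_id=sow_id,
    )


def _hsv_to_rgb255(h: float, s: float, v: float) -> np.ndarray:
    rgb = hsv_to_rgb([h / 180.0, s / 255.0, v / 255.0])
    return np.asarray(rgb) * 255.0


def render_scene(
    spec: SceneSpec, rng: np.random.Generator | None = None
) -> tuple:
    """Render a spec to an RGB uint8 array and its GroundTruth.

    The truth box is computed from the analytic (unoccluded, unblurred)
    ellipse extent; occlusion bars and blur are applied afterwards as pure
    nuisances.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    w, h = spec.image_width, spec.image_height

    # low-saturation gray-brown clutter: shared-channel value noise keeps
    # background saturation well below the red-mask S >= 50 threshold
    base = spec.background_value
    value_noise = rng.normal(0.0, 12.0, (h, w))
    img = np.empty((h, w, 3))
    img[..., 0] = base * 1.06 + value_noise
    img[..., 1] = base * 1.00 + value_noise
    img[..., 2] = base * 0.94 + value_noise

    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = spec.ellipse_center
    th = math.radians(spec.rotation)
    c, s = math.cos(th), math.sin(th)
    xr = (xx + 0.5 - cx) * c + (yy + 0.5 - cy) * s
    yr = -(xx + 0.5 - cx) * s + (yy + 0.5 - cy) * c
    a, b = spec.ellipse_axes
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    if not inside.any():
        raise ValueError("ellipse rendered to zero pixels")
    img[inside] = _hsv_to_rgb255(
        spec.region_hue, spec.region_saturation, spec.region_value
    )

    # tight truth box from the analytic rotated extent
    ex, ey = _rotated_extent(a, b, spec.rotation)
    box = BoundingBox(
        cx=cx / w,
        cy=cy / h,
        w=2 * ex / w,
        h=2 * ey / h,
        image_width=w,
        image_height=h,
    )
    truth = GroundTruth(
        box=box,
        label=spec.label,
        sow_id=spec.sow_id,
        true_aspect_ratio=ey / ex,
        true_saturation=spec.region_saturation,
    )

    # nuisances, applied after truth is fixed
    if spec.occlusion_bars > 0:
        bar_w = max(2, w // 40)
        for _ in range(spec.occlusion_bars):
            x0 = int(rng.integers(0, w - bar_w))
            img[:, x0 : x0 + bar_w, :] = 60.0
    if spec.blur_sigma > 0:
        for ch in range(3):
            img[..., ch] = ndi.gaussian_filter(img[..., ch], spec.blur_sigma)

    return np.clip(img, 0, 255).astype(np.uint8), truth


def write_yolo_label(path, box: BoundingBox, class_id: int = 0):
    Path(path).write_text(
        f"{class_id} {box.cx:.6f} {box.cy:.6f} {box.w:.6f} {box.h:.6f}\n"
    )


def read_yolo_label(path, image_width: int, image_height: int) -> BoundingBox:
    parts = Path(path).read_text().split()
    _, cx, cy, bw, bh = parts[:5]
    return BoundingBox(
        float(cx), float(cy), float(bw), float(bh), image_width, image_height
    )


def assign_splits(
    sow_ids: list, rng: np.random.Generator, sow_label: dict | None = None
) -> dict:
    """Partition sows (not images) into train/val/test at 8:1:1.

    When per-sow labels are given the partition is stratified by label so
    each split keeps the overall estrus prevalence.
    """
    split: dict = {}
    if sow_label is None:
        groups = [list(sow_ids)]
    else:
        labels = sorted({sow_label[s] for s in sow_ids})
        groups = [[s for s in sow_ids if sow_label[s] == lab] for lab in labels]
    for ids in groups:
        perm = rng.permutation(len(ids))
        n = len(ids)
        n_train = int(round(0.8 * n))
        n_val = max(1, int(round(0.1 * n))) if n - n_train >= 2 else n - n_train
        for rank, idx in enumerate(perm):
            if rank < n_train:
                split[ids[idx]] = "train"
            elif rank < n_train + n_val:
                split[ids[idx]] = "val"
            else:
                split[ids[idx]] = "test"
    return split


def build_dataset(
    out_dir,
    n_scenes: int,
    estrus_fraction: float = 0.3,
    n_sows: int = 100,
    seed: int = 0,
    image_size: tuple = (128, 128),
    blur_choices=(0.0, 1.0, 2.0),
    bar_choices=(0, 1, 2),
) -> DatasetManifest:
    """Render a labeled dataset to disk and return its manifest.

    Scenes are assigned to sows round-robin; each sow has a persistent
    estrus status so the sow-level stratified split keeps class balance.
    """
    if not (0.0 < estrus_fraction < 1.0):
        raise ValueError("estrus_fraction must be in (0, 1)")
    if n_scenes < n_sows or n_sows < 10:
        raise ValueError("need n_scenes >= n_sows >= 10")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)

    sow_ids = [f"sow_{i:03d}" for i in range(n_sows)]
    n_estrus = int(round(n_scenes * estrus_fraction))
    # sows carry the label: first ceil(share) sows estrus, rest non-estrus,
    # so that round-robin scene assignment hits the target label count
    n_estrus_sows = int(round(n_sows * estrus_fraction))
    sow_label = {
        sid: (ESTRUS if i < n_estrus_sows else NON_ESTRUS)
        for i, sid in enumerate(sow_ids)
    }
    split_of = assign_splits(sow_ids, rng, sow_label)

    # round-robin within each label group to hit the exact label count
    estrus_sows = [s for s in sow_ids if sow_label[s] == ESTRUS]
    other_sows = [s for s in sow_ids if sow_label[s] == NON_ESTRUS]
    assignments = []
    for i in range(n_estrus):
        assignments.append((ESTRUS, estrus_sows[i % len(estrus_sows)]))
    for i in range(n_scenes - n_estrus):
        assignments.append((NON_ESTRUS, other_sows[i % len(other_sows)]))

    rows = []
    for i, (label, sid) in enumerate(assignments):
        spec = sample_spec(
            label,
            rng,
            image_size=image_size,
            sow_id=sid,
            blur_choices=blur_choices,
            bar_choices=bar_choices,
        )
        img, truth = render_scene(spec, rng)
        img_path = out_dir / "images" / f"scene_{i:05d}.png"
        lbl_path = out_dir / "labels" / f"scene_{i:05d}.txt"
        Image.fromarray(img).save(img_path)
        write_yolo_label(lbl_path, truth.box)
        rows.append(
            {
                "image": str(img_path),
                "label_file": str(lbl_path),
                "sow_id": sid,
                "split": split_of[sid],
                "label": label,
            }
        )
    manifest = DatasetManifest(pd.DataFrame(rows))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
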