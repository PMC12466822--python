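"""End-to-end inference: detect -> size guard -> features -> classify -> annotate.

Per frame, the highest-confidence detected box is screened by a minimum
area guard (boxes below `min_box_fraction` of the frame are too small to
classify reliably and prompt the operator to move closer), then the two
vulvar features are extracted and the MLP produces an estrus probability.
Annotation colors follow the operator convention: green = non-estrus,
red = estrus, blue = too small.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .estrus_mlp import MLPModel, Normalizer, forward
from .fusionnet import Detector, DetectorConfig, reference_detect
from .scenegen import BoundingBox, DatasetManifest, ESTRUS, NON_ESTRUS
from .vulvafeat import FeatureVector, RedThresholds, extract_features

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FrameResult", "process_frame", "process_batch"]

ANNOTATION_COLORS = {
    ESTRUS: (255, 0, 0),
    NON_ESTRUS: (0, 255, 0),
    "too_small": (0, 0, 255),
}


@dataclass
class PipelineConfig:
    detector: "Detector | str" = "reference"  # Detector instance or "reference"
    classifier: "MLPModel | None" = None
    normalizer: "Normalizer | None" = None
    thresholds: RedThresholds = field(default_factory=RedThresholds)
    min_box_fraction: float = 0.01
    conf_threshold: float = 0.3
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.min_box_fraction < 0.5):
            raise ValueError("min_box_fraction must be in (0, 0.5)")


@dataclass
class FrameResult:
    status: str  # estrus / non_estrus / too_small / no_detection
    box: BoundingBox | None = None
    confidence: float | None = None
    probability: float | None = None
    features: FeatureVector | None = None

    def __post_init__(self):
        if self.status == "too_small" and self.probability is not None:
            raise ValueError("too-small boxes carry no classification")


def _detect(image: np.ndarray, cfg: PipelineConfig) -> list:
    if cfg.detector == "reference":
        return reference_detect(image, cfg.thresholds)
    return cfg.detector.predict(image, cfg.conf_threshold)


def _annotate(image: np.ndarray, box: BoundingBox, color: tuple) -> np.ndarray:
    out = image.copy()
    x0, y0, x1, y1 = box.to_pixels()
    t = max(1, image.shape[0] // 100)
    out[y0 : y0 + t, x0:x1] = color
    out[max(0, y1 - t) : y1, x0:x1] = color
    out[y0:y1, x0 : x0 + t] = color
    out[y0:y1, max(0, x1 - t) : x1] = color
    return out


def process_frame(image: np.ndarray, cfg: PipelineConfig) -> tuple:
    """Run the full workflow on one RGB frame; returns (FrameResult, annotated)."""
    dets = _detect(image, cfg)
    if not dets:
        logger.info("no detection in frame")
        return FrameResult(status="no_detection"), image.copy()
    if len(dets) > 1:
        logger.warning("multiple detections; classifying the most confident box")
    box, conf = dets[0]

    frame_area = box.image_width * box.image_height
    box_area = box.pixel_width() * box.pixel_height()
    if box_area < cfg.min_box_fraction * frame_area:
        result = FrameResult(status="too_small", box=box, confidence=conf)
        return result, _annotate(image, box, ANNOTATION_COLORS["too_small"])

    feats = extract_features(image, box, cfg.thresholds)
    if cfg.classifier is not None:
        prob = float(forward(cfg.classifier, feats.as_array(), cfg.normalizer)[0])
    else:
        prob = float("nan")
    status = (
        ESTRUS if prob >= cfg.decision_threshold else NON_ESTRUS
    )
    result = FrameResult(
        status=status, box=box, confidence=conf, probability=prob, features=feats
    )
    return result, _annotate(image, box, ANNOTATION_COLORS[status])


def process_batch(
    source,
    cfg: PipelineConfig,
    output_dir=None,
) -> pd.DataFrame:
    """Process a manifest CSV/DatasetManifest or an image directory.

    Returns one row per processed frame; unreadable files are skipped with
    a logged warning.  Annotated images are written when `output_dir` is
    given.
    """
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("*.png")) + sorted(Path(source).glob("*.jpg"))
        frames = [{"image": str(p)} for p in paths]
    else:
        manifest = (
            source
            if isinstance(source, DatasetManifest)
            else DatasetManifest.from_csv(source)
        )
        frames = manifest.entries.to_dict("records")

    if output_dir is not None:
        Path(output_dir).mkdir(parents=True, exist_ok=True)

    rows = []
    for rec in sorted(frames, key=lambda r: r["image"]):
        try:
            image = np.asarray(Image.open(rec["image"]).convert("RGB"))
        except (OSError, ValueError) as exc:
            logger.warning("skipping unreadable file %s: %s", rec["image"], exc)
            continue
        t0 = time.perf_counter()
        result, annotated = process_frame(image, cfg)
        logger.debug(
            "%s: %s in %.1f ms", rec["image"], result.status,
            1e3 * (time.perf_counter() - t0),
        )
        if output_dir is not None:
            Image.fromarray(annotated).save(
                Path(output_dir) / Path(rec["image"]).name
            )
        row = {
            "image": rec["image"],
            "sow_id": rec.get("sow_id", ""),
            "status": result.status,
            "confidence": result.confidence,
            "probability": result.probability,
            "aspect_ratio": result.features.aspect_ratio if result.features else None,
            "red_saturation": (
                result.features.red_saturation if result.features else None
            ),
            "n_red_pixels": result.features.n_red_pixels if result.features else None,
            "true_label": rec.get("label"),
        }
        if result.box is not None:
            row.update(
                dict(
                    zip(
                        ("box_x0", "box_y0", "box_x1", "box_y1"),
                        result.box.to_pixels(),
                    )
                )
            )
        rows.append(row)
    return pd.DataFrame(rows)
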