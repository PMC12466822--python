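"""Masked generative distillation (MGD) and the warm-up/cosine schedule.

In MGD the student's feature maps are randomly masked per pixel and a
small convolutional generator must reconstruct the teacher's features
from what remains:

    L_dis(S, T) = sum_l sum_k sum_i sum_j ( T^l_{k,i,j}
                    - G( f_align(S^l)_{k,i,j} * M^l_{i,j} ) )^2

with M^l_{i,j} = 0 where a uniform draw R^l_{i,j} < lambda and 1
otherwise.  Turning imitation into generation forces the student to carry
enough context to restore the teacher's response at masked locations,
which empirically transfers better than plain feature matching for
region-focused detection.  The squared-L2 form of the original MGD
formulation is used.

The mask is shared across channels of a layer and drawn independently per
layer and per step.  The generator is a 1x1 channel-aligning projection
followed by two 3x3 convolutions with a ReLU between.  The learning-rate
schedule is the printed three-epoch linear warm-up from 1e-4 to 1e-3
followed by cosine decay to 1e-6 over the remaining 297 of 300 epochs
(both horizons configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .fusionnet import Detector, detection_loss, build_targets

__all__ = [
    "MaskSpec",
    "ScheduleParams",
    "Generator",
    "random_mask",
    "distill_loss",
    "lr_schedule",
    "distill",
]


@dataclass
class MaskSpec:
    lambda_mask: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lambda_mask <= 1.0):
            raise ValueError("masking rate lambda must be in [0, 1]")


@dataclass
class ScheduleParams:
    eta0: float = 1e-4
    eta_peak: float = 1e-3
    eta_min: float = 1e-6
    warmup: int = 3
    total: int = 300

    def __post_init__(self):
        if not (self.eta0 < self.eta_peak and self.eta_min < self.eta_peak):
            raise ValueError("need eta0 < eta_peak and eta_min < eta_peak")
        if not (0 < self.warmup < self.total):
            raise ValueError("need 0 < warmup < total")


def random_mask(
    height: int, width: int, spec: MaskSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Binary (height, width) mask: 0 where R < lambda, 1 otherwise."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r = rng.random((height, width))
    return (r >= spec.lambda_mask).astype(float)


class Generator(nn.Module):
    """Channel alignment + two 3x3 convs regenerating teacher features."""

    def __init__(self, student_channels: int, teacher_channels: int, rng):
        self.align = nn.Conv2d(student_channels, teacher_channels, 1, rng)
        self.conv1 = nn.Conv2d(teacher_channels, teacher_channels, 3, rng)
        self.conv2 = nn.Conv2d(teacher_channels, teacher_channels, 3, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        aligned = self.align(x)
        masked = aligned * Tensor(mask[None, None, :, :])
        return self.conv2(self.conv1(masked).relu())


def distill_loss(
    student_feats: list,
    teacher_feats: list,
    gens: list,
    spec: MaskSpec,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Summed squared reconstruction error over all distillation layers.

    `gens[l]` maps the masked, aligned student map of layer l to the
    teacher's shape; identity callables are accepted (they receive the
    feature tensor and the mask).
    """
    if len(student_feats) != len(teacher_feats) or len(student_feats) != len(gens):
        raise ValueError("student/teacher/generator layer counts differ")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    total = None
    for s, t, g in zip(student_feats, teacher_feats, gens):
        h, w = s.shape[2], s.shape[3]
        if (t.shape[2], t.shape[3]) != (h, w):
            raise ValueError("teacher/student spatial sizes differ")
        mask = random_mask(h, w, spec, rng)
        regenerated = g(s, mask)
        term = ((regenerated - t) ** 2.0).sum()
        total = term if total is None else total + term
    return total


def lr_schedule(t: float, p: ScheduleParams = ScheduleParams()) -> float:
    """Piecewise warm-up/cosine learning rate at (possibly fractional) epoch t."""
    if not (0 <= t < p.total):
        raise ValueError(f"epoch {t} outside [0, {p.total})")
    if t < p.warmup:
        return p.eta0 + (p.eta_peak - p.eta0) * t / p.warmup
    span = p.total - p.warmup
    return p.eta_min + 0.5 * (p.eta_peak - p.eta_min) * (
        1.0 + math.cos(math.pi * (t - p.warmup) / span)
    )


def distill(
    teacher: Detector,
    student: Detector,
    images: list,
    boxes: list,
    spec: MaskSpec = MaskSpec(),
    epochs: int = 10,
    batch_size: int = 16,
    distill_weight: float = 1.0,
    schedule: ScheduleParams | None = None,
    lr: float = 2e-3,
    seed: int = 0,
) -> pd.DataFrame:
    """Train `student` with task loss + MGD loss against a frozen teacher.

    Returns a per-epoch trace with learning rate, task loss and distill
    loss.  The teacher is evaluated in inference mode and its parameters
    receive no updates.  Distillation hooks are the three neck outputs
    (head-input pyramid levels).
    """
    if len(images) != len(boxes):
        raise ValueError("images and boxes differ in length")
    rng = np.random.default_rng(seed)
    mask_rng = np.random.default_rng(spec.seed + 1)
    size = student.config.image_size
    if teacher.config.image_size != size:
        raise ValueError("teacher/student input sizes differ")

    x_all = np.stack([im.astype(float).transpose(2, 0, 1) for im in images]) / 255.0
    grid = size // 8
    obj_t, box_t, mask_t = build_targets(boxes, grid)

    teacher.set_training(False)
    s_c = student.config.neck_channels
    t_c = teacher.config.neck_channels
    gen_rng = np.random.default_rng(seed + 7)
    gens = [Generator(s_c, t_c, gen_rng) for _ in range(3)]

    params = student.parameters() + [p for g in gens for p in g.parameters()]
    opt = nn.Adam(params, lr=lr)
    student.set_training(True)

    # normalise the distillation term by feature size so the default
    # weight is comparable to the task loss
    def feat_scale(feats):
        return float(sum(f.data.size for f in feats))

    rows = []
    n = len(images)
    for epoch in range(epochs):
        opt.lr = lr_schedule(epoch, schedule) if schedule is not None else lr
        order = rng.permutation(n)
        task_losses, dis_losses = [], []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            x = Tensor(x_all[idx])
            s_feats, raw = student.forward_features(x)
            with_frozen = Tensor(x_all[idx])
            t_feats, _ = teacher.forward_features(with_frozen)
            t_feats = [Tensor(f.data) for f in t_feats]  # cut teacher graph
            task = detection_loss(raw, obj_t[idx], box_t[idx], mask_t[idx])
            dis = distill_loss(s_feats, t_feats, gens, spec, mask_rng)
            dis = dis * (1.0 / feat_scale(t_feats))
            loss = task + dis * distill_weight
            opt.zero_grad()
            loss.backward()
            opt.step()
            task_losses.append(float(task.data))
            dis_losses.append(float(dis.data))
        rows.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "task_loss": float(np.mean(task_losses)),
                "distill_loss": float(np.mean(dis_losses)),
            }
        )
    student.set_training(False)
    return pd.DataFrame(rows)
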