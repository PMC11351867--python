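"""Rejection network: per-image segmentation-quality regression and gating.

The network regresses the Dice coefficient of the coarse segmentation from
the channel-wise concatenation of the coarse model's final feature map and
its two-channel probability map. Images whose predicted score falls strictly
below the gate threshold are routed to manual interaction; the boundary
score equals AUTO.

The regression head is always three fully connected layers with ReLU between
(final width 1, linear output during training; scores are clamped to [0, 1]
only at inference). The full-scale profile pairs the head with an
EfficientNet-class backbone; the desk-scale profile swaps in a small
four-stage convolutional encoder with the identical contract.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from ._nn import autodiff as ad
from ._nn.layers import Conv2d, Linear, Module
from ._nn.optim import Adam, poly_decay
from ._train_utils import TrainConfig, masks_to_array, slices_to_array
from .coarse_seg import CoarseUNet, predict_batch
from .errors import ConfigurationError
from .metrics_eval import dice_coefficient
from .preprocessing_io import BinaryMask, MultiModalSlice
from .synthetic_data import PhantomCohort

__all__ = [
    "QualityScore", "RejectNetConfig", "GateConfig", "RouteDecision",
    "RejectionNet", "build_rejection_net", "quality_target", "mse_loss",
    "train_rejection", "gate", "predict_scores",
]


class RouteDecision(str, enum.Enum):
    MANUAL = "MANUAL"
    AUTO = "AUTO"


@dataclass(frozen=True)
class QualityScore:
    """Predicted score s (clamped to [0,1] at inference) and target Dice d."""

    predicted: float
    target: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.predicted):
            raise ValueError("predicted score must be finite")
        if self.target is not None and not 0.0 <= self.target <= 1.0:
            raise ValueError("target Dice must lie in [0, 1]")


@dataclass(frozen=True)
class RejectNetConfig:
    backbone: str = "small_cnn"          # desk-scale; "efficientnet_b5" reserved
    head_widths: tuple[int, int, int] = (1024, 512, 1)
    in_channels: int = 18                # coarse feature channels + 2
    base_channels: int = 8
    seed: int = 0

    def __post_init__(self):
        if len(self.head_widths) != 3 or self.head_widths[2] != 1:
            raise ConfigurationError(
                "head must have exactly three FC stages with final width 1")
        if self.in_channels < 3:
            raise ConfigurationError("in_channels must be >= 3")

    @staticmethod
    def desk_scale(in_channels: int, seed: int = 0) -> "RejectNetConfig":
        return RejectNetConfig(backbone="small_cnn", head_widths=(64, 32, 1),
                               in_channels=in_channels, base_channels=8, seed=seed)


@dataclass(frozen=True)
class GateConfig:
    """Gate threshold t. Meaningful scores live in [0, 1]; values above 1
    are accepted as an explicit "route everything to manual" limit."""

    threshold: float = 0.4

    def __post_init__(self):
        if not (np.isfinite(self.threshold) and self.threshold >= 0.0):
            raise ConfigurationError("threshold must be finite and >= 0")


class RejectionNet(Module):
    """Four-stage conv backbone + global pooling + three-FC regression head."""

    def __init__(self, config: RejectNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        self.backbone = [
            Conv2d(config.in_channels, b, 3, rng),
            Conv2d(b, 2 * b, 3, rng),
            Conv2d(2 * b, 4 * b, 3, rng),
            Conv2d(4 * b, 4 * b, 3, rng),
        ]
        w1, w2, _ = config.head_widths
        self.head = [Linear(4 * b, w1, rng), Linear(w1, w2, rng), Linear(w2, 1, rng)]

    def backbone_parameters(self):
        return [p for m in self.backbone for p in m.parameters()]

    def head_parameters(self):
        return [p for m in self.head for p in m.parameters()]

    def forward(self, x) -> ad.Tensor:
        """x: (N, C+2, H, W) -> raw scores (N, 1); no output activation."""
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(x)
        if x.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, "
                f"got {x.data.shape[1]}")
        h = x
        for conv in self.backbone:
            h = ad.maxpool2x(ad.relu(conv(h)))
        h = ad.global_avg_pool(h)
        h = ad.relu(self.head[0](h))
        h = ad.relu(self.head[1](h))
        return self.head[2](h)

    __call__ = forward


def build_rejection_net(config: RejectNetConfig) -> RejectionNet:
    return RejectionNet(config)


def quality_target(coarse_mask: np.ndarray | BinaryMask,
                   gt: np.ndarray | BinaryMask) -> float:
    """Target quality d_i: Dice between binarised coarse prediction and truth."""
    cm = coarse_mask.pixels if isinstance(coarse_mask, BinaryMask) else coarse_mask
    gm = gt.pixels if isinstance(gt, BinaryMask) else gt
    return dice_coefficient(cm, gm)


def mse_loss(predicted, target):
    """Mean squared error; Tensor inputs keep the graph, arrays return float."""
    if isinstance(predicted, ad.Tensor):
        diff = ad.add(predicted, ad.mul(target, -1.0))
        return ad.mean_all(ad.mul(diff, diff))
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean((p - t) ** 2))


def gate(score: QualityScore | float, cfg: GateConfig) -> RouteDecision:
    """MANUAL iff predicted < threshold (strict); the boundary stays AUTO."""
    s = score.predicted if isinstance(score, QualityScore) else float(score)
    return RouteDecision.MANUAL if s < cfg.threshold else RouteDecision.AUTO


def _rejection_inputs(coarse: CoarseUNet, slices: list[MultiModalSlice],
                      batch_size: int) -> np.ndarray:
    """Concatenate final features and probabilities: (N, C+2, H, W)."""
    preds = predict_batch(coarse, slices, batch_size)
    return np.stack([
        np.concatenate([f.features.transpose(2, 0, 1),
                        p.probs.transpose(2, 0, 1)], axis=0)
        for p, f in preds
    ]).astype(np.float32)


def predict_scores(model: RejectionNet, coarse: CoarseUNet,
                   slices: list[MultiModalSlice],
                   batch_size: int = 16) -> np.ndarray:
    """Inference-time quality scores, clamped to [0, 1]."""
    scores = []
    for i in range(0, len(slices), batch_size):
        x = _rejection_inputs(coarse, slices[i:i + batch_size], batch_size)
        out = model.forward(x)
        scores.append(out.data[:, 0])
    return np.clip(np.concatenate(scores), 0.0, 1.0)


def train_rejection(model: RejectionNet, coarse: CoarseUNet,
                    cohort: PhantomCohort, cfg: TrainConfig
                    ) -> tuple[RejectionNet, list[dict]]:
    """Train the quality regressor against on-the-fly Dice targets.

    The coarse model is frozen: its parameters are snapshotted before
    training and verified bitwise unchanged afterwards. Targets d_i are
    recomputed each epoch from the frozen coarse predictions. Adam uses the
    backbone/head learning-rate split (cfg.backbone_lr / cfg.lr) with
    polynomial decay; the checkpoint with lowest validation MSE is returned.
    """
    train_pairs = cohort.slices("train")
    val_pairs = cohort.slices("val")
    if not train_pairs or not val_pairs:
        raise ValueError("cohort must provide non-empty train and val splits")
    coarse_before = coarse.copy_state()

    val_x = _rejection_inputs(coarse, [s for s, _ in val_pairs], cfg.batch_size)
    val_d = _targets(coarse, val_pairs, cfg.batch_size)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam([(model.backbone_parameters(), cfg.backbone_lr),
                (model.head_parameters(), cfg.lr)])
    n = len(train_pairs)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    history: list[dict] = []
    best = (np.inf, None)
    step = 0
    for epoch in range(cfg.epochs):
        # frozen coarse model, fixed inputs: recomputing keeps targets honest
        # against any upstream change at negligible desk-scale cost
        x_tr = _rejection_inputs(coarse, [s for s, _ in train_pairs], cfg.batch_size)
        d_tr = _targets(coarse, train_pairs, cfg.batch_size)
        losses = []
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            model.zero_grad()
            out = model.forward(x_tr[idx])
            loss = mse_loss(out, ad.Tensor(d_tr[idx][:, None]))
            loss.backward()
            opt.step(lr_scale=poly_decay(1.0, step, total_steps, cfg.poly_power))
            losses.append(float(loss.data))
            step += 1
        val_pred = model.forward(val_x).data[:, 0]
        val_mse = float(np.mean((val_pred - val_d) ** 2))
        history.append({"epoch": epoch, "train_mse": float(np.mean(losses)),
                        "val_mse": val_mse})
        if val_mse < best[0]:
            best = (val_mse, model.copy_state())
    if best[1] is not None:
        model.load_state_arrays(best[1])

    for before, after in zip(coarse_before, coarse.state_arrays()):
        if not np.array_equal(before, after):
            raise RuntimeError("coarse model parameters changed during "
                               "rejection training; it must stay frozen")
    return model, history


def _targets(coarse: CoarseUNet,
             pairs: list[tuple[MultiModalSlice, BinaryMask]],
             batch_size: int) -> np.ndarray:
    preds = predict_batch(coarse, [s for s, _ in pairs], batch_size)
    return np.array([quality_target(p.binarize(), m.pixels)
                     for (p, _), (_, m) in zip(preds, pairs)], dtype=np.float32)
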