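"""Coarse segmentation network: a U-Net variant with squeeze-and-excitation
channel recalibration after every convolutional block and non-local
(embedded-Gaussian attention) units on the two deepest skip connections.

The encoder has five convolutional blocks separated by four 2x2 max-pooling
steps, so the deepest features sit at an output stride of 16. The forward
pass yields both the per-pixel background/foreground probability map and the
final decoder feature map (the representation just before the 1x1 classifier),
which the rejection network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import autodiff as ad
from ._nn.layers import Conv2d, ConvBlock, Module, NonLocalBlock
from ._nn.optim import Adam, poly_decay
from ._train_utils import TrainConfig, augment_batch, masks_to_array, slices_to_array
from .errors import ConfigurationError
from .metrics_eval import dice_coefficient
from .preprocessing_io import BinaryMask, MultiModalSlice
from .synthetic_data import PhantomCohort

__all__ = [
    "CoarseNetConfig", "ProbabilityMap", "FeatureMap", "CoarseUNet",
    "build_coarse_net", "dice_loss", "train_coarse", "predict_batch",
]

DICE_EPS = 1e-5
_CH_MULT = (1, 2, 4, 8, 8)  # channel multipliers per encoder stage


@dataclass(frozen=True)
class CoarseNetConfig:
    encoder_blocks: int = 5
    pooling_ops: int = 4
    base_channels: int = 16
    use_se: bool = True
    use_nonlocal: bool = True
    se_reduction: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.encoder_blocks != 5 or self.pooling_ops != 4:
            raise ConfigurationError(
                "architecture fixed at 5 encoder blocks / 4 pooling ops (stride 16)")
        if self.base_channels < 2:
            raise ConfigurationError("base_channels must be >= 2")


@dataclass
class ProbabilityMap:
    """Per-pixel (background, foreground) probabilities, channels last."""

    probs: np.ndarray  # (H, W, 2)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3 or self.probs.shape[2] != 2:
            raise ValueError("expected (H, W, 2) probabilities")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-pixel probabilities must sum to 1")

    @property
    def foreground(self) -> np.ndarray:
        return self.probs[:, :, 1]

    def binarize(self) -> np.ndarray:
        return self.probs[:, :, 1] > self.probs[:, :, 0]


@dataclass
class FeatureMap:
    features: np.ndarray  # (H, W, C)


class CoarseUNet(Module):
    def __init__(self, config: CoarseNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        enc_ch = [b * m for m in _CH_MULT]
        self.enc = [ConvBlock(3 if i == 0 else enc_ch[i - 1], enc_ch[i], rng,
                              use_se=config.use_se, se_reduction=config.se_reduction)
                    for i in range(5)]
        # non-local attention on the two deepest skips (encoder stages 3 and 4)
        self.nonlocal_blocks = (
            [NonLocalBlock(enc_ch[3], rng), NonLocalBlock(enc_ch[2], rng)]
            if config.use_nonlocal else [])
        self.dec = []
        ch = enc_ch[4]
        for i in (3, 2, 1, 0):
            self.dec.append(ConvBlock(ch + enc_ch[i], enc_ch[i], rng,
                                      use_se=config.use_se,
                                      se_reduction=config.se_reduction))
            ch = enc_ch[i]
        self.classifier = Conv2d(b, 2, 1, rng)
        # bias the initial prediction toward background: lesions occupy a few
        # percent of pixels, and Dice loss recovers poorly from the uniform
        # 0.5 start at this scale
        self.classifier.b.data[:] = (2.0, -2.0)
        self.feature_channels = b

    def forward(self, x) -> tuple[ad.Tensor, ad.Tensor]:
        """x: (N, 3, H, W) array or Tensor -> (probs (N,2,H,W), feat (N,b,H,W))."""
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < 4:
                skips.append(h)
                h = ad.maxpool2x(h)
        if self.nonlocal_blocks:
            skips[3] = self.nonlocal_blocks[0](skips[3])
            skips[2] = self.nonlocal_blocks[1](skips[2])
        for block, skip in zip(self.dec, reversed(skips)):
            h = ad.upsample2x(h)
            h = block(ad.concat([h, skip], axis=1))
        logits = self.classifier(h)
        return ad.softmax(logits, axis=1), h

    __call__ = forward


def build_coarse_net(config: CoarseNetConfig) -> CoarseUNet:
    """Construct the coarse network; identical seeds give identical weights."""
    return CoarseUNet(config)


def dice_loss(pred_fg, target, eps: float = DICE_EPS):
    """Soft Dice loss, batch mean: 1 - (1/N) sum_i 2<p,y> / (sum p + sum y).

    Accepts (N, H, W) tensors (training path, returns a Tensor) or plain
    arrays of matching shape (returns a float). A single (H, W) pair is
    treated as a batch of one. The additive smoothing ``eps`` keeps the loss
    defined on lesion-free slices.
    """
    is_tensor = isinstance(pred_fg, ad.Tensor)
    p = pred_fg if is_tensor else ad.Tensor(np.asarray(pred_fg, np.float32))
    t = target if isinstance(target, ad.Tensor) else ad.Tensor(
        np.asarray(target, np.float32))
    if p.data.shape != t.data.shape:
        raise ValueError(f"shape mismatch {p.data.shape} vs {t.data.shape}")
    if p.ndim == 2:
        p = ad.reshape(p, (1,) + p.data.shape)
        t = ad.reshape(t, (1,) + t.data.shape)
    n = p.data.shape[0]
    flat_p = ad.reshape(p, (n, -1))
    flat_t = ad.reshape(t, (n, -1))
    inter = _rowsum(ad.mul(flat_p, flat_t))
    sums = ad.add(_rowsum(flat_p), _rowsum(flat_t))
    ones = np.ones((n, 1), np.float32)
    dice = ad.mul(ad.add(ad.mul(inter, 2.0), eps), _inv(ad.add(sums, eps)))
    loss = ad.add(1.0, ad.mul(ad.matmul(ad.reshape(dice, (1, n)),
                                        ad.Tensor(ones)), -1.0 / n))
    loss = ad.reshape(loss, ())
    return loss if is_tensor else float(loss.data)


def _rowsum(x: ad.Tensor) -> ad.Tensor:
    n, m = x.data.shape
    return ad.matmul(x, ad.Tensor(np.ones((m, 1), np.float32)))


def _inv(x: ad.Tensor) -> ad.Tensor:
    """Elementwise reciprocal; inputs here are strictly positive sums."""
    inv = 1.0 / x.data

    def bwd(g):
        if x.requires_grad:
            x._accumulate(-g * inv * inv)

    out = ad.Tensor(inv)
    out.requires_grad = x.requires_grad
    if x.requires_grad:
        out._parents = (x,)
        out._backward = bwd
    return out


def predict_batch(model: CoarseUNet, slices: list[MultiModalSlice],
                  batch_size: int = 16) -> list[tuple[ProbabilityMap, FeatureMap]]:
    """Inference over a slice list, batched for throughput."""
    out = []
    for i in range(0, len(slices), batch_size):
        x = slices_to_array(slices[i:i + batch_size])
        probs, feat = model.forward(x)
        for j in range(x.shape[0]):
            out.append((ProbabilityMap(probs.data[j].transpose(1, 2, 0)),
                        FeatureMap(feat.data[j].transpose(1, 2, 0))))
    return out


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train_coarse(model: CoarseUNet, cohort: PhantomCohort,
                 cfg: TrainConfig) -> tuple[CoarseUNet, list[dict]]:
    """Train with soft Dice loss; returns the best-validation-DSC checkpoint.

    Adam with polynomial learning-rate decay; random flip/rotation/crop
    augmentation when ``cfg.augment``. History records per-epoch training
    loss, validation mean DSC and the learning rate in force.
    """
    train_pairs = cohort.slices("train")
    val_pairs = cohort.slices("val")
    if not train_pairs or not val_pairs:
        raise ValueError("cohort must provide non-empty train and val splits")
    x_tr = slices_to_array([s for s, _ in train_pairs])
    y_tr = masks_to_array([m for _, m in train_pairs])
    rng = np.random.default_rng(cfg.seed)
    opt = Adam([(model.parameters(), cfg.lr)])
    n = x_tr.shape[0]
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    history: list[dict] = []
    best = (-1.0, None)
    step = 0
    for epoch in range(cfg.epochs):
        losses = []
        lr_scale = 1.0
        for idx in _epoch_batches(n, cfg.batch_size, rng):
            xb, yb = x_tr[idx], y_tr[idx]
            if cfg.augment:
                xb, yb = augment_batch(xb, yb, rng)
            model.zero_grad()
            probs, _ = model.forward(xb)
            fg = _select_fg(probs)
            loss = dice_loss(fg, ad.Tensor(yb))
            loss.backward()
            lr_scale = poly_decay(1.0, step, total_steps, cfg.poly_power)
            opt.step(lr_scale=lr_scale)
            losses.append(float(loss.data))
            step += 1
        val_dsc = evaluate_coarse_dsc(model, val_pairs, cfg.batch_size,
                                      lesion_only=True)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dsc": val_dsc, "lr": cfg.lr * lr_scale})
        if val_dsc > best[0]:
            best = (val_dsc, model.copy_state())
    if best[1] is not None:
        model.load_state_arrays(best[1])
    return model, history


def _select_fg(probs: ad.Tensor) -> ad.Tensor:
    """Foreground channel (N, H, W) from (N, 2, H, W) with gradient flow."""
    n, _, h, w = probs.data.shape
    sel = np.zeros((2, 1), np.float32)
    sel[1, 0] = 1.0
    moved = ad.reshape(ad.transpose_last2(ad.reshape(probs, (n, 2, h * w))),
                       (n * h * w, 2))
    fg = ad.matmul(moved, ad.Tensor(sel))
    return ad.reshape(fg, (n, h, w))


def evaluate_coarse_dsc(model: CoarseUNet,
                        pairs: list[tuple[MultiModalSlice, BinaryMask]],
                        batch_size: int = 16,
                        lesion_only: bool = False) -> float:
    """Mean DSC of argmax-binarised predictions over (slice, mask) pairs.

    With ``lesion_only`` the mean is taken over lesion-bearing slices; this
    is used for checkpoint selection, where the both-empty = 1 convention
    would otherwise favour degenerate all-background predictions on cohorts
    dominated by lesion-free slices.
    """
    if lesion_only:
        kept = [pair for pair in pairs if pair[1].pixels.any()]
        pairs = kept or pairs
    preds = predict_batch(model, [s for s, _ in pairs], batch_size)
    return float(np.mean([dice_coefficient(p.binarize(), m.pixels)
                          for (p, _), (_, m) in zip(preds, pairs)]))
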