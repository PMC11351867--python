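"""Fine segmentation stage: box-prompted segmenters.

The cascade only needs the contract "image + bounding box -> probability
map". Two implementations are provided:

* ``BuiltinPromptNet`` — a small encoder-decoder taking four input channels
  (the three modality channels plus a rendered box-interior channel) and
  trained here with the combined cross-entropy + Dice loss. The rendered
  prompt channel replaces coordinate embeddings: at desk scale it is the
  simplest faithful conditioning on an axis-aligned box.
* ``sam_adapter`` — an optional adapter for an external promptable
  foundation model (SAM-style). It is an integration point only: without
  the external weights and runtime it raises ``ExternalDependencyMissing``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from ._nn import autodiff as ad
from ._nn.layers import Conv2d, ConvBlock, Module
from ._nn.optim import AdamW, poly_decay
from ._train_utils import TrainConfig, slices_to_array
from .boxes import (BoundingBox, augment_box_for_training, component_boxes,
                    expand_bbox, render_box_mask, tight_bbox)
from .coarse_seg import ProbabilityMap
from .errors import ConfigurationError, ExternalDependencyMissing
from .metrics_eval import dice_coefficient
from .preprocessing_io import MultiModalSlice
from .synthetic_data import PhantomCohort

__all__ = [
    "PromptSegmenter", "PromptSegConfig", "BuiltinPromptNet",
    "builtin_prompt_net", "combined_loss", "train_prompt_seg", "sam_adapter",
]

_CLIP = 1e-7


@runtime_checkable
class PromptSegmenter(Protocol):
    """Contract every fine segmenter satisfies."""

    name: str

    def segment(self, sl: MultiModalSlice, box: BoundingBox) -> ProbabilityMap:
        ...


@dataclass(frozen=True)
class PromptSegConfig:
    variant: str = "BUILTIN"              # BUILTIN | EXTERNAL_ADAPTER
    base_channels: int = 8
    freeze_policy: str = "all"            # "all" trainable | "decoder_only"
    weights_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("BUILTIN", "EXTERNAL_ADAPTER"):
            raise ConfigurationError("variant must be BUILTIN or EXTERNAL_ADAPTER")
        if self.freeze_policy not in ("all", "decoder_only"):
            raise ConfigurationError("freeze_policy must be 'all' or 'decoder_only'")
        if self.variant == "EXTERNAL_ADAPTER" and not self.weights_path:
            raise ConfigurationError("EXTERNAL_ADAPTER requires a weights_path")


class BuiltinPromptNet(Module):
    """Three-level encoder-decoder over 4 channels (image + box prompt).

    The rendered box channel is re-injected (max-pooled) at every encoder
    stage so the prompt stays visible at all scales — without this a
    desk-scale net can learn to segment from image contrast alone and
    ignore the prompt entirely.
    """

    name = "builtin-prompt-net"

    def __init__(self, config: PromptSegConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b = config.base_channels
        self.enc1 = ConvBlock(4, b, rng, use_se=False)
        self.enc2 = ConvBlock(b + 1, 2 * b, rng, use_se=False)
        self.enc3 = ConvBlock(2 * b + 1, 4 * b, rng, use_se=False)
        self.dec2 = ConvBlock(4 * b + 2 * b, 2 * b, rng, use_se=False)
        self.dec1 = ConvBlock(2 * b + b, b, rng, use_se=False)
        self.classifier = Conv2d(b, 2, 1, rng)
        # start near the background prior (see coarse_seg.CoarseUNet)
        self.classifier.b.data[:] = (2.0, -2.0)

    def encoder_parameters(self):
        return [p for m in (self.enc1, self.enc2, self.enc3) for p in m.parameters()]

    def decoder_parameters(self):
        return [p for m in (self.dec2, self.dec1, self.classifier)
                for p in m.parameters()]

    def trainable_parameters(self):
        if self.config.freeze_policy == "decoder_only":
            return self.decoder_parameters()
        return self.parameters()

    def forward(self, x) -> ad.Tensor:
        """x: (N, 4, H, W) -> per-pixel class probabilities (N, 2, H, W)."""
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(x)
        n, _, h_, w_ = x.data.shape
        prompt = ad.Tensor(x.data[:, 3:4])          # prompt needs no gradient
        prompt2 = ad.maxpool2x(prompt)
        prompt4 = ad.maxpool2x(prompt2)
        s1 = self.enc1(x)
        s2 = self.enc2(ad.concat([ad.maxpool2x(s1), prompt2], axis=1))
        h = self.enc3(ad.concat([ad.maxpool2x(s2), prompt4], axis=1))
        h = self.dec2(ad.concat([ad.upsample2x(h), s2], axis=1))
        h = self.dec1(ad.concat([ad.upsample2x(h), s1], axis=1))
        return ad.softmax(self.classifier(h), axis=1)

    __call__ = forward

    def segment(self, sl: MultiModalSlice, box: BoundingBox) -> ProbabilityMap:
        x = self._assemble(sl, box)[None]
        probs = self.forward(x)
        return ProbabilityMap(probs.data[0].transpose(1, 2, 0))

    @staticmethod
    def _assemble(sl: MultiModalSlice, box: BoundingBox) -> np.ndarray:
        h, w = sl.shape
        prompt = render_box_mask(box, h, w).astype(np.float32)
        return np.concatenate([sl.pixels.transpose(2, 0, 1), prompt[None]],
                              axis=0).astype(np.float32)


def builtin_prompt_net(config: PromptSegConfig | None = None) -> BuiltinPromptNet:
    return BuiltinPromptNet(config or PromptSegConfig())


def combined_loss(pred_fg, target, eps: float = 1e-5):
    """Binary cross-entropy plus soft Dice on the foreground channel.

    Predictions are clipped to [1e-7, 1 - 1e-7] before the logs. Tensor
    inputs keep the graph; arrays return a float.
    """
    is_tensor = isinstance(pred_fg, ad.Tensor)
    p = pred_fg if is_tensor else ad.Tensor(np.asarray(pred_fg, np.float32))
    t = target if isinstance(target, ad.Tensor) else ad.Tensor(
        np.asarray(target, np.float32))
    if p.data.shape != t.data.shape:
        raise ValueError("shape mismatch")
    p = _clip(p)
    one_m_p = ad.add(1.0, ad.mul(p, -1.0))
    bce_terms = ad.add(ad.mul(t, ad.log(p)),
                       ad.mul(ad.add(1.0, ad.mul(t, -1.0)), ad.log(one_m_p)))
    bce = ad.mul(ad.mean_all(bce_terms), -1.0)
    from .coarse_seg import dice_loss  # local import avoids a cycle at load
    dl = dice_loss(p, t, eps=eps)
    loss = ad.add(bce, dl)
    return loss if is_tensor else float(loss.data)


def _clip(x: ad.Tensor) -> ad.Tensor:
    lo, hi = _CLIP, 1.0 - _CLIP
    mask = ((x.data > lo) & (x.data < hi)).astype(np.float32)
    clipped = np.clip(x.data, lo, hi)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out = ad.Tensor(clipped)
    out.requires_grad = x.requires_grad
    if x.requires_grad:
        out._parents = (x,)
        out._backward = bwd
    return out


def _lesion_samples(pairs) -> list[tuple[MultiModalSlice, np.ndarray, BoundingBox]]:
    """One training sample per lesion component: (slice, component mask, box)."""
    samples = []
    for sl, mask in pairs:
        for box in component_boxes(mask.pixels):
            comp = np.zeros_like(mask.pixels)
            comp[box.y0:box.y1, box.x0:box.x1] = mask.pixels[box.y0:box.y1,
                                                             box.x0:box.x1]
            samples.append((sl, comp, box))
    return samples


def _negative_samples(pairs, rng: np.random.Generator, per_slice: int = 1
                      ) -> list[tuple[MultiModalSlice, np.ndarray, BoundingBox]]:
    """Boxes over lesion-free regions paired with empty targets.

    These teach the net that the prompt delimits what to segment: without
    them a strong image signal lets it ignore the box channel.
    """
    samples = []
    for sl, mask in pairs:
        h, w = mask.shape
        for _ in range(per_slice):
            for _attempt in range(20):
                bw = int(rng.integers(8, max(9, w // 3)))
                bh = int(rng.integers(8, max(9, h // 3)))
                x0 = int(rng.integers(0, w - bw))
                y0 = int(rng.integers(0, h - bh))
                box = BoundingBox(x0, y0, x0 + bw, y0 + bh)
                if not mask.pixels[box.y0:box.y1, box.x0:box.x1].any():
                    samples.append((sl, np.zeros_like(mask.pixels), box))
                    break
    return samples


def validation_dsc(net: BuiltinPromptNet, pairs, expansion_ratio: float = 0.4) -> float:
    """Mean DSC with ground-truth-derived prompts on slices carrying lesions."""
    scores = []
    for sl, mask in pairs:
        if not mask.pixels.any():
            continue
        h, w = mask.shape
        union = np.zeros((h, w), dtype=bool)
        for b in component_boxes(mask.pixels):
            pm = net.segment(sl, expand_bbox(b, expansion_ratio, w, h))
            union |= pm.binarize()
        scores.append(dice_coefficient(union, mask.pixels))
    return float(np.mean(scores)) if scores else float("nan")


def train_prompt_seg(net: BuiltinPromptNet, cohort: PhantomCohort,
                     cfg: TrainConfig) -> tuple[BuiltinPromptNet, list[dict]]:
    """Fine-tune the prompt segmenter on ground-truth-derived boxes.

    Lesion-free slices are excluded (no ground-truth box exists). Per epoch
    each lesion sample receives a freshly jittered prompt via
    ``augment_box_for_training`` (expansion 0-60%, corner shifts up to 20 px)
    when ``cfg.augment``; otherwise the 40%-expanded tight box. AdamW with
    decoupled weight decay; the best-validation-DSC checkpoint is returned.
    Only parameters allowed by the config's freeze policy are updated.
    """
    lesion_pairs = [pair for pair in cohort.slices("train")
                    if pair[1].pixels.any()]
    train_samples = _lesion_samples(lesion_pairs)
    val_pairs = [pair for pair in cohort.slices("val") if pair[1].pixels.any()]
    if not train_samples:
        raise ValueError("no training slices with lesions after filtering")
    neg_rng = np.random.default_rng([cfg.seed, 7])
    train_samples += _negative_samples(lesion_pairs, neg_rng)
    frozen = ([] if net.config.freeze_policy == "all"
              else net.encoder_parameters())
    frozen_before = [p.data.copy() for p in frozen]

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW([(net.trainable_parameters(), cfg.lr)],
                weight_decay=cfg.weight_decay)
    n = len(train_samples)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    history: list[dict] = []
    best = (-1.0, None)
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            batch = [train_samples[j] for j in order[i:i + cfg.batch_size]]
            xs, ys = [], []
            for sl, comp, box in batch:
                h, w = comp.shape
                if cfg.augment:
                    b = augment_box_for_training(box, rng, w, h)
                else:
                    b = expand_bbox(box, 0.4, w, h)
                xs.append(BuiltinPromptNet._assemble(sl, b))
                ys.append(comp.astype(np.float32))
            net.zero_grad()
            probs = net.forward(np.stack(xs))
            fg = _fg(probs)
            loss = combined_loss(fg, ad.Tensor(np.stack(ys)))
            loss.backward()
            opt.step(lr_scale=poly_decay(1.0, step, total_steps, cfg.poly_power))
            losses.append(float(loss.data))
            step += 1
        vd = validation_dsc(net, val_pairs)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dsc": vd})
        if not np.isnan(vd) and vd > best[0]:
            best = (vd, net.copy_state())
    if best[1] is not None:
        net.load_state_arrays(best[1])

    for p, before in zip(frozen, frozen_before):
        if not np.array_equal(p.data, before):
            raise RuntimeError("frozen encoder parameters changed during training")
    return net, history


def _fg(probs: ad.Tensor) -> ad.Tensor:
    from .coarse_seg import _select_fg
    return _select_fg(probs)


def sam_adapter(weights_path: str, name: str = "sam-vit-b") -> PromptSegmenter:
    """Adapter for an external SAM-style promptable model.

    Requires the external weights file plus the ``torch`` and
    ``segment_anything`` runtimes, none of which are vendored here; absent
    any of them this raises ``ExternalDependencyMissing``. When available,
    the 3-channel slice is passed as an RGB-like image and the box corner
    coordinates as the prompt, and the wrapped model is exposed behind the
    same ``PromptSegmenter`` contract as the builtin network.
    """
    import os
    if not weights_path or not os.path.exists(weights_path):
        raise ExternalDependencyMissing(
            f"external dependency missing: SAM weights not found at {weights_path!r}")
    try:
        import torch  # noqa: F401
        import segment_anything  # noqa: F401
    except ImportError as exc:
        raise ExternalDependencyMissing(
            f"external dependency missing: {exc.name} is not installed") from exc
    raise ExternalDependencyMissing(
        "external SAM adapter is an optional integration point; "
        "construct it in an environment with GPU-scale runtimes")
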