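"""Built-in prompt segmenter: contract, combined loss, freezing, adapter."""

import numpy as np
import pytest

from cascadeseg._train_utils import TrainConfig
from cascadeseg.boxes import BoundingBox, expand_bbox, tight_bbox
from cascadeseg.coarse_seg import dice_loss
from cascadeseg.errors import ExternalDependencyMissing
from cascadeseg.preprocessing_io import MultiModalSlice
from cascadeseg.prompt_seg import (PromptSegConfig, PromptSegmenter,
                                   builtin_prompt_net, combined_loss,
                                   sam_adapter, train_prompt_seg)
from cascadeseg.synthetic_data import PhantomSpec, generate_cohort


def _slice(size=64, seed=0):
    rng = np.random.default_rng(seed)
    return MultiModalSlice(pixels=rng.normal(size=(size, size, 3)),
                           spacing_mm=(1.0, 1.0))


class TestBuiltinContract:
    def test_full_image_box(self):
        net = builtin_prompt_net(PromptSegConfig(base_channels=4, seed=0))
        pm = net.segment(_slice(), BoundingBox(0, 0, 64, 64))
        assert pm.probs.shape == (64, 64, 2)
        np.testing.assert_allclose(pm.probs.sum(axis=2), 1.0, atol=1e-5)

    def test_deterministic(self):
        net = builtin_prompt_net(PromptSegConfig(base_channels=4, seed=0))
        sl = _slice(seed=3)
        box = BoundingBox(10, 12, 30, 40)
        a = net.segment(sl, box)
        b = net.segment(sl, box)
        assert np.array_equal(a.probs, b.probs)

    def test_satisfies_protocol(self):
        net = builtin_prompt_net(PromptSegConfig(base_channels=4, seed=1))
        assert isinstance(net, PromptSegmenter)


class TestCombinedLoss:
    def test_perfect_prediction_near_zero(self):
        t = (np.random.default_rng(0).random((16, 16)) > 0.8).astype(np.float32)
        p = np.clip(t, 1e-7, 1 - 1e-7)
        assert combined_loss(p, t) == pytest.approx(0.0, abs=1e-4)

    def test_uniform_half_closed_form(self):
        # BCE at p=0.5 is exactly ln 2; the Dice part adds dice_loss(0.5, t)
        t = np.zeros((10, 10), np.float32)
        t[:5] = 1.0
        p = np.full((10, 10), 0.5, np.float32)
        expected = np.log(2.0) + dice_loss(p, t)
        assert combined_loss(p, t) == pytest.approx(expected, abs=1e-5)

    def test_monotone_toward_target(self):
        rng = np.random.default_rng(4)
        t = (rng.random((12, 12)) > 0.7).astype(np.float32)
        losses = []
        for alpha in np.linspace(0.0, 0.96, 5):
            p = 0.5 + alpha * (t - 0.5)
            losses.append(combined_loss(p.astype(np.float32), t))
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_exact_binary_prediction_clipped(self):
        t = np.zeros((8, 8), np.float32)
        t[0, 0] = 1.0
        val = combined_loss(t.copy(), t)  # contains exact 0s and 1s
        assert np.isfinite(val)


@pytest.fixture(scope="module")
def easy_cohort():
    spec = PhantomSpec(image_size=64, seed=29, lesion_count_range=(1, 2))
    return generate_cohort(spec, 8, slices_per_patient=4,
                           difficulty_range=(0.0, 0.2)).normalized()


@pytest.fixture(scope="module")
def trained_prompt(easy_cohort):
    net = builtin_prompt_net(PromptSegConfig(base_channels=8, seed=2))
    net, hist = train_prompt_seg(
        net, easy_cohort,
        TrainConfig(epochs=12, batch_size=8, lr=3e-3, weight_decay=0.01,
                    seed=2))
    return net, hist


class TestTraining:

    def test_frozen_encoder_unchanged(self, easy_cohort):
        net = builtin_prompt_net(PromptSegConfig(base_channels=4, seed=0,
                                                 freeze_policy="decoder_only"))
        before = [p.data.copy() for p in net.encoder_parameters()]
        net, _ = train_prompt_seg(net, easy_cohort,
                                  TrainConfig(epochs=1, batch_size=8, seed=0))
        for a, p in zip(before, net.encoder_parameters()):
            assert np.array_equal(a, p.data)

    def test_desk_scale_dice_benchmark(self, trained_prompt):
        """A short desk-scale run reaches DSC >= 0.75 with truth-derived
        prompts on the easy validation slices."""
        _, hist = trained_prompt
        assert max(h["val_dsc"] for h in hist) >= 0.75

    def test_lesion_free_training_set_raises(self):
        spec = PhantomSpec(image_size=64, seed=31, lesion_count_range=(0, 0))
        empty = generate_cohort(spec, 4, slices_per_patient=2).normalized()
        net = builtin_prompt_net(PromptSegConfig(base_channels=4, seed=0))
        with pytest.raises(ValueError, match="lesion"):
            train_prompt_seg(net, empty, TrainConfig(epochs=1, seed=0))


class TestTrainedBehaviour:
    def test_prompt_respected(self, easy_cohort, trained_prompt):
        """Predicted foreground concentrates inside the prompt box (<20% of
        binarised mass escapes), and the correct box elicits more foreground
        probability over the lesion than a far-away box."""
        net, _ = trained_prompt
        pairs = [p for split in ("val", "test")
                 for p in easy_cohort.slices(split) if p[1].pixels.any()]
        in_fraction = []
        contrast_ok = 0
        for sl, m in pairs:
            box = expand_bbox(tight_bbox(m.pixels), 0.4, 64, 64)
            pm = net.segment(sl, box)
            predicted = pm.binarize()
            inside = predicted[box.y0:box.y1, box.x0:box.x1].sum()
            in_fraction.append(inside / max(predicted.sum(), 1))
            far = (BoundingBox(0, 0, 10, 10) if box.x0 > 12 and box.y0 > 12
                   else BoundingBox(54, 54, 64, 64))
            pm_far = net.segment(sl, far)
            good = pm.foreground[box.y0:box.y1, box.x0:box.x1].mean()
            bad = pm_far.foreground[box.y0:box.y1, box.x0:box.x1].mean()
            contrast_ok += good > bad
        assert np.mean(in_fraction) > 0.8
        assert contrast_ok / len(pairs) > 0.8


class TestSamAdapter:
    def test_missing_weights(self, tmp_path):
        with pytest.raises(ExternalDependencyMissing, match="missing"):
            sam_adapter(str(tmp_path / "sam_vit_b.pth"))
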