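"""Rejection network contracts, quality targets, MSE loss, gating."""

import numpy as np
import pytest

from cascadeseg._train_utils import TrainConfig
from cascadeseg.coarse_seg import CoarseNetConfig, build_coarse_net
from cascadeseg.errors import ConfigurationError
from cascadeseg.rejection import (GateConfig, QualityScore, RejectNetConfig,
                                  RouteDecision, build_rejection_net, gate,
                                  mse_loss, predict_scores, quality_target,
                                  train_rejection)
from cascadeseg.synthetic_data import PhantomSpec, generate_cohort


class TestBuild:
    def test_forward_scalar_per_slice(self):
        cfg = RejectNetConfig.desk_scale(in_channels=10, seed=0)
        net = build_rejection_net(cfg)
        x = np.random.default_rng(0).normal(size=(3, 10, 64, 64)).astype(np.float32)
        out = net.forward(x)
        assert out.data.shape == (3, 1)
        assert np.isfinite(out.data).all()

    def test_channel_mismatch_raises(self):
        net = build_rejection_net(RejectNetConfig.desk_scale(in_channels=10))
        with pytest.raises(ValueError, match="channels"):
            net.forward(np.zeros((1, 7, 64, 64), np.float32))

    def test_seed_determinism(self):
        a = build_rejection_net(RejectNetConfig.desk_scale(10, seed=4))
        b = build_rejection_net(RejectNetConfig.desk_scale(10, seed=4))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_head_shape_invariant(self):
        with pytest.raises(ConfigurationError):
            RejectNetConfig(head_widths=(1024, 512, 2))


class TestQualityTarget:
    def test_perfect(self):
        m = np.zeros((8, 8), bool)
        m[2:4, 2:4] = True
        assert quality_target(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = b[5, 5] = True
        assert quality_target(a, b) == 0.0

    def test_shifted_square(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[2:4, 2:4] = True
        b[2:4, 3:5] = True
        assert quality_target(a, b) == 0.5


class TestMseLoss:
    def test_zero_on_equal(self):
        assert mse_loss([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_single_term(self):
        assert mse_loss([0.5], [0.0]) == pytest.approx(0.25)

    def test_two_terms(self):
        assert mse_loss([0.2, 0.4], [0.4, 0.2]) == pytest.approx(0.04)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mse_loss([], [])


class TestGate:
    @pytest.mark.parametrize("s,t,expected", [
        (0.35, 0.4, RouteDecision.MANUAL),
        (0.45, 0.4, RouteDecision.AUTO),
        (0.40, 0.4, RouteDecision.AUTO),   # boundary is not "lower than"
    ])
    def test_strict_threshold(self, s, t, expected):
        assert gate(QualityScore(predicted=s), GateConfig(threshold=t)) is expected

    def test_limits(self):
        scores = np.random.default_rng(0).random(20)
        assert all(gate(float(s), GateConfig(threshold=0.0)) is RouteDecision.AUTO
                   for s in scores)
        assert all(gate(float(s), GateConfig(threshold=1.0)) is RouteDecision.MANUAL
                   for s in scores if s < 1.0)

    def test_above_one_routes_all_manual(self):
        cfg = GateConfig(threshold=1.01)
        assert gate(1.0, cfg) is RouteDecision.MANUAL

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            GateConfig(threshold=-0.1)


@pytest.fixture(scope="module")
def tiny_setup():
    spec = PhantomSpec(image_size=64, seed=19, lesion_count_range=(1, 2))
    cohort = generate_cohort(spec, 6, slices_per_patient=3,
                             difficulty_range=(0.1, 0.9)).normalized()
    coarse = build_coarse_net(CoarseNetConfig(base_channels=4, seed=0))
    return cohort, coarse


class TestTraining:

    def test_coarse_stays_frozen(self, tiny_setup):
        cohort, coarse = tiny_setup
        before = coarse.copy_state()
        rej = build_rejection_net(
            RejectNetConfig.desk_scale(coarse.feature_channels + 2, seed=1))
        train_rejection(rej, coarse, cohort,
                        TrainConfig(epochs=1, batch_size=8, seed=1,
                                    augment=False))
        for a, b in zip(before, coarse.state_arrays()):
            assert np.array_equal(a, b)

    def test_degenerate_constant_targets(self):
        """All-easy cohort with an untrained coarse net: targets are nearly
        constant, so the regressor collapses to that constant quickly."""
        spec = PhantomSpec(image_size=64, seed=23, lesion_count_range=(0, 0))
        cohort = generate_cohort(spec, 6, slices_per_patient=3).normalized()
        coarse = build_coarse_net(CoarseNetConfig(base_channels=4, seed=2))
        rej = build_rejection_net(
            RejectNetConfig.desk_scale(coarse.feature_channels + 2, seed=3))
        rej, hist = train_rejection(
            rej, coarse, cohort,
            TrainConfig(epochs=8, batch_size=8, lr=1e-3, seed=3, augment=False))
        assert min(h["val_mse"] for h in hist) <= 0.01

    def test_scores_clamped(self, tiny_setup):
        cohort, coarse = tiny_setup
        rej = build_rejection_net(
            RejectNetConfig.desk_scale(coarse.feature_channels + 2, seed=5))
        s = predict_scores(rej, coarse, [sl for sl, _ in cohort.slices("val")])
        assert np.all((s >= 0.0) & (s <= 1.0))
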