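"""SDI fusion, SEAM head, activations, and complexity accounting."""

import numpy as np
import pytest

from sowestrus.fusionnet import (
    REFERENCE_CHANNELS,
    REFERENCE_SE_BOTTLENECK,
    BiFPNSDINeck,
    DetectorConfig,
    SDIGate,
    SEAMHead,
    assemble_detector,
    batch_norm,
    count_complexity,
    gelu,
    reference_detect,
    sdi_fuse,
)
from sowestrus.nn import Tensor


class IdentityGate:
    """Stub gate with identity attention for closed-form fusion checks."""

    def __init__(self, alphas):
        self.alphas = Tensor(np.asarray(alphas, dtype=float), requires_grad=True)
        self.n_inputs = len(alphas)

    def attention(self, x):
        return x


class TestSDIFuse:
    def test_equal_weights_identity_attention_average(self, rng):
        a, b = Tensor(rng.normal(size=(1, 3, 4, 4))), Tensor(rng.normal(size=(1, 3, 4, 4)))
        out = sdi_fuse([a, b], IdentityGate([1.0, 1.0]))
        assert np.allclose(out.data, 0.5 * (a.data + b.data))

    def test_unequal_weights_normalised(self, rng):
        a, b = Tensor(rng.normal(size=(1, 2, 3, 3))), Tensor(rng.normal(size=(1, 2, 3, 3)))
        out = sdi_fuse([a, b], IdentityGate([3.0, 1.0]))
        assert np.allclose(out.data, 0.75 * a.data + 0.25 * b.data, atol=1e-9)

    def test_matches_loop_oracle(self, rng):
        maps = [Tensor(rng.normal(size=(2, 4, 5, 5))) for _ in range(3)]
        alphas = rng.uniform(0.1, 2.0, 3)
        out = sdi_fuse(maps, IdentityGate(alphas))
        expected = np.zeros_like(maps[0].data)
        for alpha, m in zip(alphas, maps):
            expected += (alpha / alphas.sum()) * m.data
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_scale_invariance_of_weights(self, rng):
        gate = SDIGate(4, 2, rng)
        a, b = Tensor(rng.normal(size=(1, 4, 4, 4))), Tensor(rng.normal(size=(1, 4, 4, 4)))
        gate.alphas.data[:] = [2.0, 0.5]
        out1 = sdi_fuse([a, b], gate).data
        gate.alphas.data[:] = [20.0, 5.0]
        out2 = sdi_fuse([a, b], gate).data
        assert np.allclose(out1, out2, atol=1e-9)

    def test_rejects_mismatched_shapes_and_zero_weights(self, rng):
        a = Tensor(rng.normal(size=(1, 2, 4, 4)))
        b = Tensor(rng.normal(size=(1, 2, 2, 2)))
        with pytest.raises(ValueError):
            sdi_fuse([a, b], IdentityGate([1.0, 1.0]))
        c = Tensor(rng.normal(size=(1, 2, 4, 4)))
        with pytest.raises(ValueError):
            sdi_fuse([a, c], IdentityGate([0.0, 0.0]))


class TestGelu:
    def test_fixed_points(self):
        assert gelu(np.array(0.0)) == 0.0
        assert gelu(np.array(10.0)) == pytest.approx(10.0, abs=1e-6)
        assert gelu(np.array(1.0)) == pytest.approx(0.8412, abs=1e-3)

    def test_shape_and_monotonicity(self):
        """GELU dips to a single minimum near -0.75 and rises monotonically after."""
        x = np.arange(-3.0, 3.0, 0.01)
        y = gelu(x)
        xmin = x[np.argmin(y)]
        assert -0.85 < xmin < -0.65
        right = y[x >= xmin]
        assert np.all(np.diff(right) >= 0)
        # bounded below and asymptotically identity
        assert y.min() > -0.2
        assert abs(gelu(np.array(3.0)) - 3.0) < 5e-3


class TestBatchNorm:
    def test_constant_channel_returns_beta(self):
        x = np.full((2, 1, 3, 3), 4.2)
        y = batch_norm(x, gamma=[1.0], beta=[0.7])
        assert np.allclose(y, 0.7, atol=1e-2)

    def test_standardises_each_channel(self, rng):
        x = rng.normal(3.0, 2.0, (8, 3, 6, 6))
        y = batch_norm(x, gamma=np.ones(3), beta=np.zeros(3))
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-9)
        assert np.allclose(y.var(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_hand_computed_two_by_two(self):
        x = np.array([[[[1.0, 2.0], [3.0, 4.0]]]])
        y = batch_norm(x, gamma=[2.0], beta=[1.0], eps=0.0)
        mu, sd = 2.5, np.sqrt(1.25)
        expected = 2.0 * (x - mu) / sd + 1.0
        assert np.allclose(y, expected)


class TestSEAMHead:
    def test_reference_conv_parameter_count(self, rng):
        head = SEAMHead(REFERENCE_CHANNELS, rng, project=False)
        rep = count_complexity(head)
        convs = rep.per_block["conv1"]["params"] + rep.per_block["conv2"]["params"]
        assert convs == 65792  # 384*128+128 + 128*128+128
        assert round(convs / 1e6, 3) == 0.066

    def test_zero_pyramid_gives_zero_preprojection(self, rng):
        head = SEAMHead(8, rng)
        p3 = Tensor(np.zeros((1, 8, 8, 8)))
        p4 = Tensor(np.zeros((1, 8, 4, 4)))
        p5 = Tensor(np.zeros((1, 8, 2, 2)))
        y = head.pre_projection(p3, p4, p5)
        assert np.allclose(y.data, 0.0)

    def test_output_on_concatenation_grid(self, rng):
        head = SEAMHead(8, rng)
        p3 = Tensor(np.zeros((2, 8, 12, 12)))
        p4 = Tensor(np.zeros((2, 8, 6, 6)))
        p5 = Tensor(np.zeros((2, 8, 3, 3)))
        assert head(p3, p4, p5).shape == (2, 5, 12, 12)

    def test_channel_mismatch_rejected(self, rng):
        head = SEAMHead(8, rng)
        with pytest.raises(ValueError):
            head(
                Tensor(np.zeros((1, 4, 8, 8))),
                Tensor(np.zeros((1, 8, 4, 4))),
                Tensor(np.zeros((1, 8, 2, 2))),
            )


class TestComplexity:
    def test_single_conv_count(self, rng):
        from sowestrus.nn import Conv2d

        conv = Conv2d(2, 3, 1, rng)
        assert count_complexity(conv).params == 9  # 2*3 + 3

    def test_reference_gate_and_neck_counts(self, rng):
        neck = BiFPNSDINeck(
            REFERENCE_CHANNELS, rng, bottleneck=REFERENCE_SE_BOTTLENECK
        )
        per_gate = neck.gate_t4.n_params()
        assert abs(per_gate - 24600) <= 500
        assert round(count_complexity(neck).params / 1e6, 2) == 0.12

    def test_totals_equal_block_sums(self, rng):
        det = assemble_detector(DetectorConfig(image_size=64))
        rep = count_complexity(det, (64, 64))
        assert rep.params == sum(e["params"] for e in rep.per_block.values())
        assert rep.flops == sum(e["flops"] for e in rep.per_block.values())
        assert rep.params == det.n_params()


class TestDetector:
    def test_eval_forward_is_deterministic(self, clean_scenes):
        det = assemble_detector(DetectorConfig(image_size=96))
        _, img, _ = clean_scenes[0]
        p1 = det.predict(img)
        p2 = det.predict(img)
        assert [(b.to_pixels(), c) for b, c in p1] == [
            (b.to_pixels(), c) for b, c in p2
        ]

    def test_inconsistent_widths_rejected(self):
        with pytest.raises(ValueError):
            assemble_detector(DetectorConfig(image_size=50))
        with pytest.raises(ValueError):
            assemble_detector(
                DetectorConfig(backbone_widths=(8, 16, 24))
            )

    def test_checkpoint_round_trip(self, tmp_path, clean_scenes):
        cfg = DetectorConfig(image_size=96, seed=3)
        det = assemble_detector(cfg)
        det.save(tmp_path / "det.npz")
        det2 = assemble_detector(DetectorConfig(image_size=96, seed=4))
        det2 = det2.load(tmp_path / "det.npz", cfg)
        _, img, _ = clean_scenes[2]
        assert det.predict(img) == det2.predict(img)

    def test_reference_detector_localises_clean_scenes(self, clean_scenes):
        from sowestrus.evalstats import iou

        hits = 0
        usable = 0
        for spec, img, truth in clean_scenes:
            if spec.region_saturation < 55:
                continue
            usable += 1
            dets = reference_detect(img)
            if dets and iou(dets[0][0].to_pixels(), truth.box.to_pixels()) > 0.5:
                hits += 1
        assert hits / usable >= 0.8
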