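"""MLP classifier: forward oracle, training behaviour, L1 pruning."""

import numpy as np
import pytest

from sowestrus.estrus_mlp import (
    MLPModel,
    Normalizer,
    PruneSpec,
    TrainConfig,
    fine_tune,
    forward,
    l1_prune,
    train,
)
from sowestrus.scenegen import FEATURE_STATS


def synthetic_features(n, estrus_fraction, rng):
    n1 = int(round(n * estrus_fraction))
    rows, labels = [], []
    for label, count in (("estrus", n1), ("non_estrus", n - n1)):
        stats = FEATURE_STATS[label]
        ar = rng.normal(*stats["aspect_ratio"], count)
        sat = rng.normal(*stats["saturation"], count)
        rows.append(np.c_[ar, sat])
        labels.append(np.full(count, 1.0 if label == "estrus" else 0.0))
    x = np.concatenate(rows)
    y = np.concatenate(labels)
    perm = rng.permutation(n)
    return x[perm], y[perm]


class TestForward:
    def test_zero_weights_give_half(self):
        model = MLPModel((2, 4, 1), np.random.default_rng(0))
        for layer in model.layers:
            layer.weight.data[...] = 0.0
            layer.bias.data[...] = 0.0
        assert forward(model, [0.3, 0.8]) == pytest.approx(0.5)

    def test_single_linear_layer_arithmetic(self):
        model = MLPModel((2, 1), np.random.default_rng(0))
        model.layers[0].weight.data[...] = np.array([[1.0], [0.0]])
        model.layers[0].bias.data[...] = 0.0
        assert forward(model, [0.0, 0.77]) == pytest.approx(0.5)

    def test_matches_hand_rolled_matrix_oracle(self, rng):
        model = MLPModel((2, 16, 8, 1), rng)
        x = rng.random((5, 2))
        p = forward(model, x)
        h = x
        for layer in model.layers[:-1]:
            h = np.maximum(h @ layer.weight.data + layer.bias.data, 0.0)
        z = h @ model.layers[-1].weight.data + model.layers[-1].bias.data
        oracle = 1 / (1 + np.exp(-z.reshape(-1)))
        assert np.allclose(p, oracle, atol=1e-6)

    def test_out_of_range_features_clipped_with_warning(self):
        model = MLPModel((2, 1), np.random.default_rng(0))
        norm = Normalizer(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.warns(UserWarning):
            forward(model, [[2.0, -1.0]], norm)


class TestTrain:
    def test_separates_published_feature_distributions(self, rng):
        """Test accuracy approaches the Bayes rate of the two bivariate normals
        (~0.79 at 30% prevalence on held-out data)."""
        x, y = synthetic_features(2000, 0.3, rng)
        model, norm = train(x[:1500], y[:1500], TrainConfig(epochs=120), seed=0)
        p = forward(model, x[1500:], norm)
        acc = ((p >= 0.5) == y[1500:].astype(bool)).mean()
        assert acc >= 0.75

    def test_linearly_separable_toy_set(self, rng):
        x = np.r_[rng.normal(0.2, 0.05, (50, 2)), rng.normal(0.8, 0.05, (50, 2))]
        y = np.r_[np.zeros(50), np.ones(50)]
        model, norm = train(x, y, TrainConfig(epochs=150), seed=1)
        acc = ((forward(model, x, norm) >= 0.5) == y.astype(bool)).mean()
        assert acc == 1.0

    def test_deterministic_under_seed(self, rng):
        x, y = synthetic_features(200, 0.4, rng)
        m1, _ = train(x, y, TrainConfig(epochs=20), seed=3)
        m2, _ = train(x, y, TrainConfig(epochs=20), seed=3)
        for l1, l2 in zip(m1.layers, m2.layers):
            assert np.array_equal(l1.weight.data, l2.weight.data)

    def test_single_class_rejected(self, rng):
        x = rng.random((20, 2))
        with pytest.raises(ValueError):
            train(x, np.ones(20))


class TestPrune:
    def test_zero_threshold_keeps_nonzero_weights(self, rng):
        model = MLPModel((2, 4, 1), rng)
        before = [w.copy() for w in model.weight_arrays()]
        l1_prune(model, PruneSpec(threshold=0.0))
        for b, a in zip(before, model.weight_arrays()):
            assert np.array_equal(b, a)

    def test_direct_threshold_application(self):
        model = MLPModel((3, 1), np.random.default_rng(0))
        model.layers[0].weight.data[...] = np.array([[0.1], [-0.5], [0.01]])
        l1_prune(model, PruneSpec(threshold=0.05))
        assert np.array_equal(
            model.layers[0].weight.data, np.array([[0.1], [-0.5], [0.0]])
        )

    def test_excessive_threshold_rejected(self, rng):
        model = MLPModel((2, 4, 1), rng)
        with pytest.raises(ValueError):
            l1_prune(model, PruneSpec(threshold=1e6))

    def test_sparsity_monotone_in_threshold(self, rng):
        fractions = []
        for lam in (0.01, 0.05, 0.1, 0.3):
            model = MLPModel((2, 16, 8, 1), np.random.default_rng(5))
            try:
                _, report = l1_prune(model, PruneSpec(threshold=lam))
                fractions.append(report["overall_zero_fraction"])
            except ValueError:
                fractions.append(1.0)
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_half_sparsity_plus_finetune_preserves_accuracy(self, rng):
        """Pruning 50% of weights then fine-tuning costs <= 2 accuracy points
        (median over 3 seeds)."""
        x, y = synthetic_features(1200, 0.3, rng)
        xtr, ytr, xte, yte = x[:900], y[:900], x[900:], y[900:]
        drops = []
        for seed in range(3):
            model, norm = train(xtr, ytr, TrainConfig(epochs=100), seed=seed)
            acc0 = ((forward(model, xte, norm) >= 0.5) == yte.astype(bool)).mean()
            model, _ = l1_prune(model, PruneSpec(sparsity=0.5))
            fine_tune(model, norm, xtr, ytr, epochs=30, seed=seed)
            acc1 = ((forward(model, xte, norm) >= 0.5) == yte.astype(bool)).mean()
            drops.append(acc0 - acc1)
        assert np.median(drops) <= 0.02

    def test_masks_survive_fine_tuning(self, rng):
        x, y = synthetic_features(300, 0.4, rng)
        model, norm = train(x, y, TrainConfig(epochs=30), seed=0)
        model, report = l1_prune(model, PruneSpec(sparsity=0.5))
        fine_tune(model, norm, x, y, epochs=10, seed=0)
        zeros = sum((w == 0).sum() for w in model.weight_arrays())
        total = sum(w.size for w in model.weight_arrays())
        assert zeros / total == pytest.approx(report["overall_zero_fraction"], abs=1e-9)


def test_logit_lipschitz_bound_on_grid(rng):
    """With bounded weights the logit is Lipschitz: |dz| <= prod_l ||W_l||_inf."""
    model = MLPModel((2, 8, 1), rng)
    bound = 1.0
    for layer in model.layers:
        bound *= np.abs(layer.weight.data).sum(axis=0).max()
    grid = np.linspace(0, 1, 11)
    pts = np.array([[a, b] for a in grid for b in grid])
    from sowestrus.nn import Tensor

    z = model.logits(Tensor(pts)).data.reshape(-1)
    for step in (1, 11):  # neighbours along each axis
        dz = np.abs(z[step:] - z[:-step])
        dx = np.abs(pts[step:] - pts[:-step]).sum(axis=1)
        ok = dz <= bound * dx + 1e-9
        assert ok.all()
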