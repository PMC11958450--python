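"""Step-2 synthesis: weight transfer, freezing, ancestral sampling."""

import numpy as np
import pytest

from dagaf.fcm import FcmGenerator, InverseNet
from dagaf.graphs import BinaryDag
from dagaf.synthesize import (SynthConfig, fit_forward_g, sample,
                              train_synthesizer, transfer_weights)


def chain_dag(d=2):
    e = np.zeros((d, d), dtype=int)
    for j in range(1, d):
        e[j, j - 1] = 1
    return BinaryDag(e)


def linear_chain_generator(b=1.5):
    """LiNGAM generator hand-wired to f_1(X) = b·X_0."""
    gen = FcmGenerator(d=2, h=2, assumption="lingam", seed=0)
    for p in gen.parameters():
        p.data[...] = 0.0
    gen.W1.data[1, 0, 0] = b
    gen.W2.data[1, 0, 0] = 1.0
    return gen


class TestTransferWeights:
    def test_l0_copied_exactly(self):
        src = FcmGenerator(d=3, seed=5)
        bundle = transfer_weights(src, BinaryDag(np.zeros((3, 3), dtype=int)),
                                  seed=9)
        np.testing.assert_array_equal(bundle.generator.W1.data, src.W1.data)

    def test_hidden_layers_reinitialized(self):
        src = FcmGenerator(d=3, seed=5)
        bundle = transfer_weights(src, BinaryDag(np.zeros((3, 3), dtype=int)),
                                  seed=9)
        assert not np.array_equal(bundle.generator.W2.data, src.W2.data)

    def test_l0_frozen_through_training(self):
        rng = np.random.default_rng(0)
        src = FcmGenerator(d=2, seed=1)
        bundle = transfer_weights(src, chain_dag(), seed=2)
        h0 = bundle.l0_hash()
        X = rng.normal(size=(200, 2))
        train_synthesizer(bundle, X, SynthConfig(epochs=10, batch=100,
                                                 n_critic=1, seed=3))
        assert bundle.l0_hash() == h0
        np.testing.assert_array_equal(bundle.generator.W1.data, src.W1.data)

    def test_l0_receives_no_gradient(self):
        src = FcmGenerator(d=2, seed=1)
        bundle = transfer_weights(src, chain_dag(), seed=2)
        assert not bundle.generator.W1.requires_grad
        assert bundle.generator.W1 not in bundle.generator.mechanism_parameters()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transfer_weights(FcmGenerator(d=3, seed=0),
                             BinaryDag(np.zeros((2, 2), dtype=int)))


class TestSample:
    def test_empty_graph_zero_mechanisms_pure_noise(self):
        gen = FcmGenerator(d=3, seed=0)
        for p in gen.parameters():
            p.data[...] = 0.0
        bundle = transfer_weights(gen, BinaryDag(np.zeros((3, 3), dtype=int)),
                                  seed=1)
        for p in bundle.generator.parameters():
            p.data[...] = 0.0
        X = sample(bundle, n=500, seed=42)
        Z = np.random.default_rng(42).normal(0.0, 1.0, size=(500, 3))
        np.testing.assert_allclose(X, Z, atol=1e-12)

    def test_chain_slope_recovered_by_regression(self):
        """Ancestral sampling through X1 = b·X0 + Z: OLS of col 1 on col 0
        recovers b within sampling error (n = 10⁴)."""
        b = 1.5
        bundle = transfer_weights(linear_chain_generator(b), chain_dag(), seed=0)
        bundle.generator.W1.data[1, 0, 0] = b  # keep the wired mechanism
        bundle.generator.W2.data[1, 0, 0] = 1.0
        X = sample(bundle, n=10_000, seed=7)
        slope = np.polyfit(X[:, 0], X[:, 1], 1)[0]
        # var(X0)=1 → se(slope) ≈ 1/sqrt(n)
        assert slope == pytest.approx(b, abs=4 / np.sqrt(10_000))

    def test_same_seed_identical(self):
        bundle = transfer_weights(FcmGenerator(d=3, seed=3),
                                  BinaryDag(np.zeros((3, 3), dtype=int)), seed=4)
        np.testing.assert_array_equal(sample(bundle, 50, seed=5),
                                      sample(bundle, 50, seed=5))

    def test_ancestral_covariance_matches_closed_form(self):
        """True linear SEM loaded into the generator reproduces
        Cov = (I−A)⁻¹ Σ (I−A)⁻ᵀ (row = child convention)."""
        A = np.zeros((3, 3))
        A[1, 0] = 0.8
        A[2, 1] = -1.2
        gen = FcmGenerator(d=3, h=3, assumption="lingam", seed=0)
        for p in gen.parameters():
            p.data[...] = 0.0
        for j in range(3):
            for k in range(3):
                gen.W1.data[j, k, 0] = A[j, k]
            gen.W2.data[j, 0, 0] = 1.0
        e = np.zeros((3, 3), dtype=int)
        e[1, 0] = e[2, 1] = 1
        bundle = transfer_weights(gen, BinaryDag(e), seed=1)
        for j in range(3):
            bundle.generator.W1.data[j, :, 0] = A[j]
            bundle.generator.W2.data[j, 0, 0] = 1.0
            bundle.generator.b1.data[...] = 0.0
            bundle.generator.b2.data[...] = 0.0
        X = sample(bundle, n=40_000, seed=11)
        IA = np.linalg.inv(np.eye(3) - A)
        target = IA @ IA.T
        emp = np.cov(X, rowvar=False)
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)))
        assert np.max(np.abs(emp - target) / scale) < 0.05

    def test_invalid_n(self):
        bundle = transfer_weights(FcmGenerator(d=2, seed=0), chain_dag(), seed=0)
        with pytest.raises(ValueError):
            sample(bundle, 0)


class TestTrainSynthesizer:
    def test_zero_epochs_bundle_unchanged(self):
        src = FcmGenerator(d=2, seed=0)
        bundle = transfer_weights(src, chain_dag(), seed=1)
        before = [p.data.copy() for p in bundle.generator.parameters()]
        train_synthesizer(bundle, np.random.default_rng(0).normal(size=(50, 2)),
                          SynthConfig(epochs=0))
        for p, b in zip(bundle.generator.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_univariate_mean_matched(self):
        """d=1: after adversarial training the generated marginal mean sits
        within a few standard errors of the real mean."""
        rng = np.random.default_rng(1)
        X = rng.normal(loc=1.0, size=(500, 1))
        src = FcmGenerator(d=1, seed=2)
        bundle = transfer_weights(src, BinaryDag(np.zeros((1, 1), dtype=int)),
                                  seed=3)
        train_synthesizer(bundle, X, SynthConfig(epochs=200, batch=250,
                                                 n_critic=5, seed=4))
        S = sample(bundle, 2000, seed=5)
        se = X.std() / np.sqrt(len(X))
        assert abs(S.mean() - X.mean()) < 3 * se + 0.1

    def test_shape_mismatch_rejected(self):
        bundle = transfer_weights(FcmGenerator(d=2, seed=0), chain_dag(), seed=1)
        with pytest.raises(ValueError):
            train_synthesizer(bundle, np.zeros((10, 3)))


class TestNumericInversion:
    def test_bisection_inverts_learned_inverse(self):
        """g obtained by monotone bisection satisfies g⁻¹(g(t)) ≈ t."""
        from dagaf.synthesize import _invert_monotone
        inv = InverseNet(d=3, seed=5)  # near-identity, monotone in practice
        target = np.linspace(-2.0, 2.0, 11).reshape(-1, 1)
        x = _invert_monotone(inv, target, j=1, d=3)
        full = np.zeros((11, 3))
        full[:, 1] = x.ravel()
        back = inv.forward(full).data[:, 1]
        np.testing.assert_allclose(back, target.ravel(), atol=1e-6)

    def test_sampling_uses_numeric_inversion_without_forward_g(self):
        src = FcmGenerator(d=2, assumption="pnl", seed=0)
        inv = InverseNet(d=2, seed=1)
        bundle = transfer_weights(src, chain_dag(), seed=2, inverse=inv)
        assert bundle.forward_g is None
        X = sample(bundle, 50, seed=3)
        assert X.shape == (50, 2) and np.all(np.isfinite(X))


class TestForwardG:
    def test_fit_forward_inverts_learned_inverse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 2))
        inv = InverseNet(d=2, seed=1)
        src = FcmGenerator(d=2, assumption="pnl", seed=2)
        bundle = transfer_weights(src, chain_dag(), seed=3)
        g = fit_forward_g(bundle, inv, X, epochs=150, seed=4)
        X_hat = inv.forward(X).data
        rec = g.forward(X_hat).data
        assert np.mean((rec - X) ** 2) < 0.05
        assert bundle.forward_g is g
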