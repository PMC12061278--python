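"""Slide and omics encoder contracts."""

import numpy as np
import pytest

from bridgemil.config import EncoderConfig
from bridgemil.encoders import (GatedAttentionEncoder, SNNEncoder,
                                TransMILEncoder, minmax_normalize)
from bridgemil.io import PatchBag


def _cfg(**kw):
    base = dict(patch_dim=16, d_wsi=16, n_heads=2, n_landmarks=4,
                d_omics=8, snn_hidden=8)
    base.update(kw)
    return EncoderConfig(**base)


def _bag(n, d=16, seed=0):
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(2 * n)))
    flat = rng.choice(side * side, size=n, replace=False)
    coords = np.column_stack([flat % side, flat // side])
    return PatchBag(f"B{n}", rng.standard_normal((n, d)), coords)


class TestTransMIL:
    def test_attention_length_matches_bag(self):
        # N=10 pads internally to 16 tokens but attention is truncated
        enc = TransMILEncoder(_cfg(), np.random.default_rng(0))
        emb = enc.encode_slide(_bag(10))
        assert len(emb.attention) == 10
        assert emb.vector.shape == (16,)

    def test_eval_determinism(self):
        bag = _bag(9)
        enc = TransMILEncoder(_cfg(), np.random.default_rng(1))
        a = enc.encode_slide(bag)
        b = enc.encode_slide(bag)
        assert (a.vector == b.vector).all()
        assert (a.attention == b.attention).all()

    def test_attention_minmax_normalized(self):
        enc = TransMILEncoder(_cfg(), np.random.default_rng(2))
        att = enc.encode_slide(_bag(12)).attention
        assert att.min() == pytest.approx(0.0)
        assert att.max() == pytest.approx(1.0)

    def test_positional_encoding_breaks_permutation_invariance(self):
        rng = np.random.default_rng(3)
        enc = TransMILEncoder(_cfg(use_ppeg=True), np.random.default_rng(4))
        bag = _bag(16)   # perfect square: no padding confound
        perm = rng.permutation(16)
        shuffled = PatchBag(bag.patient_id, bag.features[perm],
                            bag.coords[perm])
        a = enc.encode_slide(bag).vector
        b = enc.encode_slide(shuffled).vector
        assert not np.allclose(a, b)

    def test_no_ppeg_is_permutation_invariant(self):
        # exact-attention path (enough landmarks) and a perfect-square bag:
        # no padding, no positional encoding -> order cannot matter
        rng = np.random.default_rng(5)
        enc = TransMILEncoder(_cfg(use_ppeg=False, n_landmarks=8),
                              np.random.default_rng(6))
        bag = _bag(16)
        perm = rng.permutation(16)
        shuffled = PatchBag(bag.patient_id, bag.features[perm],
                            bag.coords[perm])
        a = enc.encode_slide(bag).vector
        b = enc.encode_slide(shuffled).vector
        assert np.allclose(a, b, atol=1e-10)

    def test_single_patch_bag(self):
        enc = TransMILEncoder(_cfg(), np.random.default_rng(7))
        emb = enc.encode_slide(_bag(1))
        assert np.isfinite(emb.vector).all()


class TestGatedAttention:
    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        enc = GatedAttentionEncoder(_cfg(), np.random.default_rng(9))
        bag = _bag(11)
        perm = rng.permutation(11)
        shuffled = PatchBag(bag.patient_id, bag.features[perm],
                            bag.coords[perm])
        assert np.allclose(enc.encode_slide(bag).vector,
                           enc.encode_slide(shuffled).vector)


class TestSNN:
    def test_eval_deterministic(self):
        enc = SNNEncoder(20, _cfg(), np.random.default_rng(10))
        x = np.random.default_rng(11).standard_normal(20)
        a = enc.encode_omics("P", x).vector
        b = enc.encode_omics("P", x).vector
        assert (a == b).all()

    def test_self_normalizing_hidden_variance(self):
        # untrained net on standardized Gaussian input keeps activations
        # near unit variance (the SELU fixed point)
        from bridgemil.nn import Tensor
        enc = SNNEncoder(512, _cfg(snn_hidden=256), np.random.default_rng(12))
        enc.eval()
        x = np.random.default_rng(13).standard_normal((512, 512))
        h = enc.block1(Tensor(x))
        var = h.data.var(axis=0).mean()
        assert 0.5 < var < 1.5

    def test_zero_input_finite(self):
        enc = SNNEncoder(20, _cfg(), np.random.default_rng(14))
        out = enc.encode_omics("P", np.zeros(20)).vector
        assert np.isfinite(out).all()

    def test_feature_mismatch_raises(self):
        enc = SNNEncoder(20, _cfg(), np.random.default_rng(15))
        with pytest.raises(ValueError, match="features"):
            enc.forward(np.zeros((1, 19)))

    def test_dropout_active_only_in_training(self):
        enc = SNNEncoder(20, _cfg(snn_dropout=0.5),
                         np.random.default_rng(16))
        x = np.random.default_rng(17).standard_normal((1, 20))
        enc.train()
        a = enc.forward(x).data
        b = enc.forward(x).data
        assert not np.allclose(a, b)
        enc.eval()
        c = enc.forward(x).data
        d = enc.forward(x).data
        assert (c == d).all()


def test_minmax_constant_scores_are_zeroed():
    assert (minmax_normalize(np.full(5, 3.0)) == 0).all()
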