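import numpy as np
import pytest

from affinet.nn import BlockDims, ModelConfig, PairTransformer
from affinet.nn import autodiff as ad
from affinet.nn.autodiff import Tensor
from affinet.nn.layers import BinaryEmbedding, ContinuousEmbedding, PeriodicEmbedding
from affinet.nn.training import logcosh_loss


@pytest.fixture
def small_model():
    dims = BlockDims(6, 8, 5, 3)
    cfg = ModelConfig(d=16, heads=2, n_separate=2, n_joint=1, d_ffn=32,
                      k_periodic=3, seed=0)
    return PairTransformer(dims, cfg), dims, cfg


def _random_inputs(dims, B=4, seed=0):
    rng = np.random.default_rng(seed)
    return (
        rng.normal(size=(B, dims.compound_continuous)),
        rng.integers(0, 2, (B, dims.compound_binary)).astype(float),
        rng.normal(size=(B, dims.protein_continuous)),
        rng.integers(0, 2, (B, dims.protein_binary)).astype(float),
    )


class TestPeriodicEmbedding:
    def test_zero_input_gives_sin_zero_cos_one(self):
        rng = np.random.default_rng(0)
        emb = PeriodicEmbedding(4, k=3, sigma=0.5, rng=rng)
        out = emb(Tensor(np.zeros((2, 4)))).data
        np.testing.assert_allclose(out[..., :3], 0.0, atol=1e-15)
        np.testing.assert_allclose(out[..., 3:], 1.0, atol=1e-15)

    def test_output_shape_n_by_2k(self):
        emb = PeriodicEmbedding(5, k=4, sigma=0.1, rng=np.random.default_rng(0))
        assert emb(Tensor(np.zeros((3, 5)))).shape == (3, 5, 8)

    def test_unit_period_for_integer_coefficients(self):
        emb = PeriodicEmbedding(1, k=1, sigma=1.0, rng=np.random.default_rng(0))
        emb.coeffs.data[:] = 1.0  # c = 1 -> sin/cos(2 pi x) has period 1
        x = np.array([[0.3]])
        a = emb(Tensor(x)).data
        b = emb(Tensor(x + 1.0)).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        emb = PeriodicEmbedding(4, k=2, sigma=0.1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            emb(Tensor(np.zeros((2, 5))))


class TestContinuousEmbedding:
    def test_relu_makes_outputs_nonnegative(self):
        emb = ContinuousEmbedding(3, k=2, sigma=0.3, d=8,
                                  rng=np.random.default_rng(1))
        out = emb(Tensor(np.random.default_rng(0).normal(size=(5, 3))))
        assert (out.data >= 0).all()

    def test_zero_weights_give_zero_output(self):
        emb = ContinuousEmbedding(3, k=2, sigma=0.3, d=8,
                                  rng=np.random.default_rng(1))
        emb.weight.data[:] = 0.0
        emb.bias.data[:] = 0.0
        out = emb(Tensor(np.ones((2, 3))))
        assert np.all(out.data == 0)

    def test_no_weight_sharing_between_features(self):
        emb = ContinuousEmbedding(2, k=2, sigma=0.3, d=4,
                                  rng=np.random.default_rng(1))
        x = np.full((1, 2), 0.7)  # identical values, distinct per-feature maps
        out = emb(Tensor(x)).data
        assert not np.allclose(out[0, 0], out[0, 1])


class TestBinaryEmbedding:
    def test_lookup_rows(self):
        emb = BinaryEmbedding(3, d=4, rng=np.random.default_rng(0))
        zeros = emb(Tensor(np.zeros((1, 3)))).data[0]
        ones = emb(Tensor(np.ones((1, 3)))).data[0]
        np.testing.assert_allclose(zeros, emb.table0.data)
        np.testing.assert_allclose(ones, emb.table1.data)

    def test_flipping_one_bit_changes_exactly_one_row(self):
        emb = BinaryEmbedding(5, d=4, rng=np.random.default_rng(0))
        bits = np.zeros((1, 5))
        flipped = bits.copy()
        flipped[0, 2] = 1.0
        a = emb(Tensor(bits)).data[0]
        b = emb(Tensor(flipped)).data[0]
        changed = [i for i in range(5) if not np.allclose(a[i], b[i])]
        assert changed == [2]

    def test_nonbinary_input_rejected(self):
        emb = BinaryEmbedding(2, d=4, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            emb(Tensor(np.full((1, 2), 0.5)))


class TestEncode:
    def test_output_is_scalar_per_pair(self, small_model):
        model, dims, _ = small_model
        out = model.predict(*_random_inputs(dims))
        assert out.shape == (4,)
        assert np.isfinite(out).all()

    def test_eval_mode_deterministic(self, small_model):
        model, dims, _ = small_model
        x = _random_inputs(dims)
        assert np.array_equal(model.predict(*x), model.predict(*x))

    def test_token_set_equivariance(self, small_model):
        """Permuting feature rows together with their per-feature parameters
        leaves the CLS outputs unchanged (no positional encoding)."""
        model, dims, _ = small_model
        x = _random_inputs(dims)
        base = model.predict(*x)
        perm = np.random.default_rng(5).permutation(dims.compound_continuous)
        x_perm = (x[0][:, perm], x[1], x[2], x[3])
        model.embed_cc.periodic.coeffs.data = model.embed_cc.periodic.coeffs.data[perm]
        model.embed_cc.weight.data = model.embed_cc.weight.data[perm]
        model.embed_cc.bias.data = model.embed_cc.bias.data[perm]
        np.testing.assert_allclose(model.predict(*x_perm), base, atol=1e-10)

    def test_prediction_head_bias_passthrough(self, small_model):
        model, dims, _ = small_model
        model.head_linear.weight.data[:] = 0.0
        model.head_linear.bias.data[:] = 3.25
        out = model.predict(*_random_inputs(dims))
        np.testing.assert_allclose(out, 3.25)

    def test_gradients_reach_every_parameter_group(self, small_model):
        model, dims, _ = small_model
        x = _random_inputs(dims, B=8)
        y = np.random.default_rng(0).normal(size=8)
        pred = model.forward(*x, training=True)
        loss = logcosh_loss(Tensor(y), pred)
        loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            # every top-level component should receive some signal
        grads = [np.abs(p.grad).max() for p in model.parameters()]
        assert np.median(grads) > 0

    def test_reproducible_from_config_and_seed(self):
        dims = BlockDims(3, 4, 3, 2)
        cfg = ModelConfig(d=8, heads=2, n_separate=1, n_joint=1, d_ffn=16, seed=7)
        a = PairTransformer(dims, cfg).state_dict()
        b = PairTransformer(dims, cfg).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(d=30, heads=4)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)
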