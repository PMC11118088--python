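import numpy as np
import pytest

from vesselseg import autodiff as ad
from vesselseg.autodiff import Tensor
from vesselseg.errors import ConfigurationError, DimensionError
from vesselseg.swin_core import (
    LinearEmbedding,
    PatchExpanding,
    PatchMerging,
    StageConfig,
    SwinStage,
    patch_partition,
)


class TestPatchPartition:
    def test_headline_shape(self):
        out = patch_partition(np.zeros((448, 448, 3), np.float32), 4)
        assert out.shape == (112, 112, 48)

    def test_constant_image_gives_constant_tokens(self):
        out = patch_partition(np.full((8, 8, 3), 1.5, np.float32), 4)
        np.testing.assert_array_equal(out, 1.5)

    def test_is_a_bijective_rearrangement(self):
        img = np.arange(8 * 8 * 3, dtype=np.float32).reshape(8, 8, 3)
        out = patch_partition(img, 4)
        assert out.shape == (2, 2, 48)
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_patch_content_matches_block(self):
        img = np.arange(8 * 8 * 3, dtype=np.float32).reshape(8, 8, 3)
        out = patch_partition(img, 4)
        np.testing.assert_array_equal(out[0, 1], img[0:4, 4:8, :].reshape(-1))

    @pytest.mark.parametrize("shape,msg", [((9, 8, 3), "height"), ((8, 10, 3), "width")])
    def test_non_divisible_axis_is_named(self, shape, msg):
        with pytest.raises(DimensionError, match=msg):
            patch_partition(np.zeros(shape, np.float32), 4)


class TestLinearEmbedding:
    def test_shape_contract(self, rng):
        emb = LinearEmbedding(48, 96).init(rng)
        out = emb(Tensor(np.zeros((1, 112, 112, 48), np.float32)))
        assert out.shape == (1, 112, 112, 96)

    def test_wrong_input_dim_raises(self, rng):
        emb = LinearEmbedding(48, 96).init(rng)
        with pytest.raises(DimensionError):
            emb(Tensor(np.zeros((1, 4, 4, 47), np.float32)))

    def test_zero_input_zero_bias_gives_zero(self, rng):
        emb = LinearEmbedding(48, 96).init(rng)
        out = emb(Tensor(np.zeros((1, 4, 4, 48), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)


class TestSwinStage:
    def _stage(self, dim=8, window=2, heads=2, depth=1, seed=0):
        return SwinStage(dim, StageConfig(depth, heads, window)).init(np.random.default_rng(seed))

    def test_shape_preserving(self, rng):
        st = self._stage()
        x = rng.standard_normal((2, 8, 8, 8)).astype(np.float32)
        assert st(Tensor(x)).shape == (2, 8, 8, 8)

    def test_zeroed_residual_branches_is_identity(self, rng):
        st = self._stage()
        for b in st.blocks:
            b.attn.proj.weight.data[:] = 0
            b.attn.proj.bias.data[:] = 0
            b.mlp.fc2.weight.data[:] = 0
            b.mlp.fc2.bias.data[:] = 0
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(st(Tensor(x)).data, x, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        st = self._stage()
        xw = rng.standard_normal((4, 4, 8)).astype(np.float32)
        attn = st.blocks[0].attn.attention_weights(xw)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)

    def test_window_must_divide_grid(self, rng):
        st = self._stage(window=2)
        with pytest.raises(DimensionError):
            st(Tensor(rng.standard_normal((1, 6, 7, 8)).astype(np.float32)))

    def test_bad_heads_rejected_at_build(self):
        with pytest.raises(ConfigurationError):
            SwinStage(8, StageConfig(1, 3, 2))

    def test_shifted_block_mixes_across_windows(self, rng):
        """With a shift, tokens outside a window influence its output."""
        st = self._stage(depth=1)
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        base = st(Tensor(x)).data
        x2 = x.copy()
        x2[0, 2, 2, 0] += 10.0  # different base window, adjacent to (1, 1)
        out2 = st(Tensor(x2)).data
        assert np.abs(out2[0, 1, 1] - base[0, 1, 1]).max() > 1e-4


class TestMergeExpand:
    def test_merging_shapes(self, rng):
        m = PatchMerging(96).init(rng)
        assert m(Tensor(np.zeros((1, 112, 112, 96), np.float32))).shape == (1, 56, 56, 192)
        m2 = PatchMerging(192).init(rng)
        assert m2(Tensor(np.zeros((1, 56, 56, 192), np.float32))).shape == (1, 28, 28, 384)

    def test_merging_zero_input_zero_output(self, rng):
        m = PatchMerging(8).init(rng)
        out = m(Tensor(np.zeros((1, 4, 4, 8), np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_merging_odd_dims_rejected(self, rng):
        m = PatchMerging(8).init(rng)
        with pytest.raises(DimensionError):
            m(Tensor(np.zeros((1, 5, 4, 8), np.float32)))

    def test_expanding_shapes(self, rng):
        e = PatchExpanding(384, 2).init(rng)
        assert e(Tensor(np.zeros((1, 28, 28, 384), np.float32))).shape == (1, 56, 56, 192)
        e4 = PatchExpanding(96, 4).init(rng)
        assert e4(Tensor(np.zeros((1, 4, 4, 96), np.float32))).shape == (1, 16, 16, 96)

    def test_expanding_zero_input_zero_output(self, rng):
        e = PatchExpanding(8, 2).init(rng)
        np.testing.assert_array_equal(e(Tensor(np.zeros((1, 4, 4, 8), np.float32))).data, 0.0)

    def test_merge_then_expand_restores_shape(self, rng):
        m = PatchMerging(8).init(rng)
        e = PatchExpanding(16, 2).init(rng)
        x = Tensor(rng.standard_normal((1, 4, 4, 8)).astype(np.float32))
        assert e(m(x)).shape == x.shape

    def test_expanding_odd_dim_rejected(self):
        with pytest.raises(DimensionError):
            PatchExpanding(7, 2)
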