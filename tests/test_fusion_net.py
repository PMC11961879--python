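"""Network family: fusion-module algebra, shapes, determinism, checkpoints."""

import numpy as np
import pytest

from mdoseqa import nn
from mdoseqa.fusion_net import (
    CCFusion,
    CPFusion,
    DecoderFuse,
    FusionNet,
    ModelConfig,
    SCFusion,
    SPFusion,
    build_model,
    decoder_fuse,
    fuse_ccf,
    fuse_cpf,
    fuse_scf,
    fuse_spf,
    load_checkpoint,
    save_checkpoint,
)


@pytest.fixture()
def feature_pair(rng):
    f_ct = nn.Tensor(rng.standard_normal((1, 4, 2, 2, 2)).astype(np.float32))
    f_rt = nn.Tensor(rng.standard_normal((1, 4, 2, 2, 2)).astype(np.float32))
    return f_ct, f_rt


def _symmetrize(module):
    """Give the CT and RTDose branch transforms identical parameters."""
    state = module.state_dict()
    for key in list(state):
        if "_rt" in key and key.replace("_rt", "_ct") in state:
            state[key] = state[key.replace("_rt", "_ct")]
    module.load_state_dict(state)
    return module


class TestFusionAlgebra:
    @pytest.mark.parametrize("cls", [CPFusion, CCFusion])
    def test_concat_zero_params_identity(self, cls, feature_pair):
        f_ct, f_rt = feature_pair
        mod = cls(4, np.random.default_rng(0))
        mod.zero_all_parameters()
        a, b = mod(f_ct, f_rt)
        assert np.array_equal(a.data, f_ct.data)
        assert np.array_equal(b.data, f_rt.data)

    def test_squeezed_zero_params_half_gate(self, feature_pair):
        """Zero FC weights force sigmoid(0)=0.5 gates on both branches."""
        f_ct, f_rt = feature_pair
        spf = SPFusion(4, np.random.default_rng(0))
        spf.zero_all_parameters()
        a, b = spf(f_ct, f_rt)
        assert np.allclose(a.data, 1.5 * f_ct.data, atol=1e-7)
        assert np.allclose(b.data, 1.5 * f_rt.data, atol=1e-7)
        scf = SCFusion(4, np.random.default_rng(0))
        scf.zero_all_parameters()
        a, b = scf(f_ct, f_rt)
        assert np.allclose(a.data, f_ct.data + 0.5 * f_rt.data, atol=1e-7)
        assert np.allclose(b.data, f_rt.data + 0.5 * f_ct.data, atol=1e-7)

    @pytest.mark.parametrize("par_cls,cross_cls", [(CPFusion, CCFusion), (SPFusion, SCFusion)])
    def test_cross_equals_parallel_with_swapped_branches(self, par_cls, cross_cls, feature_pair):
        f_ct, f_rt = feature_pair
        par = par_cls(4, np.random.default_rng(5))
        cross = cross_cls(4, np.random.default_rng(5))
        cross.load_state_dict(par.state_dict())
        t_ct, t_rt = par.branch_transforms(f_ct, f_rt)
        a, b = cross(f_ct, f_rt)
        assert np.allclose(a.data, f_ct.data + t_rt.data, atol=1e-7)
        assert np.allclose(b.data, f_rt.data + t_ct.data, atol=1e-7)

    @pytest.mark.parametrize("par_cls,cross_cls", [(CPFusion, CCFusion), (SPFusion, SCFusion)])
    def test_equal_inputs_symmetric_params_coincide(self, par_cls, cross_cls, rng):
        f = nn.Tensor(rng.standard_normal((1, 4, 2, 2, 2)).astype(np.float32))
        par = _symmetrize(par_cls(4, np.random.default_rng(5)))
        cross = cross_cls(4, np.random.default_rng(5))
        cross.load_state_dict(par.state_dict())
        a1, b1 = par(f, f)
        a2, b2 = cross(f, f)
        assert np.allclose(a1.data, a2.data, atol=1e-7)
        assert np.allclose(b1.data, b2.data, atol=1e-7)

    def test_input_swap_with_symmetric_params(self, feature_pair):
        f_ct, f_rt = feature_pair
        par = _symmetrize(CPFusion(4, np.random.default_rng(6)))
        # make the fused conv symmetric in its two input halves as well
        w = par.conv_fuse.weight.data
        w[:, 4:] = w[:, :4]
        a1, b1 = fuse_cpf(f_ct, f_rt, par)
        a2, b2 = fuse_cpf(f_rt, f_ct, par)
        assert np.allclose(a1.data, b2.data, atol=1e-6)
        assert np.allclose(b1.data, a2.data, atol=1e-6)

    def test_concat_hand_arithmetic_center_taps(self, rng):
        """Center-only 3x3x3 kernels reduce to scalar channel arithmetic."""
        f_ct = nn.Tensor(rng.standard_normal((1, 1, 2, 2, 2)).astype(np.float64))
        f_rt = nn.Tensor(rng.standard_normal((1, 1, 2, 2, 2)).astype(np.float64))
        mod = CPFusion(1, np.random.default_rng(0), dtype=np.float64)
        mod.zero_all_parameters()
        mod.conv_fuse.weight.data[0, 0, 1, 1, 1] = 2.0   # fused = 2*fct
        mod.conv_fuse.weight.data[0, 1, 1, 1, 1] = -1.0  # .. - frt
        mod.conv_fuse.bias.data[0] = 0.5
        mod.conv_ct.weight.data[0, 0, 1, 1, 1] = 3.0
        mod.conv_rt.weight.data[0, 0, 1, 1, 1] = -0.5
        a, b = mod(f_ct, f_rt)
        fused = 2.0 * f_ct.data - 1.0 * f_rt.data + 0.5
        assert np.allclose(a.data, f_ct.data + 3.0 * fused, atol=1e-12)
        assert np.allclose(b.data, f_rt.data - 0.5 * fused, atol=1e-12)

    def test_squeezed_hand_arithmetic(self, rng):
        """Hand-set FC weights on a 2-channel cube match manual gating."""
        f_ct = nn.Tensor(rng.standard_normal((1, 2, 2, 2, 2)).astype(np.float64))
        f_rt = nn.Tensor(rng.standard_normal((1, 2, 2, 2, 2)).astype(np.float64))
        mod = SPFusion(2, np.random.default_rng(0), dtype=np.float64)
        W_ct = rng.standard_normal((4, 2))
        b_ct = rng.standard_normal(2)
        mod.fc_ct.weight.data = W_ct.copy()
        mod.fc_ct.bias.data = b_ct.copy()
        mod.fc_rt.weight.data[:] = 0.0
        mod.fc_rt.bias.data[:] = 0.0
        a, b = fuse_spf(f_ct, f_rt, mod)
        squeezed = np.concatenate(
            [f_ct.data.mean(axis=(2, 3, 4)), f_rt.data.mean(axis=(2, 3, 4))], axis=1
        )
        w_ct = 1.0 / (1.0 + np.exp(-(squeezed @ W_ct + b_ct)))
        expected_a = f_ct.data + w_ct[:, :, None, None, None] * f_ct.data
        assert np.allclose(a.data, expected_a, atol=1e-12)
        assert np.allclose(b.data, 1.5 * f_rt.data, atol=1e-12)

    def test_gap_of_constant_channels(self):
        x = np.zeros((1, 2, 2, 2, 2))
        x[:, 0], x[:, 1] = 3.0, -1.5
        pooled = nn.global_avg_pool(nn.Tensor(x)).data
        assert np.allclose(pooled, [[3.0, -1.5]])

    def test_shape_mismatch_rejected(self, rng):
        mod = CPFusion(4, np.random.default_rng(0))
        a = nn.Tensor(np.zeros((1, 4, 2, 2, 2)))
        b = nn.Tensor(np.zeros((1, 4, 4, 2, 2)))
        with pytest.raises(ValueError, match="shape mismatch"):
            mod(a, b)


class TestDecoderFuse:
    def test_output_spatial_dims(self, rng):
        mod = DecoderFuse(4, 8, np.random.default_rng(0))
        f_next = nn.Tensor(rng.standard_normal((1, 8, 2, 2, 2)).astype(np.float32))
        f_ct = nn.Tensor(rng.standard_normal((1, 4, 4, 4, 4)).astype(np.float32))
        out = decoder_fuse(f_next, f_ct, f_ct, mod)
        assert out.shape == (1, 4, 4, 4, 4)

    def test_zero_inputs_give_bias_field(self, rng):
        mod = DecoderFuse(4, 8, np.random.default_rng(0))
        mod.inner.weight.data[:] = 0.0
        mod.inner.bias.data[:] = 0.0
        bias = rng.standard_normal(4).astype(np.float32)
        mod.outer.bias.data = bias.copy()
        zero_next = nn.Tensor(np.zeros((1, 8, 2, 2, 2), np.float32))
        zero_skip = nn.Tensor(np.zeros((1, 4, 4, 4, 4), np.float32))
        out = decoder_fuse(zero_next, zero_skip, zero_skip, mod)
        assert np.allclose(out.data, bias[None, :, None, None, None])

    def test_hand_arithmetic_center_taps(self, rng):
        mod = DecoderFuse(1, 1, np.random.default_rng(0), dtype=np.float64)
        mod.zero_all_parameters()
        mod.inner.weight.data[0, 0, 1, 1, 1] = 2.0   # inner = fct + frt summed taps
        mod.inner.weight.data[0, 1, 1, 1, 1] = 2.0
        mod.outer.weight.data[0, 0, 1, 1, 1] = 1.0   # outer = up + 0.5*inner
        mod.outer.weight.data[0, 1, 1, 1, 1] = 0.5
        f_next = nn.Tensor(rng.standard_normal((1, 1, 1, 1, 1)).astype(np.float64))
        f_ct = nn.Tensor(rng.standard_normal((1, 1, 2, 2, 2)).astype(np.float64))
        f_rt = nn.Tensor(rng.standard_normal((1, 1, 2, 2, 2)).astype(np.float64))
        out = decoder_fuse(f_next, f_ct, f_rt, mod)
        up = np.full((1, 1, 2, 2, 2), f_next.data[0, 0, 0, 0, 0])
        expected = up + 0.5 * (2.0 * (f_ct.data + f_rt.data))
        assert np.allclose(out.data, expected, atol=1e-12)

    def test_spatial_mismatch_rejected(self, rng):
        mod = DecoderFuse(4, 8, np.random.default_rng(0))
        f_next = nn.Tensor(np.zeros((1, 8, 2, 2, 2), np.float32))
        f_ct = nn.Tensor(np.zeros((1, 4, 6, 4, 4), np.float32))
        with pytest.raises(ValueError, match="spatial mismatch"):
            mod(f_next, f_ct, f_ct)


class TestFullModel:
    @pytest.mark.parametrize("variant", ["baseline", "spf"])
    def test_shape_contract(self, variant, rng):
        cfg = ModelConfig(variant=variant, levels=3, base_channels=4)
        model = build_model(cfg, seed=0)
        x = rng.random((1, 1, 16, 32, 32)).astype(np.float32)
        out = model.forward(nn.Tensor(x), nn.Tensor(x))
        assert out.shape == (1, 1, 16, 32, 32)

    def test_eval_determinism(self, rng):
        model = build_model(ModelConfig(variant="scf", levels=2, base_channels=4), seed=1)
        x = rng.random((1, 1, 8, 8, 8)).astype(np.float32)
        o1 = model.forward(nn.Tensor(x), nn.Tensor(x)).data
        o2 = model.forward(nn.Tensor(x), nn.Tensor(x)).data
        assert np.array_equal(o1, o2)

    def test_spf_has_more_params_than_baseline(self):
        """Second encoder and FC gates add parameters at equal width."""
        cfg_b = ModelConfig(variant="baseline", levels=3, base_channels=8)
        cfg_s = ModelConfig(variant="spf", levels=3, base_channels=8)
        assert build_model(cfg_s).num_params() > build_model(cfg_b).num_params()

    def test_indivisible_shape_rejected(self, rng):
        model = build_model(ModelConfig(variant="cpf", levels=3, base_channels=4))
        x = rng.random((1, 1, 10, 12, 12)).astype(np.float32)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(nn.Tensor(x), nn.Tensor(x))

    def test_predict_volume_pads_odd_dims_and_clips(self, rng):
        model = build_model(ModelConfig(variant="spf", levels=2, base_channels=4), seed=3)
        ct = rng.uniform(-1000, 1000, (7, 9, 10))
        rt = rng.random((7, 9, 10)) * 70
        out = model.predict_volume(ct, rt, prescription=70.0)
        assert out.shape == (7, 9, 10)
        assert (out >= 0).all()

    def test_residual_head_starts_at_identity(self, rng):
        model = build_model(ModelConfig(variant="spf", levels=2, base_channels=4), seed=4)
        ct = rng.uniform(-500, 500, (8, 8, 8))
        rt = rng.random((8, 8, 8)) * 70
        out = model.predict_volume(ct, rt, prescription=70.0)
        assert np.allclose(out, rt, atol=1e-4)

    def test_variant_validation(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(variant="nope").validate()
        with pytest.raises(ValueError, match="se_reduction"):
            ModelConfig(base_channels=6, se_reduction=4).validate()

    def test_checkpoint_round_trip(self, rng, tmp_path):
        cfg = ModelConfig(variant="ccf", levels=2, base_channels=4)
        model = build_model(cfg, seed=7)
        path = save_checkpoint(model, tmp_path / "model.npz", extra={"seed": 7})
        back, extra = load_checkpoint(path)
        assert extra == {"seed": 7}
        assert back.config == cfg
        x = rng.random((1, 1, 8, 8, 8)).astype(np.float32)
        o1 = model.forward(nn.Tensor(x), nn.Tensor(x)).data
        o2 = back.forward(nn.Tensor(x), nn.Tensor(x)).data
        assert np.array_equal(o1, o2)
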