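"""U-Net backbone structure, heads, partial decoder, weight transfer."""

import numpy as np
import pytest

from ichseg.nn import Checkpoint
from ichseg.unet import (
    HeadSpec,
    TransferScope,
    UNetSpec,
    backbone_state,
    build_head,
    build_partial_decoder,
    build_unet,
    extract_bottleneck,
    transfer_weights,
)


def conv_block_params(cin, cmid, cout):
    return (cin * cmid * 9 + cmid) + 2 * cmid + (cmid * cout * 9 + cout) + 2 * cout


def expected_param_count(spec: UNetSpec) -> int:
    """Independent parameter-count formula traced from the block design."""
    b = spec.base_channels
    total = conv_block_params(spec.in_channels, b, b)
    for i in range(1, spec.n_encoder_blocks):
        c = b * 2 ** (i - 1)
        total += conv_block_params(c, c, 2 * c)
    bott = b * 2 ** (spec.n_encoder_blocks - 1)
    for j in range(spec.n_decoder_blocks):
        d = bott // 2**j
        total += d * (d // 2) * 4 + d // 2          # transposed conv
        total += conv_block_params(d, d // 2, d // 2)
    final_in = bott // 2**spec.n_decoder_blocks
    total += final_in * spec.out_channels + spec.out_channels
    return total


class TestBackbone:
    @pytest.mark.parametrize("base", [4, 32])
    def test_parameter_count_matches_formula(self, base):
        spec = UNetSpec(base_channels=base)
        assert build_unet(spec).n_parameters() == expected_param_count(spec)

    def test_encoder_channel_progression(self):
        net = build_unet(UNetSpec(base_channels=32))
        widths = [blk.conv2.out_ch for blk in net.enc]
        assert widths == [32, 64, 128, 256, 512]

    def test_bottleneck_shape_at_full_scale(self):
        net = build_unet(UNetSpec(base_channels=32))
        x = np.zeros((1, 1, 256, 256), dtype=np.float32)
        bott = net.encode(x)
        assert bott.shape == (1, 512, 16, 16)

    def test_output_preserves_spatial_size(self, rng):
        net = build_unet(UNetSpec(base_channels=4))
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        assert net(x).shape == (2, 1, 32, 32)

    def test_indivisible_input_rejected(self, rng):
        net = build_unet(UNetSpec(base_channels=4))
        with pytest.raises(ValueError):
            net(rng.random((1, 1, 24, 24)).astype(np.float32))

    def test_halving_doubling_ladder(self, rng):
        net = build_unet(UNetSpec(base_channels=4))
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        net.encode(x)
        sizes = [s.shape[2] for s in net._skips]
        assert sizes == [64, 32, 16, 8]


class TestHeads:
    def test_projection_head_output_dim(self, rng):
        head = build_head(HeadSpec("mlp_projection", (512, 512, 128)))
        out = head(rng.random((3, 512, 4, 4)).astype(np.float32))
        assert out.shape == (3, 128)

    def test_classifier_softmax_sums_to_one(self, rng):
        head = build_head(HeadSpec("classifier", (512, 1024, 256, 2)))
        logits = head(rng.random((4, 512, 2, 2)).astype(np.float32))
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_multilabel_head_sigmoid_outputs_in_unit_interval(self, rng):
        head = build_head(HeadSpec("classifier", (64, 128, 32, 7)))
        logits = head(rng.random((5, 64, 2, 2)).astype(np.float32))
        q = 1 / (1 + np.exp(-logits))
        assert q.shape == (5, 7) and np.all((q > 0) & (q < 1))

    def test_unknown_head_kind_rejected(self):
        with pytest.raises(ValueError):
            HeadSpec("mystery", (8, 8))


class TestPartialDecoder:
    def test_feature_map_upsampled_three_times(self, rng):
        backbone = build_unet(UNetSpec(base_channels=8))
        partial = build_partial_decoder(backbone)
        out = partial(rng.random((1, 1, 64, 64)).astype(np.float32))
        # 64 / 16 * 2^3 = 32 spatial; head projects to base_channels
        assert out.shape == (1, 8, 32, 32)

    def test_head_input_channels_follow_decoder(self):
        backbone = build_unet(UNetSpec(base_channels=32))
        partial = build_partial_decoder(backbone)
        assert partial.head.conv1.in_ch == 64
        assert partial.head.conv2.out_ch == 32

    def test_skip_connections_present(self, rng):
        backbone = build_unet(UNetSpec(base_channels=8))
        partial = build_partial_decoder(backbone)
        partial(rng.random((1, 1, 64, 64)).astype(np.float32))
        assert len(partial.backbone._skip_channels) == 3

    def test_encoder_weights_inherited_from_backbone(self):
        backbone = build_unet(UNetSpec(base_channels=8), seed=3)
        partial = build_partial_decoder(backbone, seed=99)
        src = backbone.state_dict()
        dst = backbone_state(partial)
        for key in src:
            if key.startswith("enc."):
                assert np.array_equal(src[key], dst[key]), key


class TestTransfer:
    def _two_nets(self):
        a = build_unet(UNetSpec(base_channels=4), seed=1)
        b = build_unet(UNetSpec(base_channels=4), seed=2)
        return a, b

    def test_full_network_scope_copies_everything(self):
        src, dst = self._two_nets()
        transfer_weights(src, dst, TransferScope.FULL_NETWORK)
        for k, v in src.state_dict().items():
            assert np.array_equal(v, dst.state_dict()[k]), k

    def test_encoder_only_scope_leaves_decoder_fresh(self):
        src, dst = self._two_nets()
        fresh = {k: v.copy() for k, v in dst.state_dict().items()}
        transfer_weights(src, dst, TransferScope.ENCODER_ONLY)
        state = dst.state_dict()
        src_state = src.state_dict()
        for k in state:
            if k.startswith("enc."):
                assert np.array_equal(state[k], src_state[k]), k
            else:
                assert np.array_equal(state[k], fresh[k]), k

    def test_partial_decoder_scope(self):
        src, dst = self._two_nets()
        fresh = {k: v.copy() for k, v in dst.state_dict().items()}
        transfer_weights(src, dst, TransferScope.ENCODER_PLUS_PARTIAL_DECODER)
        state = dst.state_dict()
        assert np.array_equal(state["dec.2.conv1.W"], src.state_dict()["dec.2.conv1.W"])
        assert np.array_equal(state["dec.3.conv1.W"], fresh["dec.3.conv1.W"])
        assert np.array_equal(state["out.W"], fresh["out.W"])

    def test_transfer_is_idempotent(self):
        src, dst = self._two_nets()
        transfer_weights(src, dst, TransferScope.FULL_NETWORK)
        once = {k: v.copy() for k, v in dst.state_dict().items()}
        transfer_weights(src, dst, TransferScope.FULL_NETWORK)
        for k, v in dst.state_dict().items():
            assert np.array_equal(v, once[k])

    def test_shape_mismatch_names_tensor(self):
        src = build_unet(UNetSpec(base_channels=8), seed=1)
        dst = build_unet(UNetSpec(base_channels=4), seed=2)
        with pytest.raises(ValueError, match="enc"):
            transfer_weights(src, dst, TransferScope.ENCODER_ONLY)

    def test_checkpoint_roundtrip_bitwise(self, tmp_path):
        net = build_unet(UNetSpec(base_channels=4), seed=5)
        ckpt = Checkpoint(state=backbone_state(net), meta={"transfer_scope": "full_network"})
        ckpt.save(tmp_path / "ck")
        loaded = Checkpoint.load(tmp_path / "ck")
        assert loaded.meta["transfer_scope"] == "full_network"
        for k, v in ckpt.state.items():
            assert np.array_equal(v, loaded.state[k])


class TestBottleneck:
    def test_vector_length_is_sixteen_times_base(self):
        net = build_unet(UNetSpec(base_channels=32))
        vec = extract_bottleneck(net, np.zeros((64, 64), dtype=np.float32))
        assert vec.shape == (512,)

    def test_deterministic_for_identical_inputs(self, rng):
        net = build_unet(UNetSpec(base_channels=4))
        img = rng.random((32, 32)).astype(np.float32)
        assert np.array_equal(extract_bottleneck(net, img), extract_bottleneck(net, img))

    def test_batched_input(self, rng):
        net = build_unet(UNetSpec(base_channels=4))
        out = extract_bottleneck(net, rng.random((3, 32, 32)).astype(np.float32))
        assert out.shape == (3, 64)
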