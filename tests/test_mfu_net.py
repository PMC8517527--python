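import numpy as np
import pytest

from mfuseg import nn
from mfuseg.mfu_net import (
    MFBlockSpec,
    NetworkSpec,
    MFBlock,
    DecoderLevel,
    build_mfunet,
    mf_block_forward,
    parameter_count,
    predict_slice,
    predict_volume,
    threshold_masks,
    split_branch_channels,
)
from mfuseg import CTVolume

from oracles import conv2d_oracle


def audit_parameter_count(spec: NetworkSpec) -> int:
    """Independent per-layer arithmetic audit of the default topology."""
    b = spec.base_width
    bn = 2  # gamma + beta per channel

    def conv(cin, cout, k, bias):
        return cin * cout * k * k + (cout if bias else 0)

    total = conv(spec.in_channels, b, 7, False) + bn * b  # stem
    widths = (b, 2 * b, 4 * b, 8 * b)
    cin = b
    for i, w in enumerate(widths):
        for blk in range(2):
            in_ch = cin if blk == 0 else w
            total += conv(in_ch, w, 3, False) + bn * w
            total += conv(w, w, 3, False) + bn * w
            if blk == 0 and (in_ch != w or i > 0):  # projection shortcut
                total += conv(in_ch, w, 1, False) + bn * w
        cin = w
    for mf in spec.mf_block_specs():
        c1, c3, c5 = mf.branch_channels
        for c, k in ((c1, 1), (c3, 3), (c5, 5)):
            total += conv(mf.in_channels, c, k, True)
            if spec.batch_norm:
                total += bn * c
    total += conv(spec.decoder_widths[-1], spec.num_classes, 1, True)  # head
    return total


class TestMFBlock:
    @pytest.mark.parametrize("width", [3, 4, 5, 7, 12])
    def test_output_channels_are_branch_sum(self, rng, width):
        spec = MFBlockSpec(4, split_branch_channels(width))
        assert spec.out_channels == width
        block = MFBlock(spec, rng, batch_norm=False)
        out = mf_block_forward(block, rng.normal(size=(2, 4, 8, 8)))
        assert out.shape == (2, width, 8, 8)

    def test_output_nonnegative(self, rng):
        block = MFBlock(MFBlockSpec(3, (2, 2, 2)), rng)
        out = mf_block_forward(block, rng.normal(size=(1, 3, 6, 6)))
        assert (out >= 0).all()

    def test_zero_input_zero_biases_gives_zero(self, rng):
        block = MFBlock(MFBlockSpec(2, (1, 1, 1)), rng, batch_norm=False)
        out = mf_block_forward(block, np.zeros((1, 2, 6, 6)))
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_1x1_branch_matches_hand_convolution(self, rng):
        block = MFBlock(MFBlockSpec(1, (1, 2, 2)), rng, batch_norm=False)
        block.conv1.weight.data[:] = 1.0  # identity 1x1
        block.conv1.bias.data[:] = 0.0
        for conv in (block.conv3, block.conv5):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = rng.normal(size=(1, 1, 3, 3))
        out = mf_block_forward(block, x)
        # branch-1 channel: ReLU of the input plane
        np.testing.assert_allclose(out[0, 0], np.maximum(x[0, 0], 0.0), atol=1e-12)
        # other branches stay zero, verified against a direct convolution oracle
        np.testing.assert_allclose(
            out[0, 1:3], np.maximum(conv2d_oracle(x, block.conv3.weight.data, None, 1, 1), 0)[0],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            out[0, 3:5], np.maximum(conv2d_oracle(x, block.conv5.weight.data, None, 1, 2), 0)[0],
            atol=1e-12,
        )

    def test_translation_covariance_interior(self, rng):
        block = MFBlock(MFBlockSpec(1, (2, 2, 2)), rng)
        block.eval()  # running-stats normalisation is pointwise
        x = rng.normal(size=(1, 1, 12, 12))
        shifted = np.roll(x, 1, axis=3)
        y = mf_block_forward(block, x)
        ys = mf_block_forward(block, shifted)
        # compare away from the borders (3-pixel margin covers the 5x5 halo)
        np.testing.assert_allclose(ys[:, :, 3:-3, 4:-3], np.roll(y, 1, axis=3)[:, :, 3:-3, 4:-3],
                                   atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        block = MFBlock(MFBlockSpec(3, (1, 1, 1)), rng)
        with pytest.raises(ValueError, match="input channels"):
            mf_block_forward(block, np.zeros((1, 2, 8, 8)))

    def test_too_small_spatial_rejected(self, rng):
        block = MFBlock(MFBlockSpec(1, (1, 1, 1)), rng)
        with pytest.raises(ValueError, match="too small"):
            mf_block_forward(block, np.zeros((1, 1, 1, 1)))


class TestNetworkSpec:
    def test_decoder_has_exactly_ten_blocks(self):
        assert len(NetworkSpec(base_width=4).mf_block_specs()) == 10
        assert len(NetworkSpec(base_width=64).mf_block_specs()) == 10

    def test_branch_split_remainder_to_3x3(self):
        assert split_branch_channels(4) == (1, 2, 1)
        assert split_branch_channels(6) == (2, 2, 2)
        assert split_branch_channels(8) == (2, 4, 2)

    def test_non_three_class_rejected(self):
        with pytest.raises(ValueError, match="three-class"):
            NetworkSpec(num_classes=2)


class TestBuildAndForward:
    def test_seeded_builds_bit_identical(self):
        spec = NetworkSpec(base_width=4)
        s1 = build_mfunet(spec, seed=3).state_dict()
        s2 = build_mfunet(spec, seed=3).state_dict()
        assert s1.keys() == s2.keys()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_different_seeds_differ(self):
        spec = NetworkSpec(base_width=4)
        a = build_mfunet(spec, seed=1).state_dict()
        b = build_mfunet(spec, seed=2).state_dict()
        assert any(not np.array_equal(a[k], b[k]) for k in a)

    def test_forward_shape_contract(self, tiny_net, rng):
        x = nn.Var(rng.normal(size=(1, 1, 64, 64)))
        tiny_net.eval()
        with nn.no_grad():
            y = tiny_net(x)
        assert y.data.shape == (1, 3, 64, 64)

    def test_indivisible_input_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="divisible by 32"):
            with nn.no_grad():
                tiny_net(nn.Var(np.zeros((1, 1, 60, 60))))

    def test_parameter_count_matches_arithmetic_audit(self):
        for spec in (NetworkSpec(base_width=4), NetworkSpec(base_width=6, batch_norm=False),
                     NetworkSpec(base_width=4, skips="single")):
            net = build_mfunet(spec, seed=0)
            assert parameter_count(net) == audit_parameter_count(spec)

    def test_single_skip_variant_runs(self, rng):
        net = build_mfunet(NetworkSpec(base_width=4, skips="single"), seed=0)
        net.eval()
        with nn.no_grad():
            y = net(nn.Var(rng.normal(size=(1, 1, 32, 32))))
        assert y.data.shape == (1, 3, 32, 32)

    def test_eval_forward_deterministic(self, tiny_net, rng):
        x = rng.normal(size=(1, 1, 64, 64))
        tiny_net.eval()
        with nn.no_grad():
            y1 = tiny_net(nn.Var(x)).data
            y2 = tiny_net(nn.Var(x)).data
        np.testing.assert_array_equal(y1, y2)

    def test_skip_shape_mismatch_reports_both_shapes(self, rng):
        level = DecoderLevel(MFBlockSpec(4, (1, 2, 1)), MFBlockSpec(4, (1, 2, 1)), rng, True)
        x = nn.Var(np.zeros((1, 2, 4, 4)))
        bad_skip = nn.Var(np.zeros((1, 2, 16, 16)))
        with pytest.raises(ValueError, match="mismatch at merge"):
            with nn.no_grad():
                level(x, bad_skip)


class TestPrediction:
    def test_softmax_normalised_and_argmax(self, tiny_net, rng):
        plane = rng.normal(size=(64, 64))
        probs, labels = predict_slice(tiny_net, plane)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert set(np.unique(labels)) <= {0, 1, 2}
        # argmax labels equal exhaustive per-pixel comparison of the 3 maps
        brute = np.zeros_like(labels)
        for i in range(64):
            for j in range(64):
                best, arg = -1.0, 0
                for c in range(3):
                    if probs[c, i, j] > best:
                        best, arg = probs[c, i, j], c
                brute[i, j] = arg
        np.testing.assert_array_equal(labels, brute)

    def test_threshold_masks(self):
        probs = np.array([[[0.2, 0.7]], [[0.7, 0.1]], [[0.1, 0.2]]])
        masks = threshold_masks(probs)
        np.testing.assert_array_equal(masks[:, 0, 0], [False, True, False])
        np.testing.assert_array_equal(masks[:, 0, 1], [True, False, False])

    def test_volume_prediction_single_slice_reduction(self, tiny_net, rng):
        plane = rng.normal(size=(64, 64))
        vol = CTVolume(voxels=plane[None], spacing=(2.0, 0.7, 0.7))
        pred = predict_volume(tiny_net, vol)
        np.testing.assert_array_equal(pred.labels[0], predict_slice(tiny_net, plane)[1])
        assert pred.spacing == vol.spacing

    def test_volume_prediction_slice_permutation_equivariant(self, tiny_net, rng):
        vox = rng.normal(size=(4, 64, 64))
        vol = CTVolume(voxels=vox, spacing=(1, 1, 1))
        perm = np.array([2, 0, 3, 1])
        pred_then_perm = predict_volume(tiny_net, vol).labels[perm]
        perm_then_pred = predict_volume(tiny_net, CTVolume(voxels=vox[perm], spacing=(1, 1, 1))).labels
        np.testing.assert_array_equal(pred_then_perm, perm_then_pred)
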