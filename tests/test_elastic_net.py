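"""Elastic scaling, channel slicing, deformable sampling, fusion pruning."""

import numpy as np
import pytest

from conftest import TINY_NET
from eyolo.elastic_net import (
    DeformableKernel, ElasticConvSpec, ElasticScale, build_network,
    deformable_conv, effective_channels, effective_depth, elastic_conv,
    load_config,
)
from eyolo.profiler import count_flops, count_params


def brute_force_deformable(fm, kernel):
    """Scalar-loop oracle: f(xi0) = sum_xi omega(xi) g(xi0 + xi + dxi)."""
    h, w, c_in = fm.shape
    c_out, _, kh, kw = kernel.weight.shape
    out = np.zeros((h, w, c_out))

    def sample(y, x, ch):
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        wy, wx = y - y0, x - x0
        total = 0.0
        for dy_c, dx_c, wgt in ((0, 0, (1 - wy) * (1 - wx)),
                                (0, 1, (1 - wy) * wx),
                                (1, 0, wy * (1 - wx)),
                                (1, 1, wy * wx)):
            yy, xx = y0 + dy_c, x0 + dx_c
            if 0 <= yy < h and 0 <= xx < w:
                total += wgt * fm[yy, xx, ch]
        return total

    for oy in range(h):
        for ox in range(w):
            for co in range(c_out):
                acc = 0.0
                for t in range(kh * kw):
                    i, j = divmod(t, kw)
                    dy, dx = kernel.offsets[oy, ox, t]
                    py = oy + (i - kh // 2) + dy
                    px = ox + (j - kw // 2) + dx
                    for ci in range(c_in):
                        acc += kernel.weight[co, ci, i, j] * sample(py, px, ci)
                if kernel.bias is not None:
                    acc += kernel.bias[co]
                out[oy, ox, co] = acc
    return out


class TestElasticScale:
    def test_valid_values_only(self):
        ElasticScale(0.75, 1.5)
        with pytest.raises(ValueError):
            ElasticScale(0.9, 1.0)
        with pytest.raises(ValueError):
            ElasticScale(1.0, 2.0)

    def test_effective_depth_and_channels(self):
        assert effective_depth(9, 0.75) == 7       # max(1, round(6.75))
        assert effective_depth(1, 0.75) == 1
        assert effective_channels(64, 0.5) == 32   # round(0.5 * 64)
        assert effective_channels(64, 1.5) == 96

    def test_identity_scaling_reproduces_base_schedule(self):
        cfg = load_config()
        net = build_network(ElasticScale(1.0, 1.0))
        assert net.channels == cfg["base_channels"]
        assert net.depths == cfg["base_depths"]


class TestElasticConv:
    def test_full_width_equals_standard_convolution(self, rng):
        from scipy.signal import correlate
        fm = rng.standard_normal((6, 7, 3))
        spec = ElasticConvSpec(3, d_min=2, d_max=4, d_out=4)
        w = rng.standard_normal((4, 3, 3, 3)).astype(np.float32)
        out = elastic_conv(fm, spec, w)
        for co in range(4):
            ref = sum(correlate(fm[:, :, ci], w[co, ci].astype(np.float64),
                                mode="same") for ci in range(3))
            assert np.allclose(out[:, :, co], ref, atol=1e-4)

    def test_narrow_width_is_a_slice_of_full_width(self, rng):
        fm = rng.standard_normal((5, 5, 3))
        w = rng.standard_normal((6, 3, 3, 3)).astype(np.float32)
        full = elastic_conv(fm, ElasticConvSpec(3, 2, 6, 6), w)
        narrow = elastic_conv(fm, ElasticConvSpec(3, 2, 6, 2), w)
        assert np.allclose(narrow, full[:, :, :2], atol=1e-6)

    def test_1x1_preserves_spatial_dims(self, rng):
        fm = rng.standard_normal((9, 11, 2))
        w = rng.standard_normal((3, 2, 1, 1)).astype(np.float32)
        out = elastic_conv(fm, ElasticConvSpec(2, 1, 3, 3, kernel=(1, 1)), w)
        assert out.shape == (9, 11, 3)

    def test_out_of_band_width_rejected(self):
        with pytest.raises(ValueError):
            ElasticConvSpec(3, d_min=4, d_max=8, d_out=2)


class TestDeformableConv:
    def test_zero_offsets_reduce_to_standard_convolution(self, rng):
        from scipy.signal import correlate
        fm = rng.standard_normal((8, 8, 2))
        w = rng.standard_normal((3, 2, 3, 3))
        k = DeformableKernel(w, np.zeros((8, 8, 9, 2)))
        out = deformable_conv(fm, k)
        for co in range(3):
            ref = sum(correlate(fm[:, :, ci], w[co, ci], mode="same")
                      for ci in range(2))
            assert np.abs(out[:, :, co] - ref).max() < 1e-5

    def test_integer_shift_equivalence_on_interior(self, rng):
        """Offsets identically (0, 1) sample the input shifted one pixel
        left, so the output equals the standard convolution of the shifted
        map away from the borders."""
        from scipy.signal import correlate
        fm = rng.standard_normal((9, 9, 1))
        w = rng.standard_normal((1, 1, 3, 3))
        offs = np.zeros((9, 9, 9, 2))
        offs[..., 1] = 1.0  # dx = +1 everywhere
        out = deformable_conv(fm, DeformableKernel(w, offs))
        shifted = np.roll(fm, -1, axis=1)
        ref = correlate(shifted[:, :, 0], w[0, 0], mode="same")
        assert np.abs(out[2:-2, 2:-2, 0] - ref[2:-2, 2:-2]).max() < 1e-5

    def test_fractional_offsets_match_scalar_oracle(self, rng):
        fm = rng.standard_normal((5, 5, 1))
        w = rng.standard_normal((1, 1, 3, 3))
        offs = rng.uniform(-1.5, 1.5, (5, 5, 9, 2))
        out = deformable_conv(fm, DeformableKernel(w, offs))
        ref = brute_force_deformable(fm, DeformableKernel(w, offs))
        assert np.abs(out - ref).max() < 1e-5

    def test_offset_shape_mismatch_rejected(self, rng):
        fm = rng.standard_normal((5, 5, 1))
        w = rng.standard_normal((1, 1, 3, 3))
        with pytest.raises(ValueError):
            deformable_conv(fm, DeformableKernel(w, np.zeros((5, 5, 4, 2))))


class TestNetworkForward:
    def test_prediction_grids_follow_strides(self):
        net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=0)
        net.eval()
        out = net.forward(np.zeros((1, 256, 256, 3), dtype=np.float32))
        assert out[8].shape[2:] == (32, 32)
        assert out[16].shape[2:] == (16, 16)
        assert out[32].shape[2:] == (8, 8)
        assert all(o.shape[0] == 4 + 1 + 6 for o in out.values())

    def test_duplicate_images_give_identical_outputs(self, rng):
        net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=0)
        net.eval()
        img = rng.standard_normal((64, 64, 3)).astype(np.float32)
        out = net.forward(np.stack([img, img]))
        for o in out.values():
            assert np.array_equal(o[:, 0], o[:, 1])

    def test_all_zero_input_is_finite(self):
        net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=0)
        net.eval()
        out = net.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))
        for o in out.values():
            assert np.all(np.isfinite(o))

    def test_non_divisible_input_rejected(self):
        net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 60, 60, 3), dtype=np.float32))

    def test_forward_deterministic_under_fixed_seed(self, rng):
        img = rng.standard_normal((1, 64, 64, 3)).astype(np.float32)
        outs = []
        for _ in range(2):
            net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=7)
            net.eval()
            outs.append(net.forward(img))
        for s in outs[0]:
            assert np.array_equal(outs[0][s], outs[1][s])

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=3)
        net.eval()
        img = rng.standard_normal((1, 64, 64, 3)).astype(np.float32)
        before = net.forward(img)
        net.save(tmp_path / "ckpt.npz")
        from eyolo.elastic_net import EYOLONet
        net2 = EYOLONet.load(tmp_path / "ckpt.npz")
        after = net2.forward(img)
        for s in before:
            assert np.allclose(before[s], after[s], atol=1e-6)


class TestFusionPruning:
    def _trained_like_net(self):
        net = build_network(ElasticScale(1.0, 1.0), config=TINY_NET, seed=1)
        return net

    def test_epsilon_zero_prunes_nothing(self, rng):
        net = self._trained_like_net()
        net.eval()
        img = rng.standard_normal((1, 64, 64, 3)).astype(np.float32)
        before = net.forward(img)
        assert net.prune(0.0) == []
        after = net.forward(img)
        for s in before:
            assert np.array_equal(before[s], after[s])

    def test_epsilon_one_keeps_only_strongest_path(self):
        net = self._trained_like_net()
        net.prune(1.0)
        for node in net.fusion_nodes:
            assert sum(node.active) == 1

    def test_weak_path_pruned_and_flops_shrink(self):
        net = self._trained_like_net()
        # make one incoming path negligible: tiny fusion weights for it
        node = net.fuse_u4
        c0 = node.path_channels[0]
        node.block.conv.weight.data[:, :c0] *= 1e-4
        flops_before = count_flops(net, 128).total_flops
        scores = node.path_scores()
        assert scores[0] < 0.01 < scores[1]
        dropped = net.prune(0.01)
        assert any("U4" in d for d in dropped)
        flops_after = count_flops(net, 128).total_flops
        assert flops_after < flops_before

    def test_pruned_network_still_runs(self, rng):
        net = self._trained_like_net()
        net.prune(1.0)
        net.eval()
        out = net.forward(rng.standard_normal((1, 64, 64, 3)).astype(np.float32))
        assert all(np.all(np.isfinite(o)) for o in out.values())


class TestScalingMonotonicity:
    def test_param_count_strictly_monotone_in_width_and_depth(self):
        widths = [count_params(build_network(ElasticScale(1.0, w))).total_params
                  for w in (0.5, 1.0, 1.5)]
        assert widths[0] < widths[1] < widths[2]
        depths = [count_params(build_network(ElasticScale(d, 1.0))).total_params
                  for d in (0.75, 1.0, 1.25)]
        assert depths[0] < depths[1] < depths[2]
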