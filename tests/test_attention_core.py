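"""Oracle and property tests for the strip-pooling attention operator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dieanet import nn
from dieanet.attention import (
    DIEA, CoordinateAttention, DIEAConfig, DirectionalEmbeddings, GateResize,
    PoolMode, StripDescriptors, ca_forward, concat_strips, diea_forward,
    fuse_descriptors, gate_and_apply, h_swish, outer_embed, split_and_expand,
    strip_avg_pool, strip_max_pool,
)
from dieanet.autodiff import Tensor


def loop_strip_pools(x):
    """Brute-force double-loop strip pooling — the independent oracle."""
    c, h, w = x.shape
    a_h = np.zeros((c, h)); a_w = np.zeros((c, w))
    m_h = np.full((c, h), -np.inf); m_w = np.full((c, w), -np.inf)
    for ci in range(c):
        for hi in range(h):
            for wi in range(w):
                a_h[ci, hi] += x[ci, hi, wi] / w
                a_w[ci, wi] += x[ci, hi, wi] / h
                m_h[ci, hi] = max(m_h[ci, hi], x[ci, hi, wi])
                m_w[ci, wi] = max(m_w[ci, wi], x[ci, hi, wi])
    return a_h, a_w, m_h, m_w


class TestStripPooling:
    def test_worked_example(self):
        x = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        a_h, a_w = strip_avg_pool(x)
        m_h, m_w = strip_max_pool(x)
        np.testing.assert_allclose(a_h, [[2.0, 6.0]])
        np.testing.assert_allclose(a_w, [[3.0, 5.0]])
        np.testing.assert_allclose(m_h, [[3.0, 7.0]])
        np.testing.assert_allclose(m_w, [[5.0, 7.0]])

    def test_constant_input(self, rng):
        x = np.full((3, 4, 5), 2.7)
        for f in (strip_avg_pool, strip_max_pool):
            for out in f(x):
                np.testing.assert_allclose(out, 2.7)

    def test_matches_loop_oracle_on_random_tensors(self, rng):
        for _ in range(100):
            c, h, w = rng.integers(1, 9, size=3)
            x = rng.standard_normal((c, h, w))
            a_h, a_w = strip_avg_pool(x)
            m_h, m_w = strip_max_pool(x)
            oa_h, oa_w, om_h, om_w = loop_strip_pools(x)
            np.testing.assert_allclose(a_h, oa_h, atol=1e-6)
            np.testing.assert_allclose(a_w, oa_w, atol=1e-6)
            np.testing.assert_array_equal(m_h, om_h)
            np.testing.assert_array_equal(m_w, om_w)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_max_dominates_average(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((2, 3, 4))
        a_h, a_w = strip_avg_pool(x)
        m_h, m_w = strip_max_pool(x)
        assert (m_h >= a_h - 1e-12).all() and (m_w >= a_w - 1e-12).all()
        # equality exactly where the strip is constant
        const_rows = np.isclose(x.max(axis=2), x.min(axis=2))
        np.testing.assert_array_equal(np.isclose(m_h, a_h), const_rows)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            strip_avg_pool(np.zeros((0, 2, 2)))
        with pytest.raises(ValueError):
            strip_max_pool(np.array([[[np.nan]]]))


class TestConcat:
    def test_shapes_and_values(self, rng):
        sd = StripDescriptors(a_h=np.array([[1.0, 2.0]]), a_w=np.array([[3.0]]),
                              m_h=np.array([[4.0, 5.0]]), m_w=np.array([[6.0]]))
        cd = concat_strips(sd)
        np.testing.assert_allclose(cd.a, [[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(cd.m, [[4.0, 5.0, 6.0]])
        assert cd.split_h == 2

    def test_round_trip(self, rng):
        a_h, m_h = rng.standard_normal((2, 4, 2))
        a_w, m_w = rng.standard_normal((2, 4, 3))
        cd = concat_strips(StripDescriptors(a_h, a_w, m_h, m_w))
        np.testing.assert_array_equal(cd.a[:, :cd.split_h], a_h)
        np.testing.assert_array_equal(cd.a[:, cd.split_h:], a_w)
        np.testing.assert_array_equal(cd.m[:, :cd.split_h], m_h)

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValueError):
            StripDescriptors(np.zeros((2, 3)), np.zeros((3, 4)),
                             np.zeros((2, 3)), np.zeros((3, 4)))


@pytest.mark.parametrize("x,expected", [
    (0.0, 0.0), (3.0, 3.0), (-3.0, 0.0), (1.0, 2.0 / 3.0), (-4.0, 0.0), (6.0, 6.0),
])
def test_h_swish_closed_form(x, expected):
    assert h_swish(np.array(x)) == pytest.approx(expected, abs=1e-12)


@pytest.fixture()
def module16(rng):
    cfg = DIEAConfig(channels=16, reduction=4, min_mid_channels=2)
    return DIEA(cfg, rng=rng).eval()


class TestFuseSplit:
    def test_zero_input_maps_to_zero(self, module16):
        sd = StripDescriptors(a_h=np.zeros((16, 5)), a_w=np.zeros((16, 3)),
                              m_h=np.zeros((16, 5)), m_w=np.zeros((16, 3)))
        fd = fuse_descriptors(concat_strips(sd), module16)
        np.testing.assert_allclose(fd.h, 0.0, atol=1e-12)
        de = split_and_expand(fd, module16)
        np.testing.assert_allclose(de.h_a, 0.0, atol=1e-12)
        np.testing.assert_allclose(de.h_m, 0.0, atol=1e-12)

    def test_mid_channel_flooring(self):
        cfg = DIEAConfig(channels=64, reduction=32)
        assert cfg.mid_channels == 8          # floor(64/32)=2, floored up to 8
        cfg2 = DIEAConfig(channels=64, reduction=32, min_mid_channels=1)
        assert cfg2.mid_channels == 2
        with pytest.raises(ValueError):
            DIEAConfig(channels=8, reduction=32, min_mid_channels=0)

    def test_fused_shape(self, rng):
        cfg = DIEAConfig(channels=64, reduction=32)
        mod = DIEA(cfg, rng=rng).eval()
        sd = StripDescriptors(a_h=rng.standard_normal((64, 8)),
                              a_w=rng.standard_normal((64, 8)),
                              m_h=rng.standard_normal((64, 8)),
                              m_w=rng.standard_normal((64, 8)))
        fd = fuse_descriptors(concat_strips(sd), mod)
        assert fd.h.shape == (8, 32)          # (mid, 2H+2W)

    def test_split_shapes(self, module16, rng):
        sd = StripDescriptors(a_h=rng.standard_normal((16, 3)),
                              a_w=rng.standard_normal((16, 5)),
                              m_h=rng.standard_normal((16, 3)),
                              m_w=rng.standard_normal((16, 5)))
        de = split_and_expand(fuse_descriptors(concat_strips(sd), module16), module16)
        assert de.h_a.shape == (16, 8, 1)
        assert de.h_m.shape == (16, 1, 8)

    def test_split_matches_per_position_matmul(self, module16, rng):
        """Independent oracle: convolve each spatial position separately."""
        sd = StripDescriptors(a_h=rng.standard_normal((16, 4)),
                              a_w=rng.standard_normal((16, 4)),
                              m_h=rng.standard_normal((16, 4)),
                              m_w=rng.standard_normal((16, 4)))
        fd = fuse_descriptors(concat_strips(sd), module16)
        de = split_and_expand(fd, module16)
        w2 = module16.f2.weight.data[:, :, 0, 0].astype(float)
        bn = module16.bn2
        for p in range(8):
            col = w2 @ fd.h[:, p]
            col = (col - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
            col = col * bn.weight.data + bn.bias.data
            np.testing.assert_allclose(de.h_a[:, p, 0], col, atol=1e-6)


class TestOuterEmbed:
    def test_worked_example(self):
        de = DirectionalEmbeddings(h_a=np.array([[[1.0], [2.0]]]),
                                   h_m=np.array([[[3.0, 4.0]]]))
        em = outer_embed(de)
        np.testing.assert_allclose(em.h_am[0], [[3.0, 4.0], [6.0, 8.0]])

    def test_matches_triple_loop(self, rng):
        h_a = rng.standard_normal((3, 6, 1))
        h_m = rng.standard_normal((3, 1, 6))
        em = outer_embed(DirectionalEmbeddings(h_a, h_m))
        for c in range(3):
            for p in range(6):
                for q in range(6):
                    assert em.h_am[c, p, q] == h_a[c, p, 0] * h_m[c, 0, q]

    def test_rank_at_most_one(self, rng):
        h_a = rng.standard_normal((4, 10, 1))
        h_m = rng.standard_normal((4, 1, 10))
        em = outer_embed(DirectionalEmbeddings(h_a, h_m))
        for c in range(4):
            s = np.linalg.svd(em.h_am[c], compute_uv=False)
            assert s[1] <= 1e-6 * max(s[0], 1e-30)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DirectionalEmbeddings(np.zeros((2, 4, 1)), np.zeros((2, 1, 5)))


class TestGate:
    def test_attenuation_bound(self, module16, rng):
        x = rng.standard_normal((16, 8, 8))
        y = diea_forward(x, module16)
        assert (np.abs(y) <= np.abs(x) + 1e-12).all()
        assert (np.sign(y) == np.sign(x))[np.abs(x) > 1e-9].all()

    def test_zero_downsample_weights_halve_input(self, module16, rng):
        x = rng.standard_normal((16, 8, 8))
        module16.f_down.weight.data[:] = 0.0
        module16.f_down.bias.data[:] = 0.0
        sd = StripDescriptors(*strip_avg_pool(x), *strip_max_pool(x))
        em = outer_embed(split_and_expand(
            fuse_descriptors(concat_strips(sd), module16), module16))
        y, gate = gate_and_apply(x, em, module16)
        np.testing.assert_allclose(gate.g, 0.5)
        np.testing.assert_allclose(y, x / 2.0)

    def test_downsample_shape_arithmetic(self, module16, rng):
        x = rng.standard_normal((16, 8, 8))
        sd = StripDescriptors(*strip_avg_pool(x), *strip_max_pool(x))
        em = outer_embed(split_and_expand(
            fuse_descriptors(concat_strips(sd), module16), module16))
        assert em.h_am.shape == (16, 16, 16)
        _, gate = gate_and_apply(x, em, module16)
        assert gate.g.shape == (16, 8, 8)     # floor((16+2-3)/2)+1 = 8
        assert (gate.g > 0).all() and (gate.g < 1).all()

    def test_non_square_error_names_the_option(self, module16, rng):
        with pytest.raises(ValueError, match="gate_resize"):
            diea_forward(rng.standard_normal((16, 4, 6)), module16)


class TestDieaForward:
    def test_shape_preserved(self, rng):
        cfg = DIEAConfig(channels=32, reduction=8)
        mod = DIEA(cfg, rng=rng).eval()
        x = rng.standard_normal((32, 16, 16))
        assert diea_forward(x, mod).shape == x.shape

    @pytest.mark.parametrize("h", [2, 4, 8, 16, 32])
    def test_shape_preserved_across_sizes(self, rng, h):
        cfg = DIEAConfig(channels=8, reduction=4, min_mid_channels=2)
        mod = DIEA(cfg, rng=rng).eval()
        x = rng.standard_normal((8, h, h))
        assert diea_forward(x, mod).shape == (8, h, h)

    def test_pool_modes_agree_on_constant_input(self, rng):
        cfg = DIEAConfig(channels=8, reduction=4, min_mid_channels=2)
        mod = DIEA(cfg, rng=rng).eval()
        x = np.full((8, 6, 6), 1.7)
        outs = []
        for pm in PoolMode:
            mod.cfg.pool_mode = pm
            outs.append(diea_forward(x, mod))
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-12)
        np.testing.assert_allclose(outs[0], outs[2], atol=1e-12)

    @pytest.mark.parametrize("pool_mode", list(PoolMode))
    def test_module_matches_functional_composition(self, rng, pool_mode):
        """Dual route: the batched autodiff module against the step-by-step
        NumPy composition."""
        cfg = DIEAConfig(channels=12, reduction=4, min_mid_channels=2,
                         pool_mode=pool_mode)
        mod = DIEA(cfg, rng=rng).eval()
        x = rng.standard_normal((12, 10, 10)).astype(np.float32)
        np.testing.assert_allclose(mod(Tensor(x[None])).data[0],
                                   diea_forward(x, mod), atol=1e-5)

    def test_bilinear_gate_for_rectangular_input(self, rng):
        cfg = DIEAConfig(channels=8, reduction=4, min_mid_channels=2,
                         gate_resize=GateResize.BILINEAR)
        mod = DIEA(cfg, rng=rng).eval()
        x = rng.standard_normal((8, 6, 10))
        assert diea_forward(x, mod).shape == (8, 6, 10)

    def test_gradient_matches_finite_differences(self, rng):
        cfg = DIEAConfig(channels=6, reduction=2, min_mid_channels=2)
        mod = DIEA(cfg, rng=rng).eval()
        for p in mod.parameters():
            p.data = p.data.astype(np.float64)
        x0 = rng.standard_normal((1, 6, 4, 4))
        xt = Tensor(x0.copy(), requires_grad=True)
        (mod(xt) ** 2.0).mean().backward()
        g = xt.grad
        eps = 1e-6
        coords = [tuple(rng.integers(0, s) for s in x0.shape) for _ in range(5)]
        for idx in coords:
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += eps; xm[idx] -= eps
            fd = (float((mod(Tensor(xp)).data ** 2).mean())
                  - float((mod(Tensor(xm)).data ** 2).mean())) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-2, abs=1e-10)
            assert np.isfinite(g[idx])
        assert np.abs(g).max() > 0


def loop_coordinate_attention(x, mod):
    """Independent per-position reference of the CA equations."""
    c, H, W = x.shape
    a_h = np.array([[x[ci, hi, :].mean() for hi in range(H)] for ci in range(c)])
    a_w = np.array([[x[ci, :, wi].mean() for wi in range(W)] for ci in range(c)])
    s = np.concatenate([a_h, a_w], axis=1)
    w1 = mod.f1.weight.data[:, :, 0, 0].astype(float)
    z = w1 @ s
    bn = mod.bn1
    z = (z - bn.running_mean[:, None]) / np.sqrt(bn.running_var[:, None] + bn.eps)
    z = z * bn.weight.data[:, None] + bn.bias.data[:, None]
    z = z * np.clip(z + 3, 0, 6) / 6
    wh = mod.conv_h.weight.data[:, :, 0, 0].astype(float)
    ww = mod.conv_w.weight.data[:, :, 0, 0].astype(float)
    gh = 1 / (1 + np.exp(-(wh @ z[:, :H] + mod.conv_h.bias.data[:, None])))
    gw = 1 / (1 + np.exp(-(ww @ z[:, H:] + mod.conv_w.bias.data[:, None])))
    y = np.empty_like(x)
    for ci in range(c):
        for hi in range(H):
            for wi in range(W):
                y[ci, hi, wi] = x[ci, hi, wi] * gh[ci, hi] * gw[ci, wi]
    return y, gh, gw


class TestCoordinateAttention:
    def test_matches_independent_reference(self, rng):
        mod = CoordinateAttention(8, reduction=4, min_mid_channels=2, rng=rng).eval()
        x = rng.standard_normal((8, 5, 7))
        y_ref, _, _ = loop_coordinate_attention(x, mod)
        np.testing.assert_allclose(ca_forward(x, mod), y_ref, atol=1e-5)
        np.testing.assert_allclose(mod(Tensor(x[None].astype(np.float32))).data[0],
                                   y_ref, atol=1e-5)

    def test_gate_factorizes(self, rng):
        mod = CoordinateAttention(8, reduction=4, min_mid_channels=2, rng=rng).eval()
        x = rng.standard_normal((1, 8, 6, 6)).astype(np.float32)
        mod(Tensor(x))
        g = mod.last_gate[0]
        for c in range(8):
            s = np.linalg.svd(g[c], compute_uv=False)
            assert s[1] <= 1e-6 * s[0]

    def test_constant_input_gives_constant_gate(self, rng):
        mod = CoordinateAttention(8, reduction=4, min_mid_channels=2, rng=rng).eval()
        x = np.full((1, 8, 6, 6), 3.0, np.float32)
        mod(Tensor(x))
        g = mod.last_gate[0]
        assert np.allclose(g, g[:, :1, :1], atol=1e-6)
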