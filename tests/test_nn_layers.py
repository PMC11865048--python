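"""Neural-network core: activations, gradients, attention blocks, counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mungseed.nn import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    ChannelConv1d,
    Conv2d,
    ConvSpec,
    DmsBlock,
    EcaBlock,
    InvertedResidual,
    Mish,
    ReLU6,
    UpsampleNearest2d,
    conv_flop_count,
    conv_param_count,
    eca_kernel_size,
    mish,
    relu6,
)
from mungseed.nn.functional import mish_grad


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(-2.0, 0.0), (0.0, 0.0), (3.0, 3.0),
                                            (6.0, 6.0), (8.0, 6.0)])
    def test_relu6_clamp(self, x, expected):
        assert relu6(x) == expected

    @pytest.mark.parametrize("x,expected,tol", [
        (0.0, 0.0, 0.0),
        (1.0, 0.8651, 1e-4),       # 1 * tanh(ln(1 + e))
        (20.0, 20.0, 1e-6),        # saturates to identity
    ])
    def test_mish_values(self, x, expected, tol):
        assert mish(x) == pytest.approx(expected, abs=tol)

    def test_mish_negative_limit(self):
        assert mish(-30.0) == pytest.approx(0.0, abs=1e-10)

    def test_mish_global_minimum(self):
        """Grid search: the non-monotonic dip bottoms out near -0.3088."""
        xs = np.linspace(-6, 2, 200001)
        ys = mish(xs)
        assert ys.min() == pytest.approx(-0.30884, abs=1e-4)

    def test_mish_smooth(self):
        """Analytic derivative matches central differences everywhere sampled."""
        xs = np.linspace(-8, 8, 401)
        num = (mish(xs + 1e-6) - mish(xs - 1e-6)) / 2e-6
        assert np.allclose(mish_grad(xs), num, atol=1e-7)


class TestEcaKernel:
    @pytest.mark.parametrize("channels,k", [(2, 1), (16, 3), (24, 3), (32, 3),
                                            (64, 3), (96, 3), (160, 5), (320, 5)])
    def test_kernel_size(self, channels, k):
        assert eca_kernel_size(channels) == k

    @given(st.integers(min_value=1, max_value=4096))
    @settings(max_examples=100, deadline=None)
    def test_odd_and_monotone(self, c):
        k = eca_kernel_size(c)
        assert k % 2 == 1 and k >= 1
        assert eca_kernel_size(c + 1) >= k

    def test_rejects_zero_channels(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)


class TestClosedFormCounts:
    @pytest.mark.parametrize("spec,params", [
        (ConvSpec(3, 16, 32), 4608),            # K^2 C_in C_out
        (ConvSpec(3, 96, 96, groups=96), 864),   # depthwise: K^2 C
        (ConvSpec(1, 3, 8, bias=True), 32),      # 3*8 + 8
    ])
    def test_examples(self, spec, params):
        assert conv_param_count(spec) == params

    def test_group_one_equals_standard(self):
        a = ConvSpec(5, 12, 24, h_out=7, w_out=7, groups=1)
        assert conv_flop_count(a) == 5 * 5 * 12 * 24 * 49

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ConvSpec(3, 10, 8, groups=4)

    @given(k=st.sampled_from([1, 3, 5]),
           cig=st.integers(1, 6), cog=st.integers(1, 6), g=st.integers(1, 4),
           bias=st.booleans())
    @settings(max_examples=40, deadline=None)
    def test_closed_form_matches_enumeration(self, k, cig, cog, g, bias):
        """Table of closed forms vs literally counting a built layer's scalars."""
        c_in, c_out = cig * g, cog * g
        layer = Conv2d(c_in, c_out, k, groups=g, bias=bias)
        spec = ConvSpec(k, c_in, c_out, groups=g, bias=bias)
        assert conv_param_count(spec) == layer.param_count()

    @given(k=st.sampled_from([1, 3]), c=st.integers(1, 8), h=st.integers(1, 6))
    @settings(max_examples=30, deadline=None)
    def test_depthwise_reduces_to_k2c(self, k, c, h):
        spec = ConvSpec(k, c, c, h_out=h, w_out=h, groups=c)
        assert conv_param_count(spec) == k * k * c
        assert conv_flop_count(spec) == k * k * c * h * h


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.mark.parametrize("make_layer,shape", [
    (lambda rng: Conv2d(3, 5, 3, stride=2, padding=1, rng=rng), (2, 3, 6, 6)),
    (lambda rng: Conv2d(4, 4, 3, padding=1, groups=4, rng=rng), (2, 4, 5, 5)),
    (lambda rng: Conv2d(4, 6, 3, padding=1, groups=2, rng=rng), (1, 4, 5, 5)),
    (lambda rng: BatchNorm2d(3), (3, 3, 4, 4)),
    (lambda rng: Mish(), (2, 3, 4, 4)),
    (lambda rng: ReLU6(), (2, 3, 4, 4)),
    (lambda rng: AdaptiveAvgPool2d(2), (2, 3, 5, 5)),
    (lambda rng: UpsampleNearest2d((6, 6)), (2, 3, 3, 3)),
    (lambda rng: ChannelConv1d(3, rng=rng), (3, 8)),
    (lambda rng: EcaBlock(8, rng=rng), (2, 8, 3, 3)),
    (lambda rng: DmsBlock(4, pooled_size=2, rng=rng), (2, 4, 5, 5)),
    (lambda rng: InvertedResidual(4, 4, 2, 1, "hp", dms_pooled_size=2, rng=rng),
     (2, 4, 6, 6)),
    (lambda rng: InvertedResidual(4, 6, 2, 2, "baseline", rng=rng), (2, 4, 6, 6)),
])
def test_backward_matches_numerical_gradient(make_layer, shape, rng):
    """Analytic backward vs central differences, inputs and every parameter."""
    layer = make_layer(np.random.default_rng(5))
    x = rng.normal(size=shape)
    proj = rng.normal(size=layer.forward(x.copy()).shape)

    def loss():
        return float((layer.forward(x) * proj).sum())

    layer.zero_grad()
    layer.forward(x)
    gx = layer.backward(proj)
    assert np.abs(gx - _num_grad(loss, x)).max() < 1e-5
    for _, p in layer.named_params():
        assert np.abs(p.grad - _num_grad(loss, p.value)).max() < 1e-5


class TestBlocks:
    def test_eca_preserves_shape_and_zeros(self, rng):
        block = EcaBlock(16)
        x = rng.normal(size=(2, 16, 5, 5))
        assert block.forward(x).shape == x.shape
        assert block.forward(np.zeros((1, 16, 4, 4))).max() == 0.0

    def test_eca_gate_in_unit_interval(self, rng):
        block = EcaBlock(8)
        x = np.abs(rng.normal(size=(1, 8, 4, 4))) + 0.1
        out = block.forward(x)
        ratio = out / x
        assert (ratio > 0).all() and (ratio < 1).all()

    def test_eca_param_count_is_kernel_size(self):
        assert EcaBlock(320).param_count() == 5
        assert EcaBlock(32).param_count() == 3

    def test_dms_shape_and_param_count(self, rng):
        for h, w in ((7, 7), (3, 9), (1, 1)):
            block = DmsBlock(96)
            x = rng.normal(size=(1, 96, h, w))
            assert block.forward(x).shape == x.shape
        assert DmsBlock(96).param_count() == 1824  # 19 per channel

    def test_dms_bounded_amplification(self, rng):
        block = DmsBlock(8)
        x = rng.normal(size=(2, 8, 6, 6))
        out = block.forward(x)
        assert (np.abs(out) <= 2 * np.abs(x) + 1e-12).all()  # gate in (0,1)

    def test_bottleneck_shortcut_only_at_stride1_matching(self, rng):
        x = rng.normal(size=(1, 8, 8, 8))
        with_sc = InvertedResidual(8, 8, 6, 1, "baseline", rng=np.random.default_rng(1))
        without = InvertedResidual(8, 16, 6, 2, "baseline", rng=np.random.default_rng(1))
        assert with_sc.use_shortcut and not without.use_shortcut
        body = with_sc.body.forward(x)
        assert np.allclose(with_sc.forward(x), body + x)
        assert without.forward(x).shape == (1, 16, 4, 4)

    def test_bottleneck_param_count_matches_closed_forms(self):
        """Sum of the conv closed forms plus affine BN terms."""
        t, c_in, c_out = 6, 16, 24
        block = InvertedResidual(c_in, c_out, t, 2, "baseline")
        hidden = c_in * t
        expected = (conv_param_count(ConvSpec(1, c_in, hidden)) + 2 * hidden
                    + conv_param_count(ConvSpec(3, hidden, hidden, groups=hidden)) + 2 * hidden
                    + conv_param_count(ConvSpec(1, hidden, c_out)) + 2 * c_out)
        assert block.param_count() == expected

    def test_hp_bottleneck_adds_dms_and_eca_params(self):
        base = InvertedResidual(16, 24, 6, 2, "baseline")
        hp = InvertedResidual(16, 24, 6, 2, "hp")
        hidden = 16 * 6
        assert hp.param_count() - base.param_count() == 19 * hidden + eca_kernel_size(24)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            InvertedResidual(8, 8, 6, 3)
        with pytest.raises(ValueError):
            InvertedResidual(8, 8, 0, 1)
        with pytest.raises(ValueError):
            InvertedResidual(8, 8, 6, 1, "fancy")
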