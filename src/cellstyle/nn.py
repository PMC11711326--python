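"""Neural-network building blocks: modules, convolutions, normalization.

Layers follow the residual architecture used throughout the model family:
stride-1 3x3 convolutions, 2x2 average pooling for downsampling, nearest-
neighbour upsampling for the decoder, instance normalization in the encoder
and adaptive instance normalization (AdaIN) in the decoder. LeakyReLU slope
is 0.2 everywhere.

All parameters are He-initialized: weights ~ N(0, 2/fan_in), biases zero.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from . import ag
from .ag import Tensor

LEAKY_SLOPE = 0.2
IN_EPS = 1e-5

_PARAM_DTYPE = [np.float64]


@contextmanager
def param_dtype(dtype):
    """Build parameters in the given float dtype inside the context.

    float64 is the default; float32 halves the arithmetic cost of training
    at a precision GAN training does not need.
    """
    _PARAM_DTYPE.append(np.dtype(dtype))
    try:
        yield
    finally:
        _PARAM_DTYPE.pop()


class Parameter(Tensor):
    """A leaf tensor that optimizers update."""

    def __init__(self, data):
        super().__init__(
            np.asarray(data, dtype=_PARAM_DTYPE[-1]), requires_grad=True
        )


class Module:
    """Minimal parameter container with named state."""

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng, fan_in, shape):
    """He-style draw: N(0, 2/fan_in)."""
    if fan_in <= 0:
        raise ValueError("fan-in must be positive")
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features, out_features, rng):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(he_init(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Conv2d(Module):
    """Stride-1 2-D convolution (kernel 1 or 3), implemented with shifted
    slices feeding a single matmul so the whole op is built from engine
    primitives and stays twice-differentiable."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, padding=None):
        if kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = (kernel_size // 2) if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            he_init(rng, fan_in, (out_channels, kernel_size, kernel_size, in_channels))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x):
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        k, p = self.kernel_size, self.padding
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        if k == 1 and p == 0:
            cols = x
        else:
            xp = ag.pad2d(x, p)
            parts = []
            for di in range(k):
                for dj in range(k):
                    parts.append(
                        xp[:, :, di : di + ho, dj : dj + wo]
                    )
            cols = ag.concat(parts, axis=1)  # (b, k*k*c, ho, wo)
        flat = cols.transpose(0, 2, 3, 1).reshape(b * ho * wo, k * k * c)
        wmat = self.weight.reshape(self.out_channels, k * k * c).transpose(1, 0)
        out = ag.matmul(flat, wmat)
        out = ag.add(out, self.bias)
        return out.reshape(b, ho, wo, self.out_channels).transpose(0, 3, 1, 2)


def avg_pool2(x):
    """2x2 average pooling (spatial dims must be even)."""
    return ag.mul(
        ag.add(
            ag.add(x[:, :, 0::2, 0::2], x[:, :, 1::2, 0::2]),
            ag.add(x[:, :, 0::2, 1::2], x[:, :, 1::2, 1::2]),
        ),
        0.25,
    )


def upsample2(x):
    """2x nearest-neighbour upsampling."""
    b, c, h, w = x.shape
    y = x.reshape(b, c, h, 1, w, 1)
    y = ag.broadcast_to(y, (b, c, h, 2, w, 2))
    return y.reshape(b, c, 2 * h, 2 * w)


def standardize(x, eps=IN_EPS):
    """Per-instance, per-channel spatial standardization (the parameter-free
    core of instance normalization): (x - mu) / sqrt(var + eps)."""
    if not np.isfinite(x.data).all():
        bad = np.argwhere(~np.isfinite(x.data))[0]
        raise ValueError(
            f"non-finite activation at instance {int(bad[0])}, channel {int(bad[1])}"
        )
    mu = x.mean(axis=(2, 3), keepdims=True)
    centred = ag.add(x, ag.mul(mu, -1.0))
    var = ag.tmean(ag.power(centred, 2.0), axis=(2, 3), keepdims=True)
    return ag.mul(centred, ag.power(ag.add(var, eps), -0.5))


def instance_norm(x, gamma, beta, eps=IN_EPS):
    """Instance normalization with affine parameters: gamma * y + beta."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    y = standardize(x, eps)
    return ag.add(ag.mul(y, gamma), beta)


class InstanceNorm(Module):
    """IN layer with learned per-channel affine (gamma init 1, beta init 0)."""

    def __init__(self, channels, eps=IN_EPS):
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta, self.eps)


class AdaIN(Module):
    """Adaptive instance normalization: a linear head maps the style vector to
    per-channel (scale, shift); the feature map is standardized and re-styled
    as scale * IN(x) + shift. The head's scale output is offset by +1 so an
    untrained (zero-weight) head is the identity affine."""

    def __init__(self, channels, style_dim, rng, eps=IN_EPS):
        self.channels = channels
        self.style_dim = style_dim
        self.eps = eps
        self.head = Linear(style_dim, 2 * channels, rng)

    def forward(self, x, style):
        if style.shape[-1] != self.style_dim:
            raise ValueError(
                f"style length {style.shape[-1]} != expected {self.style_dim}"
            )
        b = x.shape[0]
        params = self.head(style)  # (b, 2C)
        scale = ag.add(params[:, : self.channels], 1.0).reshape(b, self.channels, 1, 1)
        shift = params[:, self.channels :].reshape(b, self.channels, 1, 1)
        y = standardize(x, self.eps)
        return ag.add(ag.mul(y, scale), shift)


class DownResBlock(Module):
    """Residual block: IN -> LeakyReLU -> 3x3 conv -> [avg pool] -> IN ->
    LeakyReLU -> 3x3 conv, plus a skip with optional pooling and a 1x1 conv
    when channel counts change."""

    def __init__(self, in_ch, out_ch, rng, downsample=True):
        self.downsample = downsample
        self.norm1 = InstanceNorm(in_ch)
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.norm2 = InstanceNorm(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.skip = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x):
        h = ag.leaky_relu(self.norm1(x), LEAKY_SLOPE)
        h = self.conv1(h)
        if self.downsample:
            h = avg_pool2(h)
        h = ag.leaky_relu(self.norm2(h), LEAKY_SLOPE)
        h = self.conv2(h)
        s = avg_pool2(x) if self.downsample else x
        if self.skip is not None:
            s = self.skip(s)
        return ag.add(h, s)


class UpResBlock(Module):
    """Decoder residual block conditioned on a style vector via AdaIN."""

    def __init__(self, in_ch, out_ch, style_dim, rng, upsample=True):
        self.upsample = upsample
        self.adain1 = AdaIN(in_ch, style_dim, rng)
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.adain2 = AdaIN(out_ch, style_dim, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.skip = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x, style):
        h = ag.leaky_relu(self.adain1(x, style), LEAKY_SLOPE)
        if self.upsample:
            h = upsample2(h)
        h = self.conv1(h)
        h = ag.leaky_relu(self.adain2(h, style), LEAKY_SLOPE)
        h = self.conv2(h)
        s = upsample2(x) if self.upsample else x
        if self.skip is not None:
            s = self.skip(s)
        return ag.add(h, s)
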