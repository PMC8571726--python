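"""Hierarchical convolutional network model of the ventral visual stream.

The model is a 15-layer feedforward network: a *feature extraction* stack of
8 convolutional layers interleaved with 5 non-overlapping 2x2 max-pooling
layers, followed by a *classification* head (global average pooling over the
final 768 feature maps and a 1000-way softmax output).  Every convolutional
stage applies, in order: convolution with bias (stride 1, zero padding
preserving the spatial size) -> batch normalization -> rectification
f(x)=max(x,0); local response normalization across adjacent feature maps (a
divisive model of lateral inhibition between units sharing a receptive
field) follows rectification on the configured layers — by default the
first two convolutional stages, the placement of the architecture the LRN
constants come from.

The final feature-extraction layer (table index 13) holds 768 maps of 7x7
units, i.e. 37,632 units; these are the "recorded" population in all
numerosity analyses.  Multiplicative Gaussian noise (mu=1, sigma=0.15),
re-drawn per unit and per presentation, can be injected into the outputs of
every convolutional stage so that even a constant stimulus (the empty set)
evokes variable responses.

Batch normalization standardizes each feature map (zero mean, unit variance
before the learnable affine).  During stimulus presentation the per-map
statistics are taken from the network's stored running estimates
(evaluation mode).  For an untrained network the freshly initialized
running statistics make BN the identity transform; responses to blank
displays are then carried by the convolution biases and varied by the
multiplicative noise.  :func:`calibrate_batch_norm` can instead estimate
the statistics from a stimulus sample when ensemble standardization is
wanted.

Everything runs on NumPy arrays in channel-last (B, H, W, C) layout;
convolutions are im2col + BLAS matrix products, fast enough to push
hundreds of 224x224 stimuli through the full network on one CPU core.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import fft as sfft

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "LRNParams",
    "NoiseParams",
    "TrainConfig",
    "ActivationMatrix",
    "Network",
    "ConfigurationError",
    "default_config",
    "tiny_config",
    "config_from_yaml",
    "config_to_yaml",
    "build_network",
    "local_response_normalize",
    "calibrate_batch_norm",
    "forward_record",
    "predict_proba",
    "top_k_predictions",
    "train_object_recognition",
    "save_activations",
    "load_activations",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Raised for an inconsistent layer chain or invalid normalization/noise
    parameters."""


# ---------------------------------------------------------------------------
# Architecture description
# ---------------------------------------------------------------------------

ROLE_INPUT = "input"
ROLE_CONV = "convolutional"
ROLE_MAXPOOL = "max-pooling"
ROLE_AVGPOOL = "average-pooling"
ROLE_SOFTMAX = "softmax-classifier"

_ROLES = {ROLE_INPUT, ROLE_CONV, ROLE_MAXPOOL, ROLE_AVGPOOL, ROLE_SOFTMAX}


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table.

    ``spatial_size`` is the size of the layer's *input*, following the
    convention of the architecture table; pooling layers emit half their
    input resolution, convolutional layers preserve it.
    """

    index: int
    role: str
    n_feature_maps: int
    spatial_size: int
    kernel_size: int  # 0 for the input layer

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ConfigurationError(f"layer {self.index}: unknown role {self.role!r}")


# The canonical architecture: (role, maps, spatial, kernel) per table row.
_CANONICAL_ROWS = [
    (ROLE_INPUT, 3, 224, 0),
    (ROLE_CONV, 32, 224, 9),
    (ROLE_MAXPOOL, 32, 224, 2),
    (ROLE_CONV, 48, 112, 9),
    (ROLE_MAXPOOL, 48, 112, 2),
    (ROLE_CONV, 96, 56, 7),
    (ROLE_MAXPOOL, 96, 56, 2),
    (ROLE_CONV, 192, 28, 5),
    (ROLE_MAXPOOL, 192, 28, 2),
    (ROLE_CONV, 384, 14, 5),
    (ROLE_MAXPOOL, 384, 14, 2),
    (ROLE_CONV, 768, 7, 5),
    (ROLE_CONV, 768, 7, 5),
    (ROLE_CONV, 768, 7, 5),
    (ROLE_AVGPOOL, 768, 7, 7),
    (ROLE_SOFTMAX, 1000, 1, 1),
]


@dataclass
class NetworkConfig:
    layers: list[LayerSpec]
    n_classes: int = 1000
    reduced: bool = False  # True for explicitly-flagged small test variants

    def validate(self) -> None:
        layers = self.layers
        if not layers or layers[0].role != ROLE_INPUT:
            raise ConfigurationError("layer 0 must be the input layer")
        size = layers[0].spatial_size
        for spec in layers[1:]:
            if spec.role in (ROLE_CONV, ROLE_MAXPOOL) and spec.spatial_size != size:
                raise ConfigurationError(
                    f"layer {spec.index}: expected spatial size {size}, "
                    f"table says {spec.spatial_size}"
                )
            if spec.role == ROLE_MAXPOOL:
                if size % 2:
                    raise ConfigurationError(
                        f"layer {spec.index}: cannot 2x2-pool odd size {size}"
                    )
                size //= 2
            elif spec.role == ROLE_AVGPOOL:
                if spec.kernel_size != size:
                    raise ConfigurationError(
                        f"layer {spec.index}: global average pool kernel "
                        f"{spec.kernel_size} != feature size {size}"
                    )
                size = 1
        if not self.reduced:
            rows = [
                (s.role, s.n_feature_maps, s.spatial_size, s.kernel_size)
                for s in layers
            ]
            if rows != _CANONICAL_ROWS:
                raise ConfigurationError(
                    "layer chain does not match the canonical 15-layer "
                    "architecture; pass reduced=True for test variants"
                )

    @property
    def input_size(self) -> int:
        return self.layers[0].spatial_size

    @property
    def final_feature_layer(self) -> int:
        """Table index of the last convolutional layer."""
        return max(s.index for s in self.layers if s.role == ROLE_CONV)

    def feature_shape(self, layer_index: int) -> tuple[int, int, int]:
        """(maps, height, width) of the *output* of the given table layer."""
        size = self.layers[0].spatial_size
        for spec in self.layers[1:]:
            if spec.role == ROLE_MAXPOOL:
                size //= 2
            if spec.index == layer_index:
                if spec.role not in (ROLE_CONV, ROLE_MAXPOOL):
                    raise ValueError(
                        f"layer {layer_index} is not a feature-extraction layer"
                    )
                return (spec.n_feature_maps, size, size)
        raise ValueError(f"no layer with index {layer_index}")


def default_config() -> NetworkConfig:
    layers = [
        LayerSpec(i, role, maps, spatial, kernel)
        for i, (role, maps, spatial, kernel) in enumerate(_CANONICAL_ROWS)
    ]
    cfg = NetworkConfig(layers=layers, n_classes=1000, reduced=False)
    cfg.validate()
    return cfg


def tiny_config(input_size: int = 64, n_classes: int = 10) -> NetworkConfig:
    """A reduced variant for fast tests: same role sequence, fewer maps,
    smaller input (must be divisible by 32)."""
    if input_size % 32:
        raise ConfigurationError("tiny input size must be divisible by 32")
    maps = [3, 8, 8, 12, 12, 16, 16, 16, 16, 24, 24, 24, 24, 24, 24, n_classes]
    kernels = [0, 5, 2, 5, 2, 3, 2, 3, 2, 3, 2, 3, 3, 3, input_size // 32, 1]
    sizes, s = [], input_size
    for role, _, _, _ in _CANONICAL_ROWS:
        sizes.append(s if role != ROLE_SOFTMAX else 1)
        if role == ROLE_MAXPOOL:
            s //= 2
    layers = [
        LayerSpec(i, _CANONICAL_ROWS[i][0], maps[i], sizes[i], kernels[i])
        for i in range(16)
    ]
    cfg = NetworkConfig(layers=layers, n_classes=n_classes, reduced=True)
    cfg.validate()
    return cfg


def config_to_yaml(cfg: NetworkConfig, path: str) -> None:
    import yaml

    doc = {
        "n_classes": cfg.n_classes,
        "reduced": cfg.reduced,
        "layers": [asdict(s) for s in cfg.layers],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str) -> NetworkConfig:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = NetworkConfig(
        layers=[LayerSpec(**row) for row in doc["layers"]],
        n_classes=int(doc.get("n_classes", 1000)),
        reduced=bool(doc.get("reduced", False)),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Normalization / noise / training parameters
# ---------------------------------------------------------------------------


@dataclass
class LRNParams:
    """Constants of the divisive lateral-inhibition normalization.

    b^i_{x,y} = a^i_{x,y} / (k + alpha * sum_j max(0, a^j_{x,y})^2)^beta with
    j running over feature maps max(0, i-n/2) ... min(N-1, i+n/2).
    """

    k: float = 2.0
    alpha: float = 1e-4
    beta: float = 0.75
    n: int = 15


@dataclass
class NoiseParams:
    """Multiplicative Gaussian response noise, drawn independently per unit
    and per stimulus presentation."""

    mu: float = 1.0
    sigma: float = 0.15
    enabled: bool = True


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 256
    learning_rate: float = 0.1
    momentum: float = 0.9


# ---------------------------------------------------------------------------
# Network container & initialization
# ---------------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class ConvStage:
    layer_index: int
    W: np.ndarray  # (out_maps, in_maps, k, k)
    bias: np.ndarray  # (out_maps,)
    gamma: np.ndarray  # (out_maps,)
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray

    def w_matrix(self) -> np.ndarray:
        """(k*k*in_maps, out_maps) weight matrix for channel-last im2col."""
        O, C, k, _ = self.W.shape
        return np.ascontiguousarray(
            self.W.transpose(2, 3, 1, 0).reshape(k * k * C, O)
        )

    def fft_kernels(self, S: int) -> np.ndarray:
        """Cached (S*Sr, in_maps, out_maps) complex64 kernel spectra for the
        FFT convolution path (inference only; invalidated on weight change
        via the cache key)."""
        cache = self.__dict__.setdefault("_fft_cache", {})
        key = (S, self.W.ctypes.data)
        if key not in cache:
            cache.clear()
            flipped = self.W[:, :, ::-1, ::-1].astype(np.float32)
            wf = sfft.rfft2(flipped, s=(S, S), axes=(2, 3))  # (O, C, S, Sr)
            cache[key] = np.ascontiguousarray(
                wf.transpose(2, 3, 1, 0).reshape(-1, wf.shape[1], wf.shape[0])
            ).astype(np.complex64)
        return cache[key]


@dataclass
class Network:
    config: NetworkConfig
    stages: list  # ConvStage or ("maxpool", index)
    fc_W: np.ndarray  # (n_classes, final_maps)
    fc_b: np.ndarray
    lrn: LRNParams
    seed: int
    lrn_layers: tuple = ()  # conv layer indices carrying LRN
    bn_calibrated: bool = False

    @property
    def final_feature_layer(self) -> int:
        return self.config.final_feature_layer

    def conv_stages(self) -> list[ConvStage]:
        return [st for st in self.stages if isinstance(st, ConvStage)]


def _xavier_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def build_network(
    config: NetworkConfig | None = None,
    seed: int = 0,
    lrn: LRNParams | None = None,
    lrn_layers: Sequence[int] | None = None,
    dtype=np.float32,
) -> Network:
    """Build the network with Xavier-initialized (uniform, fan-based) random
    weights drawn from ``seed``.  The same seed always yields the same
    weights.

    ``lrn_layers`` lists the convolutional layers whose outputs receive
    lateral-inhibition normalization; the default is the first two
    convolutional stages, the placement of the architecture the LRN
    constants were taken from.
    """
    config = config or default_config()
    config.validate()
    lrn = lrn or LRNParams()
    if lrn.k <= 0 or lrn.beta < 0 or lrn.n < 1:
        raise ConfigurationError("invalid LRN constants (need k>0, beta>=0, n>=1)")
    rng = np.random.default_rng(seed)
    stages: list = []
    in_maps = config.layers[0].n_feature_maps
    for spec in config.layers[1:]:
        if spec.role == ROLE_CONV:
            k = spec.kernel_size
            fan_in = in_maps * k * k
            fan_out = spec.n_feature_maps * k * k
            W = _xavier_uniform(
                rng, (spec.n_feature_maps, in_maps, k, k), fan_in, fan_out, dtype
            )
            bb = 1.0 / np.sqrt(fan_in)
            bias = rng.uniform(-bb, bb, size=spec.n_feature_maps).astype(dtype)
            stages.append(
                ConvStage(
                    layer_index=spec.index,
                    W=W,
                    bias=bias,
                    gamma=np.ones(spec.n_feature_maps, dtype),
                    beta=np.zeros(spec.n_feature_maps, dtype),
                    running_mean=np.zeros(spec.n_feature_maps, dtype),
                    running_var=np.ones(spec.n_feature_maps, dtype),
                )
            )
            in_maps = spec.n_feature_maps
        elif spec.role == ROLE_MAXPOOL:
            stages.append(("maxpool", spec.index))
    n_classes = config.n_classes
    fc_W = _xavier_uniform(rng, (n_classes, in_maps), in_maps, n_classes, dtype)
    fc_b = np.zeros(n_classes, dtype)
    conv_indices = [s.index for s in config.layers if s.role == ROLE_CONV]
    if lrn_layers is None:
        lrn_layers = tuple(conv_indices[:2])
    else:
        lrn_layers = tuple(lrn_layers)
        if not set(lrn_layers) <= set(conv_indices):
            raise ConfigurationError(
                f"lrn_layers {lrn_layers} must be convolutional layers"
            )
    return Network(
        config=config, stages=stages, fc_W=fc_W, fc_b=fc_b, lrn=lrn, seed=seed,
        lrn_layers=lrn_layers,
    )


# ---------------------------------------------------------------------------
# Primitive layer operations (channel-last: B, H, W, C)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """x: (B, H, W, C) -> (B*H*W, k*k*C), stride-1 'same' zero padding."""
    B, H, W, C = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    col = np.empty((B, H, W, k * k * C), x.dtype)
    for ki in range(k):
        for kj in range(k):
            o = (ki * k + kj) * C
            col[..., o : o + C] = xp[:, ki : ki + H, kj : kj + W, :]
    return col.reshape(B * H * W, k * k * C)


_FFT_MIN_SIZE = 56  # spatial size above which the FFT path beats im2col


def _conv_same_fft(x: np.ndarray, st: "ConvStage") -> np.ndarray:
    """Same convolution via real FFTs: per frequency bin one small complex
    matrix product contracts the input channels.  Much faster than im2col
    for large spatial maps; numerically equal to within float32 rounding."""
    O, C, k, _ = st.W.shape
    B, H, W, _ = x.shape
    S = sfft.next_fast_len(H + k - 1, real=True)
    xt = np.moveaxis(x, -1, 1)  # (B, C, H, W)
    Xf = sfft.rfft2(xt, s=(S, S), axes=(2, 3)).astype(np.complex64)  # (B,C,S,Sr)
    Sr = Xf.shape[-1]
    Xf_t = np.ascontiguousarray(Xf.transpose(2, 3, 0, 1).reshape(S * Sr, B, C))
    Yf = Xf_t @ st.fft_kernels(S)  # (S*Sr, B, O)
    Yf = Yf.reshape(S, Sr, B, O).transpose(2, 3, 0, 1)
    y = sfft.irfft2(Yf, s=(S, S), axes=(2, 3))
    p = k // 2
    out = y[:, :, p : p + H, p : p + W].astype(np.float32)
    return np.ascontiguousarray(np.moveaxis(out, 1, -1))


def _conv_same(x: np.ndarray, st_or_W, allow_fft: bool = True) -> np.ndarray:
    """Stride-1 same-padded convolution; x (B,H,W,C) -> (B,H,W,O)."""
    B, H, W, _ = x.shape
    if isinstance(st_or_W, ConvStage):
        if allow_fft and H >= _FFT_MIN_SIZE and x.dtype == np.float32:
            out = _conv_same_fft(x, st_or_W)
            out += st_or_W.bias
            return out
        Wmat = st_or_W.w_matrix()
        k = st_or_W.W.shape[2]
        O = st_or_W.W.shape[0]
        col = _im2col(x, k)
        out = (col @ Wmat).reshape(B, H, W, O)
        out += st_or_W.bias
        return out
    # raw (O, C, k, k) kernel, no bias
    O, C, k, _ = st_or_W.shape
    Wmat = np.ascontiguousarray(st_or_W.transpose(2, 3, 1, 0).reshape(-1, O))
    col = _im2col(x, k)
    return (col @ Wmat).reshape(B, H, W, O)


def _col2im(dcol: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add (B*H*W, k*k*C) back to (B, H, W, C)."""
    B, H, W, C = shape
    p = k // 2
    dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dcol.dtype)
    d = dcol.reshape(B, H, W, k * k * C)
    for ki in range(k):
        for kj in range(k):
            o = (ki * k + kj) * C
            dxp[:, ki : ki + H, kj : kj + W, :] += d[..., o : o + C]
    return dxp[:, p : p + H, p : p + W, :]


def _maxpool2(x: np.ndarray):
    B, H, W, C = x.shape
    xr = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    xr = xr.reshape(B, H // 2, W // 2, C, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    B, H, W, C = in_shape
    dxr = np.zeros((B, H // 2, W // 2, C, 4), dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(B, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dxr.reshape(B, H, W, C)


def _lrn_window_sum(s: np.ndarray, n: int) -> np.ndarray:
    """Sum of ``s`` over a clipped window of half-width n//2 along the last
    (feature-map) axis."""
    N = s.shape[-1]
    half = n // 2
    cs = np.cumsum(s, axis=-1, dtype=s.dtype)
    cs = np.concatenate([np.zeros(s.shape[:-1] + (1,), s.dtype), cs], axis=-1)
    hi = np.minimum(np.arange(N) + half, N - 1) + 1
    lo = np.maximum(np.arange(N) - half, 0)
    return cs[..., hi] - cs[..., lo]


def _pow_beta(d: np.ndarray, beta: float) -> np.ndarray:
    if beta == 0.75:  # d**0.75 == sqrt(d * sqrt(d)); much faster than pow
        return np.sqrt(d * np.sqrt(d))
    return np.power(d, beta)


def local_response_normalize(
    a: np.ndarray, params: LRNParams | None = None, channel_axis: int = -3
) -> np.ndarray:
    """Divisive normalization across neighbouring feature maps at each
    spatial location (lateral inhibition):

        b^i = a^i / (k + alpha * sum_{j in window(i)} max(0, a^j)^2)^beta

    ``channel_axis`` names the feature-map axis (default -3 for the
    conventional (..., C, H, W) map-stack layout).
    """
    params = params or LRNParams()
    if params.k <= 0 or params.beta < 0 or params.n < 1:
        raise ConfigurationError("invalid LRN constants (need k>0, beta>=0, n>=1)")
    a = np.asarray(a)
    if a.ndim < 3:
        raise ValueError("expected at least 3 dimensions (maps + 2 spatial)")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite input to local_response_normalize")
    am = np.moveaxis(a, channel_axis, -1)
    s = np.square(np.maximum(am, 0))
    denom = params.k + params.alpha * _lrn_window_sum(s, params.n)
    return np.moveaxis(am / _pow_beta(denom, params.beta), -1, channel_axis)


def _lrn_forward_fast(r: np.ndarray, params: LRNParams) -> np.ndarray:
    """Channel-last LRN for non-negative (post-ReLU) inputs, in-place-ish."""
    denom = params.k + params.alpha * _lrn_window_sum(np.square(r), params.n)
    r /= _pow_beta(denom, params.beta)
    return r


def _lrn_backward(g, r, denom, params: LRNParams):
    """Gradient through b = r * denom**-beta with denom = k + alpha*winsum(r^2)
    for non-negative (post-ReLU) channel-last r."""
    t = g * r * np.power(denom, -params.beta - 1.0)
    back = _lrn_window_sum(t, params.n)  # the clipped window is symmetric
    return g * np.power(denom, -params.beta) - 2.0 * params.alpha * params.beta * r * back


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Forward pass and activation recording
# ---------------------------------------------------------------------------


def _as_batch(images: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Accept (H,W), (B,H,W) grayscale or (B,H,W,3); return (B,H,W,3)."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = np.repeat(x[..., None], config.layers[0].n_feature_maps, axis=-1)
    size = config.input_size
    if x.shape[1] != size or x.shape[2] != size:
        raise ValueError(
            f"input images are {x.shape[1]}x{x.shape[2]}, network expects {size}x{size}"
        )
    return x


def _bn_apply(z: np.ndarray, st: ConvStage, mean, var) -> np.ndarray:
    scale = (st.gamma / np.sqrt(var + _BN_EPS)).astype(z.dtype)
    shift = (st.beta - mean * scale).astype(z.dtype)
    z *= scale
    z += shift
    return z


def _forward_features(
    net: Network,
    x: np.ndarray,
    layer_index: int,
    noise: NoiseParams,
    rng: np.random.Generator | None,
    bn_mode: str,
):
    """Run the feature-extraction stack up to (and including) ``layer_index``."""
    if bn_mode not in ("running", "batch"):
        raise ValueError("bn_mode must be 'running' or 'batch'")
    for st in net.stages:
        if isinstance(st, ConvStage):
            z = _conv_same(x, st)
            if bn_mode == "batch":
                mean = z.mean(axis=(0, 1, 2))
                var = z.var(axis=(0, 1, 2))
            else:
                mean, var = st.running_mean, st.running_var
            y = _bn_apply(z, st, mean, var)
            r = np.maximum(y, 0, out=y)
            b = (
                _lrn_forward_fast(r, net.lrn)
                if st.layer_index in net.lrn_layers
                else r
            )
            if noise.enabled and rng is not None:
                f = rng.standard_normal(b.shape, dtype=np.float32)
                f *= noise.sigma
                f += noise.mu
                b *= f
                np.maximum(b, 0, out=b)
            x = b
            idx = st.layer_index
        else:
            x, _ = _maxpool2(x)
            idx = st[1]
        if idx == layer_index:
            return x
    raise ValueError(f"layer {layer_index} is not a feature-extraction layer")


def calibrate_batch_norm(
    net: Network, images: np.ndarray, chunk: int = 6
) -> Network:
    """Estimate batch-normalization statistics from a stimulus sample.

    Streams the sample layer by layer: at each convolutional stage the
    per-map mean and variance of the pre-normalization responses (over the
    sample and all spatial positions) are stored as the stage's running
    statistics, then the stage output is formed with exactly those
    statistics.  Afterwards the network can present arbitrary stimuli in
    evaluation mode.  Noise is never applied during calibration.
    """
    x = _as_batch(images, net.config)
    for st in net.stages:
        if isinstance(st, ConvStage):
            B = x.shape[0]
            maps = st.W.shape[0]
            out = np.empty(x.shape[:3] + (maps,), np.float32)
            for lo in range(0, B, chunk):
                out[lo : lo + chunk] = _conv_same(x[lo : lo + chunk], st)
            st.running_mean = out.mean(axis=(0, 1, 2))
            st.running_var = out.var(axis=(0, 1, 2))
            y = _bn_apply(out, st, st.running_mean, st.running_var)
            r = np.maximum(y, 0, out=y)
            x = (
                _lrn_forward_fast(r, net.lrn)
                if st.layer_index in net.lrn_layers
                else r
            )
        else:
            x, _ = _maxpool2(x)
    net.bn_calibrated = True
    return net


@dataclass
class ActivationMatrix:
    """Unit responses (units x stimuli) at one feature-extraction layer.

    ``unit_coords`` gives the (feature map, row, column) of every unit, so
    the (maps, h, w) decomposition of the layer is recoverable.
    """

    values: np.ndarray  # (n_units, n_stimuli) float32, >= 0
    unit_coords: np.ndarray  # (n_units, 3) int
    stimulus_ids: np.ndarray  # (n_stimuli,)
    layer_index: int
    attrs: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]


def forward_record(
    net: Network,
    images: np.ndarray,
    layer_index: int | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    bn_mode: str = "running",
    stimulus_ids: Sequence | None = None,
    chunk: int = 6,
) -> ActivationMatrix:
    """Present a stimulus batch and record unit responses at one layer.

    ``bn_mode`` is "running" (evaluation mode: per-map statistics from the
    stored running estimates, see :func:`calibrate_batch_norm`) or "batch"
    (statistics of the presented batch itself, which is then processed
    jointly and should be small).
    """
    noise = noise if noise is not None else NoiseParams()
    layer_index = layer_index if layer_index is not None else net.final_feature_layer
    x = _as_batch(images, net.config)
    B = x.shape[0]
    rng = np.random.default_rng(seed) if noise.enabled else None
    maps, h, w = net.config.feature_shape(layer_index)
    out = np.empty((B, h * w * maps), dtype=np.float32)
    if bn_mode == "batch":
        chunk = B
    for lo in range(0, B, chunk):
        acts = _forward_features(
            net, x[lo : lo + chunk], layer_index, noise, rng, bn_mode
        )
        out[lo : lo + chunk] = acts.reshape(acts.shape[0], -1)
    yy, xx, cc = np.unravel_index(np.arange(h * w * maps), (h, w, maps))
    coords = np.stack([cc, yy, xx], axis=1).astype(np.int32)
    ids = (
        np.asarray(stimulus_ids)
        if stimulus_ids is not None
        else np.arange(B, dtype=np.int64)
    )
    return ActivationMatrix(
        values=np.ascontiguousarray(out.T),
        unit_coords=coords,
        stimulus_ids=ids,
        layer_index=layer_index,
        attrs={
            "seed": seed,
            "noise_mu": noise.mu,
            "noise_sigma": noise.sigma,
            "noise_enabled": noise.enabled,
            "bn_mode": bn_mode,
            "weights_seed": net.seed,
        },
    )


def predict_proba(
    net: Network,
    images: np.ndarray,
    noise: NoiseParams | None = None,
    seed: int = 0,
    bn_mode: str = "running",
    chunk: int = 6,
) -> np.ndarray:
    """Category probabilities (B, n_classes) from the softmax output layer."""
    noise = noise if noise is not None else NoiseParams(enabled=False)
    x = _as_batch(images, net.config)
    rng = np.random.default_rng(seed) if noise.enabled else None
    final = net.final_feature_layer
    probs = []
    step = x.shape[0] if bn_mode == "batch" else chunk
    for lo in range(0, x.shape[0], step):
        feats = _forward_features(net, x[lo : lo + step], final, noise, rng, bn_mode)
        pooled = feats.mean(axis=(1, 2))  # global average pooling
        logits = pooled @ net.fc_W.T + net.fc_b
        probs.append(_softmax(logits))
    return np.concatenate(probs, axis=0)


def top_k_predictions(
    net: Network, image: np.ndarray, k: int = 5, **kwargs
) -> list[tuple[int, float]]:
    """The ``k`` most probable categories with confidences, descending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > net.config.n_classes:
        raise ValueError(f"k={k} exceeds the {net.config.n_classes} categories")
    p = predict_proba(net, image, **kwargs)[0]
    order = np.argsort(p)[::-1][:k]
    return [(int(i), float(p[i])) for i in order]


# ---------------------------------------------------------------------------
# Training (object recognition)
# ---------------------------------------------------------------------------


def _load_image_folder(root: str, size: int):
    """ImageNet-style layout: one sub-directory per category, images inside."""
    from PIL import Image

    classes = sorted(
        d for d in os.listdir(root) if os.path.isdir(os.path.join(root, d))
    )
    if not classes:
        raise FileNotFoundError(
            f"no class sub-directories under {root!r}; expected an "
            "ImageNet-style labeled image folder"
        )
    X, y = [], []
    for ci, cname in enumerate(classes):
        cdir = os.path.join(root, cname)
        for fname in sorted(os.listdir(cdir)):
            img = Image.open(os.path.join(cdir, fname)).convert("RGB")
            img = img.resize((size, size))
            X.append(np.asarray(img, dtype=np.float32) / 255.0)
            y.append(ci)
    return np.stack(X), np.asarray(y, dtype=np.int64), classes


def _forward_train(net: Network, x: np.ndarray):
    """Forward pass in training mode (batch-statistics batch norm, running-
    stat update, no noise), returning per-stage caches for backprop."""
    caches = []
    for st in net.stages:
        if isinstance(st, ConvStage):
            z = _conv_same(x, st, allow_fft=False)
            mean = z.mean(axis=(0, 1, 2))
            var = z.var(axis=(0, 1, 2))
            inv = 1.0 / np.sqrt(var + _BN_EPS)
            zh = (z - mean) * inv
            y = zh * st.gamma + st.beta
            r = np.maximum(y, 0)
            if st.layer_index in net.lrn_layers:
                denom = net.lrn.k + net.lrn.alpha * _lrn_window_sum(
                    np.square(r), net.lrn.n
                )
                b = r * np.power(denom, -net.lrn.beta)
            else:
                denom = None
                b = r
            st.running_mean = (1 - _BN_MOMENTUM) * st.running_mean + _BN_MOMENTUM * mean
            st.running_var = (1 - _BN_MOMENTUM) * st.running_var + _BN_MOMENTUM * var
            caches.append(("conv", st, x, zh, inv, y, r, denom))
            x = b
        else:
            out, idx = _maxpool2(x)
            caches.append(("pool", x.shape, idx))
            x = out
    pooled = x.mean(axis=(1, 2))
    logits = pooled @ net.fc_W.T + net.fc_b
    probs = _softmax(logits)
    caches.append(("head", x.shape, pooled))
    return probs, caches


def _backward_train(net: Network, probs, labels, caches, grads):
    B = probs.shape[0]
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    _, feat_shape, pooled = caches[-1]
    grads["fc_W"] += dlogits.T @ pooled
    grads["fc_b"] += dlogits.sum(axis=0)
    dpooled = dlogits @ net.fc_W
    _, H, W, C = feat_shape
    dx = np.broadcast_to(
        dpooled[:, None, None, :] / (H * W), feat_shape
    ).astype(dpooled.dtype)
    for cache in reversed(caches[:-1]):
        if cache[0] == "pool":
            _, in_shape, idx = cache
            dx = _maxpool2_backward(dx, idx, in_shape)
        else:
            _, st, x_in, zh, inv, y, r, denom = cache
            dr = _lrn_backward(dx, r, denom, net.lrn) if denom is not None else dx
            dy = dr * (y > 0)
            # batch-norm backward (per map, statistics over batch*space)
            n = dy.shape[0] * dy.shape[1] * dy.shape[2]
            grads[f"gamma{st.layer_index}"] += (dy * zh).sum(axis=(0, 1, 2))
            grads[f"beta{st.layer_index}"] += dy.sum(axis=(0, 1, 2))
            dzh = dy * st.gamma
            dz = (
                inv
                / n
                * (
                    n * dzh
                    - dzh.sum(axis=(0, 1, 2), keepdims=True)
                    - zh * (dzh * zh).sum(axis=(0, 1, 2), keepdims=True)
                )
            )
            grads[f"bias{st.layer_index}"] += dz.sum(axis=(0, 1, 2))
            # conv backward via the column matrices
            Bx, H, W, C = x_in.shape
            O, _, k, _ = st.W.shape
            col = _im2col(x_in, k)
            dz_flat = dz.reshape(Bx * H * W, O)
            dWmat = col.T @ dz_flat  # (k*k*C, O)
            grads[f"W{st.layer_index}"] += (
                dWmat.reshape(k, k, C, O).transpose(3, 2, 0, 1)
            )
            dcol = dz_flat @ st.w_matrix().T
            dx = _col2im(dcol, x_in.shape, k)
    return grads


def train_object_recognition(
    net: Network,
    dataset: str,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    checkpoint_dir: str | None = None,
) -> tuple[Network, dict]:
    """Optimize the network for object categorization by mini-batch gradient
    descent with momentum on the softmax cross-entropy.

    ``dataset`` is an ImageNet-style directory (one sub-directory per class).
    This is the long-running, non-desk pathway: all numerosity analyses in
    this package run on untrained (randomly initialized) networks.
    """
    cfg = cfg or TrainConfig()
    if not os.path.isdir(dataset):
        raise FileNotFoundError(
            f"training dataset directory {dataset!r} not found; note that all "
            "desk-scale numerosity analyses run with untrained networks and "
            "need no training data"
        )
    X, y, classes = _load_image_folder(dataset, net.config.input_size)
    if len(classes) > net.config.n_classes:
        raise ConfigurationError(
            f"dataset has {len(classes)} classes, network outputs "
            f"{net.config.n_classes}"
        )
    rng = np.random.default_rng(seed)
    vel: dict = {}
    log: dict = {"epoch_loss": [], "classes": classes}
    names = _param_names(net)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            xb, yb = X[sel], y[sel]
            probs, caches = _forward_train(net, xb)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            losses.append(float(loss))
            grads = {name: np.zeros_like(p) for name, p in names.items()}
            _backward_train(net, probs, yb, caches, grads)
            for name, p in names.items():
                v = vel.get(name)
                if v is None:
                    v = vel[name] = np.zeros_like(p)
                v *= cfg.momentum
                v -= cfg.learning_rate * grads[name]
                p += v
        log["epoch_loss"].append(float(np.mean(losses)))
        if checkpoint_dir:
            os.makedirs(checkpoint_dir, exist_ok=True)
            save_checkpoint(net, os.path.join(checkpoint_dir, f"epoch{epoch:03d}.h5"))
    net.bn_calibrated = True  # running stats now reflect the training data
    return net, log


def _param_names(net: Network) -> dict[str, np.ndarray]:
    names = {}
    for st in net.stages:
        if isinstance(st, ConvStage):
            names[f"W{st.layer_index}"] = st.W
            names[f"bias{st.layer_index}"] = st.bias
            names[f"gamma{st.layer_index}"] = st.gamma
            names[f"beta{st.layer_index}"] = st.beta
    names["fc_W"] = net.fc_W
    names["fc_b"] = net.fc_b
    return names


# ---------------------------------------------------------------------------
# Persistence (HDF5)
# ---------------------------------------------------------------------------


def _arch_hash(config: NetworkConfig) -> str:
    import hashlib

    text = repr(
        [
            (s.index, s.role, s.n_feature_maps, s.spatial_size, s.kernel_size)
            for s in config.layers
        ]
        + [config.n_classes]
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def save_checkpoint(net: Network, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["arch_hash"] = _arch_hash(net.config)
        fh.attrs["seed"] = net.seed
        fh.attrs["bn_calibrated"] = net.bn_calibrated
        for name, p in _param_names(net).items():
            fh.create_dataset(name, data=p)
        for st in net.conv_stages():
            fh.create_dataset(f"running_mean{st.layer_index}", data=st.running_mean)
            fh.create_dataset(f"running_var{st.layer_index}", data=st.running_var)


def load_checkpoint(net: Network, path: str) -> Network:
    import h5py

    with h5py.File(path, "r") as fh:
        if fh.attrs["arch_hash"] != _arch_hash(net.config):
            raise ConfigurationError("checkpoint architecture does not match config")
        for name, p in _param_names(net).items():
            p[...] = fh[name][...]
        for st in net.conv_stages():
            st.running_mean[...] = fh[f"running_mean{st.layer_index}"][...]
            st.running_var[...] = fh[f"running_var{st.layer_index}"][...]
        net.bn_calibrated = bool(fh.attrs.get("bn_calibrated", True))
    return net


def save_activations(acts: ActivationMatrix, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=acts.values)
        fh.create_dataset("unit_coords", data=acts.unit_coords)
        ids = np.asarray(acts.stimulus_ids)
        if ids.dtype.kind in "US":
            ids = ids.astype(h5py.string_dtype())
        fh.create_dataset("stimulus_ids", data=ids)
        fh.attrs["layer_index"] = acts.layer_index
        for k, v in acts.attrs.items():
            fh.attrs[k] = v


def load_activations(path: str) -> ActivationMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        attrs = dict(fh.attrs)
        layer = int(attrs.pop("layer_index"))
        ids = fh["stimulus_ids"][...]
        if ids.dtype.kind == "O":
            ids = ids.astype(str)
        return ActivationMatrix(
            values=fh["values"][...],
            unit_coords=fh["unit_coords"][...],
            stimulus_ids=ids,
            layer_index=layer,
            attrs=attrs,
        )
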