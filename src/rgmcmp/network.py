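"""Model factory for the segmentation architectures under comparison.

Four variants share one encoder-decoder skeleton:

* ``unet3d`` — standard 3D U-Net reference: single path, isotropic stride-2
  downsampling, no channel attention, no deep supervision.
* ``scsp``   — single-channel single-path variant: anisotropic downsampling
  schedule (the first and last downsampling steps leave the axial dimension
  unchanged), channel attention on the skip tensors and deep supervision.
* ``mcsp``   — the scsp architecture with the three guidance channels
  (aCT1, aCTV1, CT2) stacked at the input of a single encoder path.
* ``mcmp``   — multi-channel multi-path: each input channel gets its own
  independent encoder path (no cross-path feature mixing before the
  decoder); the decoder concatenates, at each depth, the skip tensors from
  every path.

Every convolutional module is a 3×3×3 convolution, instance normalization
and LReLU(α). Downsampling is a stride-2 convolution that doubles the
channel count; decoder upsampling is a transposed convolution mirroring
the downsampling strides. The segmentation heads are 1×1×1 convolutions;
the deep-supervision head logits are upsampled to full resolution by
trilinear interpolation, summed with the final head and passed through a
channel softmax, so the network output is a valid probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor

__all__ = ["ModelConfig", "AlignedInputs", "build_model", "Network", "plan_encoder_shapes"]

VARIANTS = ("unet3d", "scsp", "mcsp", "mcmp")


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    variant: str = "mcmp"
    in_channels: int = 3
    n_classes: int = 2
    base_filters: int = 16
    n_levels: int = 5
    axial_preserving_steps: tuple[int, ...] | None = None  # downsampling indices
    lrelu_alpha: float = 0.2
    use_channel_attention: bool = True
    ca_reduction: int = 8
    deep_supervision_heads: int = 3

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.variant == "mcmp" and self.in_channels < 2:
            raise ConfigurationError("mcmp requires a multi-channel input (in_channels ≥ 2)")
        if self.variant in ("scsp", "unet3d") and self.in_channels != 1:
            raise ConfigurationError(f"{self.variant} is single-channel (in_channels must be 1)")
        if self.variant == "mcsp" and self.in_channels < 2:
            raise ConfigurationError("mcsp requires a multi-channel input")
        if self.n_levels < 2:
            raise ConfigurationError("need at least 2 resolution levels")
        if self.variant == "unet3d":
            # the standard reference: isotropic, plain
            object.__setattr__(self, "axial_preserving_steps", ())
            self.use_channel_attention = False
            self.deep_supervision_heads = 0
        elif self.axial_preserving_steps is None:
            n_down = self.n_levels - 1
            self.axial_preserving_steps = tuple(sorted({0, n_down - 1}))

    @property
    def n_paths(self) -> int:
        return self.in_channels if self.variant == "mcmp" else 1

    @property
    def down_strides(self) -> list[tuple[int, int, int]]:
        strides = []
        for i in range(self.n_levels - 1):
            if i in (self.axial_preserving_steps or ()):
                strides.append((2, 2, 1))
            else:
                strides.append((2, 2, 2))
        return strides

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["axial_preserving_steps"] = list(self.axial_preserving_steps or ())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("axial_preserving_steps") is not None:
            d["axial_preserving_steps"] = tuple(d["axial_preserving_steps"])
        return cls(**d)


@dataclass
class AlignedInputs:
    """The three guidance channels on the training grid."""

    act1: np.ndarray
    actv1: np.ndarray
    ct2: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack(
            [np.asarray(self.act1), np.asarray(self.actv1), np.asarray(self.ct2)]
        ).astype(np.float32)


def plan_encoder_shapes(cfg: ModelConfig, input_shape: tuple[int, int, int]):
    """Spatial shapes at every encoder level, as forced by the stride plan."""
    shapes = [tuple(input_shape)]
    for s in cfg.down_strides:
        prev = shapes[-1]
        shapes.append(tuple(-(-p // st) for p, st in zip(prev, s)))
    return shapes


# -- parameters -------------------------------------------------------------

class ParamStore:
    """Creates and tracks parameters; he_normal init from a seeded RNG."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: list[Tensor] = []

    def he_normal(self, shape, fan_in: int) -> Tensor:
        std = np.sqrt(2.0 / fan_in)
        t = Tensor(self.rng.normal(0.0, std, size=shape), requires_grad=True)
        self.params.append(t)
        return t

    def constant(self, shape, value: float) -> Tensor:
        t = Tensor(np.full(shape, value, dtype=np.float32), requires_grad=True)
        self.params.append(t)
        return t


class ConvModule:
    """3×3×3 convolution (optionally strided) + instance norm + LReLU."""

    def __init__(self, store: ParamStore, c_in: int, c_out: int, alpha: float, stride=(1, 1, 1)):
        self.w = store.he_normal((c_out, c_in, 3, 3, 3), fan_in=c_in * 27)
        self.gamma = store.constant((c_out,), 1.0)
        self.beta = store.constant((c_out,), 0.0)
        self.alpha = alpha
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv3d(x, self.w, stride=self.stride)
        y = ad.instance_norm(y, self.gamma, self.beta)
        return ad.leaky_relu(y, self.alpha)


class UpModule:
    """Transposed convolution (kernel == stride) + instance norm + LReLU."""

    def __init__(self, store: ParamStore, c_in: int, c_out: int, alpha: float, stride):
        self.w = store.he_normal((c_in, c_out, *stride), fan_in=c_in)
        self.gamma = store.constant((c_out,), 1.0)
        self.beta = store.constant((c_out,), 0.0)
        self.alpha = alpha
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv_transpose3d(x, self.w, stride=self.stride)
        y = ad.instance_norm(y, self.gamma, self.beta)
        return ad.leaky_relu(y, self.alpha)


class ChannelAttention:
    """Squeeze-and-excitation gate: global average pool, bottleneck MLP,
    sigmoid gates in (0,1), channel-wise rescaling of the input."""

    def __init__(self, store: ParamStore, channels: int, reduction: int):
        if reduction > channels:
            raise ConfigurationError(
                f"channel-attention reduction {reduction} exceeds channel count {channels}"
            )
        hidden = max(1, channels // reduction)
        self.w1 = store.he_normal((hidden, channels, 1, 1, 1), fan_in=channels)
        self.b1 = store.constant((hidden,), 0.0)
        self.w2 = store.he_normal((channels, hidden, 1, 1, 1), fan_in=hidden)
        self.b2 = store.constant((channels,), 0.0)

    def gates(self, x: Tensor) -> Tensor:
        z = ad.channel_mean(x)
        z = ad.relu(ad.conv3d(z, self.w1, self.b1))
        return ad.sigmoid(ad.conv3d(z, self.w2, self.b2))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.mul(x, self.gates(x))


class Head:
    """1×1×1 convolution producing K logit channels."""

    def __init__(self, store: ParamStore, c_in: int, k: int):
        self.w = store.he_normal((k, c_in, 1, 1, 1), fan_in=c_in)
        self.b = store.constant((k,), 0.0)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.w, self.b)


class Network:
    """An encoder-decoder build; ``forward`` maps an input stack to a
    per-voxel class probability map."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        store = ParamStore(np.random.default_rng(self.seed))
        a = cfg.lrelu_alpha
        F = cfg.base_filters
        L = cfg.n_levels
        strides = cfg.down_strides
        widths = [F * 2**l for l in range(L)]
        per_path_in = 1 if cfg.variant == "mcmp" else cfg.in_channels

        # encoder paths -----------------------------------------------------
        self.paths = []
        self._encoder_param_start = len(store.params)
        for _ in range(cfg.n_paths):
            levels = []
            c_in = per_path_in
            for l in range(L):
                blocks = []
                if l > 0:
                    blocks.append(ConvModule(store, widths[l - 1], widths[l], a, stride=strides[l - 1]))
                    c_in = widths[l]
                blocks.append(ConvModule(store, c_in, widths[l], a))
                blocks.append(ConvModule(store, widths[l], widths[l], a))
                levels.append(blocks)
                c_in = widths[l]
            self.paths.append(levels)
        self._encoder_param_end = len(store.params)

        # decoder -----------------------------------------------------------
        npaths = cfg.n_paths
        self.ups = []
        self.dec_blocks = []
        self.attn = []
        c = widths[L - 1] * npaths  # concatenated bottleneck
        for l in range(L - 2, -1, -1):
            self.ups.append(UpModule(store, c, widths[l], a, strides[l]))
            skip_c = widths[l] * npaths
            self.attn.append(
                ChannelAttention(store, skip_c, min(cfg.ca_reduction, skip_c))
                if cfg.use_channel_attention
                else None
            )
            self.dec_blocks.append(
                [
                    ConvModule(store, widths[l] + skip_c, widths[l], a),
                    ConvModule(store, widths[l], widths[l], a),
                ]
            )
            c = widths[l]

        # heads: final (finest) plus deep-supervision heads at the coarsest
        # decoder stages
        n_dec = L - 1
        self.n_ds = min(cfg.deep_supervision_heads, max(0, n_dec - 1))
        self.final_head = Head(store, widths[0], cfg.n_classes)
        self.ds_heads = [
            Head(store, widths[L - 2 - i], cfg.n_classes) for i in range(self.n_ds)
        ]
        self.params = store.params
        self.last_encoder_shapes: list[tuple[int, ...]] | None = None

    # -- introspection ------------------------------------------------------
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def encoder_parameter_count(self) -> int:
        return int(
            sum(
                p.data.size
                for p in self.params[self._encoder_param_start : self._encoder_param_end]
            )
        )

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.params):
            raise ValueError("state does not match this architecture")
        for p, s in zip(self.params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"parameter shape mismatch: {p.data.shape} vs {s.shape}")
            p.data = s.astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    # -- forward ------------------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[0]}"
            )
        shapes = plan_encoder_shapes(self.cfg, x.shape[1:])
        for axis in range(3):
            if shapes[-1][axis] < 1:
                raise ValueError(f"input axis {axis} too small for {self.cfg.n_levels} levels")
        return x

    def forward(self, x: np.ndarray | AlignedInputs) -> Tensor:
        if isinstance(x, AlignedInputs):
            x = x.stacked()
        x = self._check_input(x)
        cfg = self.cfg
        full_shape = x.shape[1:]

        # encoder
        skips_per_level: list[list[Tensor]] = [[] for _ in range(cfg.n_levels)]
        enc_shapes = None
        for p_idx, levels in enumerate(self.paths):
            if cfg.variant == "mcmp":
                h = Tensor(x[p_idx : p_idx + 1])
            else:
                h = Tensor(x)
            shapes = []
            for l, blocks in enumerate(levels):
                for blk in blocks:
                    h = blk(h)
                shapes.append(h.data.shape[1:])
                skips_per_level[l].append(h)
            enc_shapes = shapes
        self.last_encoder_shapes = enc_shapes

        # decoder
        h = ad.concat_channels(skips_per_level[-1]) if cfg.n_paths > 1 else skips_per_level[-1][0]
        ds_logits: list[Tensor] = []
        n_dec = cfg.n_levels - 1
        for i, (up, attn, blocks) in enumerate(zip(self.ups, self.attn, self.dec_blocks)):
            l = cfg.n_levels - 2 - i
            h = up(h)
            skip = (
                ad.concat_channels(skips_per_level[l])
                if cfg.n_paths > 1
                else skips_per_level[l][0]
            )
            if attn is not None:
                skip = attn(skip)
            h = ad.concat_channels([h, skip])
            for blk in blocks:
                h = blk(h)
            # deep-supervision heads at the coarsest decoder stages
            if i < self.n_ds and i < n_dec - 1:
                ds_logits.append(self.ds_heads[i](h))

        logits = self.final_head(h)
        for dl in ds_logits:
            logits = ad.add(logits, ad.resize_linear(dl, full_shape))
        return ad.softmax_channels(logits)

    def predict_mask(self, x) -> np.ndarray:
        """Argmax segmentation (class 1 = target) as a binary array."""
        probs = self.forward(x)
        return (np.argmax(probs.data, axis=0) == 1).astype(np.uint8)


def build_model(cfg: ModelConfig, seed: int = 0) -> Network:
    """Construct a network; (cfg, seed) fully determines the initial weights."""
    return Network(cfg, seed)


def save_checkpoint(net: Network, path) -> None:
    """Single-file checkpoint: parameters plus the embedded ModelConfig."""
    import json

    arrays = {f"p{i}": p.data for i, p in enumerate(net.params)}
    np.savez_compressed(
        path,
        __config__=np.frombuffer(
            json.dumps({"model": net.cfg.to_dict(), "seed": net.seed}).encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_checkpoint(path) -> Network:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"].tobytes()).decode())
        net = Network(ModelConfig.from_dict(meta["model"]), seed=meta.get("seed", 0))
        net.load_state_dict([data[f"p{i}"] for i in range(len(net.params))])
    return net


def describe(net: Network, input_shape=(32, 32, 16)) -> str:
    """Architecture audit: variant, paths, parameter counts, shape plan."""
    cfg = net.cfg
    shapes = plan_encoder_shapes(cfg, input_shape)
    lines = [
        f"variant            : {cfg.variant}",
        f"input channels     : {cfg.in_channels}",
        f"encoder paths      : {cfg.n_paths}",
        f"resolution levels  : {cfg.n_levels} (base {cfg.base_filters} filters)",
        f"channel attention  : {cfg.use_channel_attention} (reduction {cfg.ca_reduction})",
        f"deep supervision   : {net.n_ds} auxiliary heads",
        f"parameters         : {net.parameter_count()} "
        f"(encoder {net.encoder_parameter_count()})",
        f"encoder shape plan : {' -> '.join(str(s) for s in shapes)} for input {input_shape}",
    ]
    return "\n".join(lines)


def channel_attention(features: np.ndarray, reduction: int, seed: int = 0) -> np.ndarray:
    """Standalone channel-attention application (functional form).

    Builds a seeded gate module for the given channel count and applies it;
    mainly useful for inspecting the gating behaviour in isolation.
    """
    f = np.asarray(features, dtype=np.float32)
    store = ParamStore(np.random.default_rng(seed))
    ca = ChannelAttention(store, f.shape[0], reduction)
    return ca(Tensor(f)).data
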