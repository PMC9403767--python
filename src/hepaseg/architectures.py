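"""Model families for liver lesion segmentation, built on the NumPy runtime.

Four styles are supported:

* ``standard`` / ``residual`` / ``dense`` — 3D U-Nets sharing one
  encoder–decoder frame.  ``layers`` counts the poolings (factor 2 per axis);
  the filter count doubles after each pooling up to ``filters_max`` and the
  number of convolution blocks per level grows by ``conv_block_increase``
  (the "convolution lambda") up to ``conv_blocks_max``.  Block internals
  differ: standard blocks convolve and activate; residual blocks add the
  block input to the convolution output before activation; dense blocks
  concatenate every previous same-level output before each convolution.
* ``hybrid_wnet`` — two coupled networks forming a W: a 2D U-Net whose
  encoder is the DenseNet-121 topology, decoded back to full resolution into
  32 feature maps per slice, concatenated (together with the image and liver
  channels) into a 3D densely connected network.  The 3D dense connections
  are *global*: every convolution at a spatial scale receives the
  concatenation of all previous same-scale outputs across the whole 3D
  network, not just within its own block.

All models output per-voxel class probabilities with the same spatial shape
as their input; variable input sizes are handled by reflect-padding to the
required pooling multiple and cropping the output back.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np

from . import nn
from .errors import ConfigError, ResourceError

Style = Literal["standard", "residual", "dense", "hybrid_wnet"]

DENSENET121_BLOCKS = (6, 12, 24, 16)

# batch-norm momentum used by the builder helpers; set from the config at the
# start of each build (builds are single-threaded)
_BN_M = 0.99


@dataclasses.dataclass
class ArchitectureConfig:
    style: Style = "standard"
    layers: int = 2
    conv_blocks_initial: int = 2
    conv_block_increase: int = 0          # extra blocks per deeper level
    conv_blocks_max: int = 4
    filters_initial: int = 8
    filters_max: int | None = 128
    growth_rate: int | None = None        # dense styles: extra channels per block
    input_channels: int = 2               # image + liver mask
    classes: int = 2
    conv_bias: bool = True                # 3D U-Net styles (the hybrid is bias-free)
    bn_momentum: float = 0.99             # lower it for short CPU trainings

    # hybrid_wnet only -----------------------------------------------------
    backbone_blocks: tuple[int, ...] = DENSENET121_BLOCKS
    backbone_growth: int = 32
    backbone_init_filters: int = 64
    backbone_in_channels: int = 3         # pretrained DenseNet-121 expects RGB
    decoder_channels: tuple[int, ...] | None = None   # default: halve down to 32
    feature_channels: int = 32            # 2D features handed to the 3D net
    filters_3d: int = 8                   # Fig-reading; the alternative reading is 32
    blocks_3d: tuple[int, ...] = (2, 3)   # conv blocks per 3D level

    def __post_init__(self):
        if self.layers < 1 or self.filters_initial < 1 or self.conv_blocks_initial < 1:
            raise ConfigError("layers, filters_initial and conv_blocks_initial must be >= 1")
        if self.style == "dense" and self.filters_max is None and self.growth_rate is None:
            raise ConfigError("dense style with unbounded filters requires a growth_rate")

    def filters_at(self, level: int) -> int:
        f = self.filters_initial * (2 ** level)
        return f if self.filters_max is None else min(f, self.filters_max)

    def blocks_at(self, level: int) -> int:
        return min(self.conv_blocks_initial + level * self.conv_block_increase,
                   self.conv_blocks_max)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("backbone_blocks", "decoder_channels", "blocks_3d"):
            if d[k] is not None:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        for k in ("backbone_blocks", "decoder_channels", "blocks_3d"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class ModelSpec:
    """A built model: declarative graph, parameter accounting and runtime network."""

    style: str
    config: ArchitectureConfig
    network: nn.Network
    accepts_variable_size: bool
    pad_multiple: tuple[int, int, int]    # (slice, row, column)
    output_name: str = "out"
    output_2d_name: str | None = None

    @property
    def graph(self) -> list[dict]:
        return self.network.describe()

    @property
    def parameter_counts(self) -> tuple[int, int, int]:
        return self.network.count_parameters()

    # ------------------------------------------------------------- running
    def pad_batch(self, arr: np.ndarray) -> tuple[np.ndarray, tuple]:
        """Reflect-pad (B, D, H, W, C) spatial dims up to the pooling multiple."""
        return self._pad(arr)

    def _pad(self, arr: np.ndarray) -> tuple[np.ndarray, tuple]:
        sp = arr.shape[1:4]
        target = [int(-(-n // m) * m) for n, m in zip(sp, self.pad_multiple)]
        pads = [(0, 0)] + [(0, t - n) for n, t in zip(sp, target)] + [(0, 0)]
        if all(p == (0, 0) for p in pads):
            return arr, sp
        return np.pad(arr, pads, mode="reflect"), sp

    def forward(self, image: np.ndarray, liver: np.ndarray, training: bool = False,
                head: str | None = None) -> np.ndarray:
        """Per-voxel class probabilities for (B, D, H, W[, 1]) inputs.

        ``head`` selects the output node ("out" for the final 3D prediction,
        the 2D head for the hybrid's slice-wise branch).
        """
        squeeze = image.ndim == 3
        if squeeze:
            image, liver = image[None], liver[None]
        if image.ndim == 4:
            image, liver = image[..., None], liver[..., None]
        image = image.astype(np.float32)
        liver = liver.astype(np.float32)
        img_p, orig_sp = self._pad(image)
        liv_p, _ = self._pad(liver)
        out_name = head or self.output_name
        out = self.network.forward({"image": img_p, "liver": liv_p}, [out_name],
                                   training=training)[out_name]
        if out.ndim == image.ndim:  # 3D output
            out = out[:, :orig_sp[0], :orig_sp[1], :orig_sp[2], :]
        else:                        # stacked 2D output (B*D, H, W, C)
            out = out.reshape(image.shape[0], -1, *out.shape[1:])
            out = out[:, :orig_sp[0], :orig_sp[1], :orig_sp[2], :]
        return out[0] if squeeze else out

    def backward_from(self, head: str, grad: np.ndarray) -> None:
        """Backpropagate an output gradient (already padded-shape aligned)."""
        self.network.backward({head: grad})

    # ----------------------------------------------------------- freezing
    def freeze(self, scopes) -> None:
        self.network.set_frozen(scopes)

    def unfreeze(self) -> None:
        self.network.set_frozen([])

    # -------------------------------------------------------------- state
    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path, **self.network.state_dict())
        total, tr, nt = self.parameter_counts
        sidecar = {"config": self.config.to_dict(), "style": self.style,
                   "parameters": {"total": total, "trainable": tr, "non_trainable": nt}}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    def load(self, path) -> None:
        with np.load(path) as data:
            self.network.load_state_dict(dict(data))


# =====================================================================
# 3D U-Net styles
# =====================================================================

def _conv_block_3d(net: nn.Network, name: str, x: str, cin: int, cout: int,
                   style: str, rng, scope: str, scale: int, bias: bool) -> tuple[str, int]:
    """One convolution block in the chosen style; returns (output node, channels)."""
    if style == "standard":
        c = net.add(f"{name}/conv", nn.Conv((3, 3, 3), cin, cout, bias=bias, rng=rng,
                                            name=name), x, scope, scale)
        b = net.add(f"{name}/bn", nn.BatchNorm(cout, name=name, momentum=_BN_M), c, scope, scale)
        return net.add(f"{name}/relu", nn.ReLU(), b, scope, scale), cout
    if style == "residual":
        c = net.add(f"{name}/conv", nn.Conv((3, 3, 3), cin, cout, bias=bias, rng=rng,
                                            name=name), x, scope, scale)
        b = net.add(f"{name}/bn", nn.BatchNorm(cout, name=name, momentum=_BN_M), c, scope, scale)
        skip = x
        if cin != cout:
            skip = net.add(f"{name}/proj", nn.Conv((1, 1, 1), cin, cout, bias=bias,
                                                   rng=rng, name=name), x, scope, scale)
        a = net.add(f"{name}/add", nn.Add(), [b, skip], scope, scale)
        return net.add(f"{name}/relu", nn.ReLU(), a, scope, scale), cout
    raise ConfigError(f"unknown block style {style!r}")


def _dense_level(net: nn.Network, name: str, feats: list[tuple[str, int]],
                 n_blocks: int, base_filters: int, growth: int,
                 fmax: int | None, rng, scope: str, scale: int, bias: bool
                 ) -> list[tuple[str, int]]:
    """Dense blocks: each conv consumes the concat of every feature in `feats`."""
    feats = list(feats)
    for k in range(n_blocks):
        cout = base_filters + k * (growth or 0)
        if fmax is not None:
            cout = min(cout, fmax)
        cin = sum(c for _, c in feats)
        src = [h for h, _ in feats]
        cat = (net.add(f"{name}/b{k}/cat", nn.Concat(), src, scope, scale)
               if len(src) > 1 else src[0])
        b = net.add(f"{name}/b{k}/bn", nn.BatchNorm(cin, name=f"{name}/b{k}", momentum=_BN_M), cat,
                    scope, scale)
        r = net.add(f"{name}/b{k}/relu", nn.ReLU(), b, scope, scale)
        c = net.add(f"{name}/b{k}/conv", nn.Conv((3, 3, 3), cin, cout, bias=bias,
                                                 rng=rng, name=f"{name}/b{k}"), r,
                    scope, scale)
        feats.append((c, cout))
    return feats


def _concat_feats(net: nn.Network, name: str, feats: list[tuple[str, int]],
                  scope: str, scale: int) -> tuple[str, int]:
    if len(feats) == 1:
        return feats[0]
    h = net.add(name, nn.Concat(), [f for f, _ in feats], scope, scale)
    return h, sum(c for _, c in feats)


def build_unet3d(config: ArchitectureConfig, rng_seed: int = 0) -> ModelSpec:
    """Standard / residual / dense 3D U-Net with ``config.layers`` poolings."""
    if config.style not in ("standard", "residual", "dense"):
        raise ConfigError(f"build_unet3d does not build style {config.style!r}")
    global _BN_M
    _BN_M = config.bn_momentum
    rng = np.random.default_rng(rng_seed)
    net = nn.Network()
    net.feed("image")
    net.feed("liver")
    x = net.add("input", nn.Concat(), ["image", "liver"], "unet", 1)
    ch = config.input_channels
    L = config.layers

    skips: list[tuple[str, int]] = []
    for lvl in range(L + 1):            # encoder levels 0..L-1, bottom at L
        scale = 2 ** lvl
        f, m = config.filters_at(lvl), config.blocks_at(lvl)
        if config.style == "dense":
            feats = _dense_level(net, f"enc{lvl}", [(x, ch)], m, f,
                                 config.growth_rate, config.filters_max, rng,
                                 "unet.encoder", scale, config.conv_bias)
            x, ch = _concat_feats(net, f"enc{lvl}/out", feats, "unet.encoder", scale)
        else:
            for k in range(m):
                x, ch = _conv_block_3d(net, f"enc{lvl}/b{k}", x, ch, f, config.style,
                                       rng, "unet.encoder", scale, config.conv_bias)
        if lvl < L:
            skips.append((x, ch))
            x = net.add(f"pool{lvl}", nn.Pool((2, 2, 2)), x, "unet.encoder", 2 ** (lvl + 1))

    for lvl in range(L - 1, -1, -1):
        scale = 2 ** lvl
        f, m = config.filters_at(lvl), config.blocks_at(lvl)
        up = net.add(f"up{lvl}", nn.Upsample((2, 2, 2)), x, "unet.decoder", scale)
        skip, sch = skips[lvl]
        if config.style == "dense":
            feats = _dense_level(net, f"dec{lvl}", [(up, ch), (skip, sch)], m, f,
                                 config.growth_rate, config.filters_max, rng,
                                 "unet.decoder", scale, config.conv_bias)
            x, ch = _concat_feats(net, f"dec{lvl}/out", feats, "unet.decoder", scale)
        else:
            x = net.add(f"dec{lvl}/cat", nn.Concat(), [up, skip], "unet.decoder", scale)
            ch = ch + sch
            for k in range(m):
                x, ch = _conv_block_3d(net, f"dec{lvl}/b{k}", x, ch, f, config.style,
                                       rng, "unet.decoder", scale, config.conv_bias)

    logits = net.add("head/conv", nn.Conv((1, 1, 1), ch, config.classes, bias=True,
                                          rng=rng, name="head"), x, "unet.head", 1)
    net.add("out", nn.Softmax(), logits, "unet.head", 1)
    m = 2 ** L
    return ModelSpec(config.style, config, net, True, (m, m, m))


# =====================================================================
# Hybrid-WNet
# =====================================================================

def _dense_backbone_2d(net: nn.Network, x: str, cin: int, cfg: ArchitectureConfig,
                       rng) -> list[tuple[str, int, int]]:
    """DenseNet-style 2D encoder; returns [(node, channels, scale), ...] tap points.

    With the default configuration this is exactly the DenseNet-121 topology
    (init 64, growth 32, blocks 6/12/24/16, bottleneck 4x, compression 1/2).
    """
    scope = "2d.encoder"
    g = cfg.backbone_growth
    taps = []
    c = net.add("enc2d/conv1", nn.Conv((7, 7), cin, cfg.backbone_init_filters,
                                       stride=2, rng=rng, name="enc2d/conv1"), x, scope, 2)
    b = net.add("enc2d/bn1", nn.BatchNorm(cfg.backbone_init_filters, name="enc2d/bn1", momentum=_BN_M),
                c, scope, 2)
    r = net.add("enc2d/relu1", nn.ReLU(), b, scope, 2)
    taps.append((r, cfg.backbone_init_filters, 2))
    x = net.add("enc2d/pool1", nn.Pool((3, 3), (2, 2)), r, scope, 4)
    ch = cfg.backbone_init_filters
    scale = 4
    for bi, n_layers in enumerate(cfg.backbone_blocks):
        feats = [(x, ch)]
        for li in range(n_layers):
            name = f"enc2d/block{bi + 1}/l{li + 1}"
            cat, cin_l = _concat_feats(net, f"{name}/cat", feats, scope, scale)
            b1 = net.add(f"{name}/bn1", nn.BatchNorm(cin_l, name=f"{name}/bn1", momentum=_BN_M), cat, scope, scale)
            r1 = net.add(f"{name}/relu1", nn.ReLU(), b1, scope, scale)
            c1 = net.add(f"{name}/conv1", nn.Conv((1, 1), cin_l, 4 * g, rng=rng,
                                                  name=f"{name}/conv1"), r1, scope, scale)
            b2 = net.add(f"{name}/bn2", nn.BatchNorm(4 * g, name=f"{name}/bn2", momentum=_BN_M), c1, scope, scale)
            r2 = net.add(f"{name}/relu2", nn.ReLU(), b2, scope, scale)
            c2 = net.add(f"{name}/conv2", nn.Conv((3, 3), 4 * g, g, rng=rng,
                                                  name=f"{name}/conv2"), r2, scope, scale)
            feats.append((c2, g))
        x, ch = _concat_feats(net, f"enc2d/block{bi + 1}/out", feats, scope, scale)
        if bi < len(cfg.backbone_blocks) - 1:
            taps.append((x, ch, scale))
            name = f"enc2d/trans{bi + 1}"
            b = net.add(f"{name}/bn", nn.BatchNorm(ch, name=f"{name}/bn", momentum=_BN_M), x, scope, scale)
            r = net.add(f"{name}/relu", nn.ReLU(), b, scope, scale)
            c = net.add(f"{name}/conv", nn.Conv((1, 1), ch, ch // 2, rng=rng,
                                                name=f"{name}/conv"), r, scope, scale)
            scale *= 2
            x = net.add(f"{name}/pool", nn.Pool((2, 2), mode="avg"), c, scope, scale)
            ch //= 2
    b = net.add("enc2d/bn_final", nn.BatchNorm(ch, name="enc2d/bn_final", momentum=_BN_M), x, scope, scale)
    r = net.add("enc2d/relu_final", nn.ReLU(), b, scope, scale)
    taps.append((r, ch, scale))
    return taps


def default_decoder_channels(n_stages: int, feature_channels: int = 32,
                             start: int = 256) -> tuple[int, ...]:
    """Halving channel schedule ending at the 2D feature width."""
    out = []
    c = start
    for _ in range(n_stages):
        out.append(max(c, feature_channels))
        c //= 2
    out[-1] = feature_channels
    return tuple(out)


def build_hybrid_wnet(config: ArchitectureConfig, rng_seed: int = 0,
                      pretrained: str | Path | None = None) -> ModelSpec:
    """The W-shaped hybrid: 2D dense U-Net feeding per-slice features to a 3D dense net.

    ``pretrained`` may name an .npz weight archive for the 2D encoder; when the
    file is missing a :class:`ResourceError` is raised.  ``pretrained=None``
    requests random initialization explicitly (pretrained ImageNet weights are
    not bundled).
    """
    if config.style != "hybrid_wnet":
        raise ConfigError(f"build_hybrid_wnet does not build style {config.style!r}")
    global _BN_M
    _BN_M = config.bn_momentum
    rng = np.random.default_rng(rng_seed)
    net = nn.Network()
    net.feed("image")
    net.feed("liver")

    # ---------------------------------------------------------------- 2D branch
    stack = nn.StackSlices()
    x2 = net.add("stack", stack, "image", "2d.encoder", 1)
    cin2 = 1
    if config.backbone_in_channels != 1:
        x2 = net.add("rgb", nn.RepeatChannels(config.backbone_in_channels), x2,
                     "2d.encoder", 1)
        cin2 = config.backbone_in_channels
    taps = _dense_backbone_2d(net, x2, cin2, config, rng)

    n_stages = len(taps)  # one upsampling per downsampling
    dec_ch = (config.decoder_channels if config.decoder_channels is not None
              else default_decoder_channels(n_stages, config.feature_channels))
    if len(dec_ch) != n_stages:
        raise ConfigError(f"decoder_channels needs {n_stages} entries, got {len(dec_ch)}")
    if dec_ch[-1] != config.feature_channels:
        raise ConfigError("last decoder stage must emit the 2D feature channels")

    x, ch, _ = taps[-1]
    scope = "2d.decoder"
    for si in range(n_stages):
        scale = taps[-1][2] // (2 ** (si + 1))
        up = net.add(f"dec2d/s{si}/up", nn.Upsample((2, 2)), x, scope, scale)
        skip = taps[n_stages - 2 - si] if si < n_stages - 1 else None
        if skip is not None:
            x = net.add(f"dec2d/s{si}/cat", nn.Concat(), [up, skip[0]], scope, scale)
            ch = ch + skip[1]
        else:
            x = up
        cout = dec_ch[si]
        for k in range(2):
            c = net.add(f"dec2d/s{si}/c{k}", nn.Conv((3, 3), ch, cout, rng=rng,
                                                     name=f"dec2d/s{si}/c{k}"), x, scope, scale)
            b = net.add(f"dec2d/s{si}/bn{k}", nn.BatchNorm(cout, name=f"dec2d/s{si}/bn{k}", momentum=_BN_M),
                        c, scope, scale)
            x = net.add(f"dec2d/s{si}/r{k}", nn.ReLU(), b, scope, scale)
            ch = cout
    feat2d = x   # (B*N, H, W, feature_channels)

    logits2d = net.add("head2d/conv", nn.Conv((1, 1), ch, config.classes, bias=True,
                                              rng=rng, name="head2d"), feat2d, "2d.head", 1)
    net.add("out2d", nn.Softmax(), logits2d, "2d.head", 1)

    # ---------------------------------------------------------------- 3D branch
    scope = "3d"
    feat3d = net.add("feat3d", nn.UnstackSlices(stack), feat2d, scope, 1)
    x = net.add("in3d", nn.Concat(), ["image", "liver", feat3d], scope, 1)
    ch = 2 + config.feature_channels
    feats_at_scale: dict[int, list[tuple[str, int]]] = {0: [(x, ch)]}
    Ld = len(config.blocks_3d)

    def run_level(level: int, tag: str):
        f = config.filters_3d * (2 ** level)
        pool = feats_at_scale[level]
        for k in range(config.blocks_3d[level] if tag != "dec" else config.blocks_3d[level]):
            name = f"{tag}3d/l{level}/b{k}"
            cat, cin_l = _concat_feats(net, f"{name}/cat", pool, scope, 2 ** level)
            b = net.add(f"{name}/bn", nn.BatchNorm(cin_l, name=f"{name}/bn", momentum=_BN_M), cat,
                        scope, 2 ** level)
            r = net.add(f"{name}/relu", nn.ReLU(), b, scope, 2 ** level)
            c = net.add(f"{name}/conv", nn.Conv((3, 3, 3), cin_l, f, rng=rng,
                                                name=f"{name}/conv"), r, scope, 2 ** level)
            pool.append((c, f))
        feats_at_scale[level] = pool

    for level in range(Ld):
        run_level(level, "enc")
        if level < Ld - 1:
            cat, cch = _concat_feats(net, f"enc3d/l{level}/down_cat",
                                     feats_at_scale[level], scope, 2 ** level)
            p = net.add(f"enc3d/pool{level}", nn.Pool((2, 2, 2)), cat, scope, 2 ** (level + 1))
            feats_at_scale[level + 1] = [(p, cch)]
    for level in range(Ld - 2, -1, -1):
        cat, cch = _concat_feats(net, f"dec3d/l{level + 1}/up_cat",
                                 feats_at_scale[level + 1], scope, 2 ** (level + 1))
        up = net.add(f"dec3d/up{level}", nn.Upsample((2, 2, 2)), cat, scope, 2 ** level)
        feats_at_scale[level].append((up, cch))
        run_level(level, "dec")

    cat, cch = _concat_feats(net, "head3d/cat", feats_at_scale[0], scope, 1)
    logits = net.add("head3d/conv", nn.Conv((1, 1, 1), cch, config.classes, bias=True,
                                            rng=rng, name="head3d"), cat, "3d", 1)
    net.add("out", nn.Softmax(), logits, "3d", 1)

    if pretrained is not None:
        path = Path(pretrained)
        if not path.exists():
            raise ResourceError(
                f"pretrained weight file {path} not found; pass pretrained=None for an "
                f"explicit random initialization")
        spec = ModelSpec("hybrid_wnet", config, net, True,
                         _hybrid_pad_multiple(config), "out", "out2d")
        _load_partial(net, path)
        return spec

    return ModelSpec("hybrid_wnet", config, net, True, _hybrid_pad_multiple(config),
                     "out", "out2d")


def _hybrid_pad_multiple(config: ArchitectureConfig) -> tuple[int, int, int]:
    m2d = 2 ** (1 + len(config.backbone_blocks))     # conv1 + pool + transitions
    m3d = 2 ** (len(config.blocks_3d) - 1)
    return (m3d, max(m2d, m3d), max(m2d, m3d))


def _load_partial(net: nn.Network, path: Path) -> None:
    with np.load(path) as data:
        state = net.state_dict()
        for k in data.files:
            if k in state:
                state[k] = data[k]
        net.load_state_dict(state)


def build_model(config: ArchitectureConfig, rng_seed: int = 0, **kw) -> ModelSpec:
    if config.style == "hybrid_wnet":
        return build_hybrid_wnet(config, rng_seed, **kw)
    return build_unet3d(config, rng_seed)


# =====================================================================
# Tensor layout helpers and parameter accounting
# =====================================================================

def reshape_3d_to_2d(batch: np.ndarray) -> np.ndarray:
    """(B, N, H, W, C) -> (B*N, H, W, C), patient-major then slice index."""
    if batch.ndim != 5:
        raise ValueError(f"expected a 5D B,N,H,W,C tensor, got {batch.ndim}D")
    return batch.reshape(-1, *batch.shape[2:])


def reshape_2d_to_3d(slices: np.ndarray, batch_size: int) -> np.ndarray:
    """Inverse of :func:`reshape_3d_to_2d` for a known batch size."""
    if slices.shape[0] % batch_size:
        raise ValueError("slice count is not a multiple of the batch size")
    return slices.reshape(batch_size, -1, *slices.shape[1:])


def count_parameters(model: ModelSpec) -> tuple[int, int, int]:
    """(total, trainable, non_trainable); counts every weight exactly once."""
    return model.parameter_counts
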