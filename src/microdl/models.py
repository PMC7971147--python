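"""Task networks: encoder-decoder U-Net and residual classifiers.

Both networks keep dropout units that can be left live at inference, which is
what Monte-Carlo-dropout uncertainty estimation requires. The ``stochastic``
flag of ``forward`` controls exactly that: dropout masks are sampled when it is
True (always during training) and bypassed otherwise.

Weights are stored as a flat ``name -> tensor`` archive (numpy ``.npz``); when
loading, a stored tensor is copied into the model only if both the layer name
and the full shape match, everything else is skipped and reported — the
transfer-learning contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, Conv2d, ConvTranspose2d, Dense, Dropout, GlobalAvgPool,
                 Layer, MaxPool2d, Parameter, ReLU, Sigmoid)

__all__ = [
    "UNet",
    "ResidualClassifier",
    "Softmax",
    "WeightManifest",
    "save_weights",
    "load_matching_weights",
    "build_unet",
    "build_classifier",
]


class Softmax(Layer):
    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, dy):
        y = self._y
        return y * (dy - (dy * y).sum(axis=1, keepdims=True))


class _Model:
    """Common parameter bookkeeping for the explicit-graph models."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._dropouts: list[Dropout] = []

    def parameters(self) -> list[Parameter]:
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        byname = {p.name: p for p in self.parameters()}
        for name, value in state.items():
            byname[name].value = np.array(value, dtype=np.float32)

    def reseed_dropout(self, rng: np.random.Generator) -> None:
        for d in self._dropouts:
            d.rng = rng

    @property
    def has_dropout(self) -> bool:
        """True if the model contains dropout units (even at rate 0)."""
        return len(self._dropouts) > 0

    def _dropout(self, rate: float) -> Dropout:
        d = Dropout(rate, self.rng)
        self._dropouts.append(d)
        return d


class _ConvBlock:
    """conv-relu-conv-relu (+ optional dropout at the end)."""

    def __init__(self, in_ch, out_ch, rng, name, dropout: Dropout | None = None):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng=rng, name=f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng, name=f"{name}.conv2")
        self.relu2 = ReLU()
        self.dropout = dropout

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x, stochastic):
        y = self.relu1(self.conv1(x))
        y = self.relu2(self.conv2(y))
        if self.dropout is not None:
            y = self.dropout.forward(y, training=stochastic)
        return y

    def backward(self, dy):
        if self.dropout is not None:
            dy = self.dropout.backward(dy)
        dy = self.conv2.backward(self.relu2.backward(dy))
        return self.conv1.backward(self.relu1.backward(dy))


class UNet(_Model):
    """Encoder-decoder with skip connections, same-size output.

    All convolutions are zero-padded so the output spatial shape equals the
    input spatial shape; inputs whose sides are not divisible by ``2**depth``
    are auto-padded and the output cropped back. Dropout sits at the end of
    every encoder block and of the bottleneck.

    Parameters
    ----------
    in_channels : input image channels.
    depth : number of 2x down-samplings. Default 2 — sized for CPU training
        on desk-scale images.
    base_filters : channel count of the first encoder block, doubled per level.
    dropout_rate : encoder dropout probability (0 disables the noise source).
    head : ``"sigmoid"`` for per-pixel probabilities, ``"linear"`` for
        unbounded regression output.
    """

    def __init__(self, in_channels: int = 1, depth: int = 2, base_filters: int = 16,
                 dropout_rate: float = 0.25, head: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        super().__init__(rng or np.random.default_rng())
        if head not in ("sigmoid", "linear"):
            raise ValueError(f"head must be 'sigmoid' or 'linear', got {head!r}")
        self.depth, self.head, self.dropout_rate = depth, head, dropout_rate
        self.in_channels = in_channels
        rng = self.rng

        self.enc: list[_ConvBlock] = []
        self.pools: list[MaxPool2d] = []
        ch = in_channels
        filt = base_filters
        for d in range(depth):
            self.enc.append(_ConvBlock(ch, filt, rng, f"enc{d + 1}",
                                       self._dropout(dropout_rate)))
            self.pools.append(MaxPool2d())
            ch, filt = filt, filt * 2
        self.bottleneck = _ConvBlock(ch, filt, rng, "bottleneck",
                                     self._dropout(dropout_rate))
        self.ups: list[ConvTranspose2d] = []
        self.dec: list[_ConvBlock] = []
        for d in reversed(range(depth)):
            skip_ch = filt // 2
            self.ups.append(ConvTranspose2d(filt, skip_ch, rng, name=f"up{d + 1}"))
            self.dec.append(_ConvBlock(2 * skip_ch, skip_ch, rng, f"dec{d + 1}"))
            filt = skip_ch
        self.out_conv = Conv2d(base_filters, 1, 1, rng=rng, name="out")
        self.sigmoid = Sigmoid()

    def parameters(self):
        params = []
        for b in self.enc:
            params += b.parameters()
        params += self.bottleneck.parameters()
        for up, b in zip(self.ups, self.dec):
            params += up.parameters() + b.parameters()
        params += self.out_conv.parameters()
        return params

    def forward(self, x: np.ndarray, stochastic: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, c, h, w = x.shape
        m = 2 ** self.depth
        ph, pw = (-h) % m, (-w) % m
        self._pad = (h, w, ph, pw)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, stochastic)
            skips.append(x)
            x = pool(x)
        x = self.bottleneck.forward(x, stochastic)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x)
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, stochastic)
        x = self.out_conv(x)
        if self.head == "sigmoid":
            x = self.sigmoid(x)
        if ph or pw:
            x = x[:, :, :h, :w]
        return x

    def backward(self, dy: np.ndarray) -> None:
        h, w, ph, pw = self._pad
        if ph or pw:
            dy = np.pad(dy, ((0, 0), (0, 0), (0, ph), (0, pw)))
        if self.head == "sigmoid":
            dy = self.sigmoid.backward(dy)
        dy = self.out_conv.backward(dy)
        dskips = []
        for up, block, skip_ch in zip(reversed(self.ups), reversed(self.dec),
                                      reversed(self._skip_ch)):
            dy = block.backward(dy)
            dskip, dy = dy[:, :skip_ch], dy[:, skip_ch:]
            dskips.append(dskip)
            dy = up.backward(dy)
        dy = self.bottleneck.backward(dy)
        for pool, block, dskip in zip(reversed(self.pools), reversed(self.enc),
                                      reversed(dskips)):
            dy = pool.backward(dy) + dskip
            dy = block.backward(dy)
        # gradient w.r.t. the input is discarded


class _ResBlock:
    """Residual block; ``bottleneck=True`` gives the 1x1-3x3-1x1 layout."""

    def __init__(self, in_ch, width, stride, rng, name, bottleneck=False):
        self.bottleneck = bottleneck
        out_ch = width * 4 if bottleneck else width
        if bottleneck:
            self.convs = [
                Conv2d(in_ch, width, 1, rng=rng, name=f"{name}.conv1"),
                Conv2d(width, width, 3, stride=stride, rng=rng, name=f"{name}.conv2"),
                Conv2d(width, out_ch, 1, rng=rng, name=f"{name}.conv3"),
            ]
        else:
            self.convs = [
                Conv2d(in_ch, width, 3, stride=stride, rng=rng, name=f"{name}.conv1"),
                Conv2d(width, out_ch, 3, rng=rng, name=f"{name}.conv2"),
            ]
        self.relus = [ReLU() for _ in self.convs]
        self.out_ch = out_ch
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng,
                               name=f"{name}.proj")

    def parameters(self):
        params = []
        for c in self.convs:
            params += c.parameters()
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    @property
    def n_weight_layers(self):
        return len(self.convs)

    def forward(self, x, stochastic):
        y = x
        for i, conv in enumerate(self.convs):
            y = conv(y)
            if i < len(self.convs) - 1:
                y = self.relus[i](y)
        shortcut = self.proj(x) if self.proj is not None else x
        self._plain_shortcut = self.proj is None
        return self.relus[-1](y + shortcut)

    def backward(self, dy):
        dy = self.relus[-1].backward(dy)
        dshort = self.proj.backward(dy) if self.proj is not None else dy
        for i in reversed(range(len(self.convs))):
            if i < len(self.convs) - 1:
                dy = self.relus[i].backward(dy)
            dy = self.convs[i].backward(dy)
        return dy + dshort


class ResidualClassifier(_Model):
    """Residual image classifier with dropout, softmax output.

    ``layout="resnet50"`` builds the canonical 50-weight-layer bottleneck
    network (stem + 3/4/6/3 three-conv blocks + final dense = 50). The added
    dropout — the modification that enables Monte-Carlo uncertainty — sits
    after each residual stage (rate ``stage_dropout``) and before the final
    dense layer (rate ``dropout_rate``). ``layout="lite"`` is a reduced-depth
    basic-block variant sized for CPU training.
    """

    _LAYOUTS = {
        "resnet50": dict(blocks=[3, 4, 6, 3], widths=[64, 128, 256, 512],
                         bottleneck=True, stem_kernel=7, stem_ch=64),
        "lite": dict(blocks=[1, 1, 1], widths=[16, 32, 64],
                     bottleneck=False, stem_kernel=3, stem_ch=16),
    }

    def __init__(self, n_classes: int, in_channels: int = 1, layout: str = "resnet50",
                 dropout_rate: float = 0.5, stage_dropout: float = 0.2,
                 rng: np.random.Generator | None = None):
        super().__init__(rng or np.random.default_rng())
        if n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {n_classes}")
        if layout not in self._LAYOUTS:
            raise ValueError(f"layout must be one of {sorted(self._LAYOUTS)}")
        cfg = self._LAYOUTS[layout]
        self.n_classes, self.layout = n_classes, layout
        rng = self.rng

        self.stem = Conv2d(in_channels, cfg["stem_ch"], cfg["stem_kernel"],
                           stride=2, rng=rng, name="stem")
        self.stem_relu = ReLU()
        self.stem_pool = MaxPool2d()
        self.stages: list[list[_ResBlock]] = []
        self.stage_drops: list[Dropout] = []
        ch = cfg["stem_ch"]
        for s, (n_blocks, width) in enumerate(zip(cfg["blocks"], cfg["widths"])):
            stage = []
            for b in range(n_blocks):
                stride = 2 if (b == 0 and s > 0) else 1
                block = _ResBlock(ch, width, stride, rng,
                                  f"stage{s + 1}.block{b + 1}",
                                  bottleneck=cfg["bottleneck"])
                ch = block.out_ch
                stage.append(block)
            self.stages.append(stage)
            self.stage_drops.append(self._dropout(stage_dropout))
        self.gap = GlobalAvgPool()
        self.head_drop = self._dropout(dropout_rate)
        self.fc = Dense(ch, n_classes, rng=rng, name="fc")
        self.softmax = Softmax()

    @property
    def n_weight_layers(self) -> int:
        n = 1 + 1  # stem conv + final dense
        for stage in self.stages:
            n += sum(b.n_weight_layers for b in stage)
        return n

    def parameters(self):
        params = self.stem.parameters()
        for stage in self.stages:
            for b in stage:
                params += b.parameters()
        params += self.fc.parameters()
        return params

    def forward(self, x: np.ndarray, stochastic: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        x = self.stem_pool(self.stem_relu(self.stem(x)))
        for stage, drop in zip(self.stages, self.stage_drops):
            for block in stage:
                x = block.forward(x, stochastic)
            x = drop.forward(x, training=stochastic)
        x = self.gap(x)
        x = self.head_drop.forward(x, training=stochastic)
        return self.softmax(self.fc(x))

    def backward(self, dy: np.ndarray) -> None:
        dy = self.fc.backward(self.softmax.backward(dy))
        dy = self.head_drop.backward(dy)
        dy = self.gap.backward(dy)
        for stage, drop in zip(reversed(self.stages), reversed(self.stage_drops)):
            dy = drop.backward(dy)
            for block in reversed(stage):
                dy = block.backward(dy)
        self.stem.backward(self.stem_relu.backward(self.stem_pool.backward(dy)))


@dataclass
class WeightManifest:
    """Report of a transfer-learning weight load.

    ``loaded`` and ``skipped`` together cover every entry of the stored
    archive; a layer is loaded only when its name and full shape match the
    target model.
    """

    loaded: list[tuple[str, tuple]] = field(default_factory=list)
    skipped: list[tuple[str, tuple, object]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"loaded {len(self.loaded)} layer(s), skipped {len(self.skipped)}"]
        for name, shape in self.loaded:
            lines.append(f"  loaded  {name} {tuple(shape)}")
        for name, stored, model_shape in self.skipped:
            lines.append(f"  skipped {name} stored={tuple(stored)} model={model_shape}")
        return "\n".join(lines)


def save_weights(model: _Model, path) -> None:
    """Write all model parameters as a flat name->tensor archive."""
    np.savez(path, **model.state_dict())


def load_matching_weights(model: _Model, weights_path) -> WeightManifest:
    """Load stored layers whose name and shape fit the model; skip the rest.

    Matching is layer-wise, as a framework's load-by-name would do it: a
    layer (all tensors sharing the prefix before ``.weight``/``.bias``) is
    loaded only if every one of its stored tensors matches the model in name
    and full shape. Never raises on a mismatch — partial transfer is the
    expected use: a backbone trained on one dataset initialises a model
    whose head differs.
    """
    with np.load(weights_path) as archive:
        stored = {k: archive[k] for k in archive.files}
    byname = {p.name: p for p in model.parameters()}
    layers: dict[str, list[str]] = {}
    for name in sorted(stored):
        layers.setdefault(name.rsplit(".", 1)[0], []).append(name)
    manifest = WeightManifest()
    for layer in sorted(layers):
        entries = layers[layer]
        fits = all(name in byname and byname[name].shape == stored[name].shape
                   for name in entries)
        for name in entries:
            tensor = stored[name]
            if fits:
                byname[name].value = tensor.astype(np.float32).copy()
                manifest.loaded.append((name, tensor.shape))
            elif name not in byname:
                manifest.skipped.append((name, tensor.shape, "absent"))
            else:
                manifest.skipped.append((name, tensor.shape, byname[name].shape))
    return manifest


def build_unet(in_channels: int = 1, depth: int = 2, base_filters: int = 16,
               dropout_rate: float = 0.25, head: str = "sigmoid",
               rng: np.random.Generator | None = None) -> UNet:
    """Construct the segmentation/regression U-Net (sigmoid or linear head)."""
    return UNet(in_channels=in_channels, depth=depth, base_filters=base_filters,
                dropout_rate=dropout_rate, head=head, rng=rng)


def build_classifier(n_classes: int, in_channels: int = 1, layout: str = "resnet50",
                     dropout_rate: float = 0.5, stage_dropout: float = 0.2,
                     rng: np.random.Generator | None = None) -> ResidualClassifier:
    """Construct the residual classifier (softmax probabilities out)."""
    return ResidualClassifier(n_classes, in_channels=in_channels, layout=layout,
                              dropout_rate=dropout_rate, stage_dropout=stage_dropout,
                              rng=rng)
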