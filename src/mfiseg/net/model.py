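"""A compact 3D dense V-Net for multi-label segmentation.

The architecture follows the dense V-Net design functionally: dense
feature stacks at several resolution levels (each unit sees the
concatenation of everything before it in its block and contributes
``growth`` new channels), dilated convolutions in the coarser blocks,
V-Net style downsampling between levels with the full-resolution stack
forwarded by a skip connection, batch-wise spatial dropout on the fused
features, and a final convolution producing per-class logits at the input
resolution.  Channel widths are configuration so a tiny CPU-trainable
variant exists alongside larger ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Adam,
    AvgPool3D,
    BatchNorm3D,
    Conv3D,
    NearestUpsample3D,
    ReLU,
    SpatialDropout,
)

__all__ = ["DenseVNetConfig", "DenseVNet"]


@dataclass(frozen=True)
class DenseVNetConfig:
    """Architecture hyperparameters.

    ``block_layers[i]`` units of growth ``growth[i]`` form the dense block
    at level ``i`` (level 0 = input resolution); ``dilations[i]`` gives the
    per-unit dilation rates (cycled if shorter than the block).  Each level
    below 0 is reached by average-pooling with ``down_factor``.
    """

    input_channels: int = 2
    n_classes: int = 15
    growth: tuple[int, ...] = (6, 8, 8)
    block_layers: tuple[int, ...] = (2, 2, 2)
    dilations: tuple[tuple[int, ...], ...] = ((1,), (1, 2), (1, 2))
    down_factor: tuple[int, int, int] = (2, 2, 2)
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.growth) < 2:
            raise ValueError("need at least 2 resolution levels")
        if not (len(self.growth) == len(self.block_layers) == len(self.dilations)):
            raise ValueError("growth, block_layers and dilations must align")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def levels(self) -> int:
        return len(self.growth)

    def total_down_factor(self) -> tuple[int, int, int]:
        n = self.levels - 1
        return tuple(f**n for f in self.down_factor)


class _DenseBlock:
    """Dense feature stack: each unit is BN -> ReLU -> Conv(growth)."""

    def __init__(self, c_in: int, n_layers: int, growth: int,
                 dilations: tuple[int, ...], rng: np.random.Generator) -> None:
        self.units = []
        self.feat_channels = [c_in]
        for j in range(n_layers):
            d = dilations[j % len(dilations)]
            cin_j = sum(self.feat_channels)
            self.units.append(
                (BatchNorm3D(cin_j), ReLU(), Conv3D(cin_j, growth, 3, dilation=d, rng=rng))
            )
            self.feat_channels.append(growth)
        self.c_out = growth * n_layers

    @property
    def layers(self):
        return [l for unit in self.units for l in unit]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        feats = [x]
        outs = []
        for bn, relu, conv in self.units:
            inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=1)
            y = conv.forward(relu.forward(bn.forward(inp, training), training), training)
            feats.append(y)
            outs.append(y)
        self._n_feats = len(feats)
        return outs[0] if len(outs) == 1 else np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        growths = self.feat_channels[1:]
        splits = np.cumsum(growths)[:-1]
        d_outs = np.split(grad, splits, axis=1) if len(growths) > 1 else [grad]
        d_feats = [None] * self._n_feats
        for j in range(len(self.units) - 1, -1, -1):
            bn, relu, conv = self.units[j]
            dy = d_outs[j]
            if d_feats[j + 1] is not None:
                dy = dy + d_feats[j + 1]
            dinp = bn.backward(relu.backward(conv.backward(dy)))
            in_channels = self.feat_channels[: j + 1]
            if len(in_channels) == 1:
                pieces = [dinp]
            else:
                pieces = np.split(dinp, np.cumsum(in_channels)[:-1], axis=1)
            for i, piece in enumerate(pieces):
                d_feats[i] = piece if d_feats[i] is None else d_feats[i] + piece
        return d_feats[0]


class DenseVNet:
    """Maps (batch, channels, X, Y, Z) inputs to per-class logit grids."""

    def __init__(self, config: DenseVNetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.blocks: list[_DenseBlock] = []
        self.pools: list[AvgPool3D] = []
        self.ups: list[NearestUpsample3D] = []
        c_in = c.input_channels
        fused = 0
        for lvl in range(c.levels):
            block = _DenseBlock(c_in, c.block_layers[lvl], c.growth[lvl], c.dilations[lvl], rng)
            self.blocks.append(block)
            fused += block.c_out
            if lvl < c.levels - 1:
                self.pools.append(AvgPool3D(c.down_factor))
            if lvl > 0:
                f = tuple(v**lvl for v in c.down_factor)
                self.ups.append(NearestUpsample3D(f))
            c_in = block.c_out
        self.dropout = SpatialDropout(c.dropout_rate)
        self.head_bn = BatchNorm3D(fused)
        self.head_relu = ReLU()
        self.head_conv = Conv3D(fused, c.n_classes, kernel=1, rng=rng)

    # ------------------------------------------------------------- plumbing
    @property
    def layers(self):
        out = []
        for b in self.blocks:
            out.extend(b.layers)
        out.extend([self.head_bn, self.head_conv])
        return out

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def check_window(self, spatial_shape) -> None:
        total = self.config.total_down_factor()
        for s, f in zip(spatial_shape, total):
            if s % f:
                raise ValueError(
                    f"window {tuple(spatial_shape)} not divisible by total "
                    f"downsampling factor {total}"
                )

    # -------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError(f"expected (B, C, X, Y, Z) input, got shape {x.shape}")
        if x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} channels, got {x.shape[1]}"
            )
        self.check_window(x.shape[2:])
        feats = []
        h = x
        for lvl, block in enumerate(self.blocks):
            h = block.forward(h, training)
            feats.append(h)
            if lvl < len(self.pools):
                h = self.pools[lvl].forward(h, training)
        fused = [feats[0]] + [up.forward(f, training) for up, f in zip(self.ups, feats[1:])]
        z = np.concatenate(fused, axis=1)
        z = self.dropout.forward(z, training, rng=rng)
        z = self.head_relu.forward(self.head_bn.forward(z, training), training)
        return self.head_conv.forward(z, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head_bn.backward(self.head_relu.backward(self.head_conv.backward(dlogits)))
        dz = self.dropout.backward(dz)
        widths = [self.blocks[0].c_out] + [b.c_out for b in self.blocks[1:]]
        pieces = np.split(dz, np.cumsum(widths)[:-1], axis=1)
        d_feats = [pieces[0]] + [
            up.backward(p) for up, p in zip(self.ups, pieces[1:])
        ]
        # walk levels from the deepest back up, folding pooled-path gradients in
        grad = None
        for lvl in range(len(self.blocks) - 1, -1, -1):
            g = d_feats[lvl]
            if grad is not None:
                g = g + self.pools[lvl].backward(grad)
            grad = self.blocks[lvl].backward(g)

    # ------------------------------------------------------------ check/save
    def state_dict(self) -> dict:
        state = {f"p{i}": p for i, p in enumerate(self.params)}
        for i, l in enumerate(self.layers):
            if isinstance(l, BatchNorm3D):
                state[f"bn{i}_mean"] = l.running_mean
                state[f"bn{i}_var"] = l.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params):
            p[...] = state[f"p{i}"]
        for i, l in enumerate(self.layers):
            if isinstance(l, BatchNorm3D):
                l.running_mean[...] = state[f"bn{i}_mean"]
                l.running_var[...] = state[f"bn{i}_var"]

    def save(self, path, extra: dict | None = None) -> None:
        from dataclasses import asdict
        import json

        meta = {"format": "mfiseg-densevnet-v1", "config": asdict(self.config)}
        if extra:
            meta["extra"] = extra
        np.savez_compressed(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path) -> "DenseVNet":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            if meta.get("format") != "mfiseg-densevnet-v1":
                raise ValueError("not a recognised model checkpoint")
            cfg = meta["config"]
            for key in ("growth", "block_layers", "down_factor"):
                cfg[key] = tuple(cfg[key])
            cfg["dilations"] = tuple(tuple(d) for d in cfg["dilations"])
            model = cls(DenseVNetConfig(**cfg))
            model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model

    def make_optimizer(self, lr: float = 1e-3, l2_decay: float = 0.0) -> Adam:
        return Adam(self.params, self.grads, lr=lr, l2_decay=l2_decay)
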