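"""The residual-inception refinement network.

Architecture
------------
A 3x3x2 patch tensor (NDVI neighbourhood + pixel-location layer) feeds a
stack of two inception blocks.  Each block runs four parallel branches with
differing kernel sizes and dilation rates — some behind a 1x1 channel-halving
bottleneck — every branch ending in batch normalisation and an ELU before
channel concatenation.  Zero padding keeps the spatial field 3x3 throughout.
Global average pooling collapses the final feature tensor; a dense head
(32 units, ELU, dropout p=0.2, then a single ELU unit) produces a correction
that a residual connection adds to the raw central NDVI pixel, so the
convolutional trunk only has to learn the mixed-pixel refinement, not the
value itself.  A final single-weight ReLU unit removes any remaining offset
between the satellite and reference NDVI spaces and clamps the output to be
non-negative.

The reference configuration has 17,342 trainable parameters — a deliberately
light-weight model that trains in minutes on a CPU.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass

import numpy as np

from ._layers import (
    AvgPool2dSame,
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    ELU,
    GlobalAvgPool,
    Layer,
    ReLU,
)
from .raster_io import PatchTensor


@dataclass(frozen=True)
class BranchSpec:
    """One inception branch.

    kind
        ``"conv"`` — (optional 1x1 channel-halving bottleneck, then) an
        f x f convolution with the given dilation; or ``"pool"`` — a 3x3
        average pool followed by a 1x1 convolution.
    """

    kind: str = "conv"
    kernel_size: int = 3
    dilation: int = 1
    bottleneck: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "pool"):
            raise ValueError(f"unknown branch kind {self.kind!r}")
        if self.kernel_size % 2 == 0:
            raise ValueError("branch kernel sizes must be odd (spatial shape must stay 3x3)")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")


_DEFAULT_BLOCK1 = (
    BranchSpec("conv", 3, 1, bottleneck=True),
    BranchSpec("conv", 3, 1),
    BranchSpec("conv", 3, 2),   # atrous branch: non-local correlations
    BranchSpec("conv", 1, 1),
)
_DEFAULT_BLOCK2 = (
    BranchSpec("conv", 3, 1, bottleneck=True),
    BranchSpec("conv", 3, 2, bottleneck=True),
    BranchSpec("conv", 1, 1),
    BranchSpec("pool", 3, 1),
)


@dataclass(frozen=True)
class RarefyNetConfig:
    """Architecture hyperparameters.

    Defaults give the reference light-weight model: 8 feature maps per branch
    in block 1 (concat width 32), 32 per branch in block 2 (concat width
    128), a 32-unit dense layer and dropout p=0.2.  The 1x1 bottlenecks on
    the f>1 branches of block 2 keep the parameter count under 20k.
    """

    block1_branches: tuple[BranchSpec, ...] = _DEFAULT_BLOCK1
    block2_branches: tuple[BranchSpec, ...] = _DEFAULT_BLOCK2
    maps_block1: int = 8
    maps_block2: int = 32
    dense_width: int = 32
    dropout_p: float = 0.2
    normalize_locations: bool = True

    def __post_init__(self) -> None:
        for name, branches in (("block1", self.block1_branches),
                               ("block2", self.block2_branches)):
            if len(branches) != 4:
                raise ValueError(f"{name} must have exactly 4 branches")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if min(self.maps_block1, self.maps_block2, self.dense_width) < 1:
            raise ValueError("layer widths must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RarefyNetConfig":
        d = dict(d)
        for key in ("block1_branches", "block2_branches"):
            if key in d:
                d[key] = tuple(
                    b if isinstance(b, BranchSpec) else BranchSpec(**b) for b in d[key]
                )
        return cls(**d)


class _Branch:
    """A sequential chain of layers forming one inception branch."""

    def __init__(self, spec: BranchSpec, in_channels: int, n_maps: int,
                 rng: np.random.Generator):
        layers: list[Layer] = []
        if spec.kind == "pool":
            layers.append(AvgPool2dSame(spec.kernel_size))
            layers.append(Conv2d(in_channels, n_maps, 1, 1, rng))
        else:
            channels = in_channels
            if spec.bottleneck:
                half = max(in_channels // 2, 1)
                layers.append(Conv2d(channels, half, 1, 1, rng))
                channels = half
            layers.append(Conv2d(channels, n_maps, spec.kernel_size, spec.dilation, rng))
        layers.append(BatchNorm2d(n_maps))
        layers.append(ELU())
        self.layers = layers

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class _InceptionBlock:
    def __init__(self, in_channels: int, branches: tuple[BranchSpec, ...],
                 n_maps: int, rng: np.random.Generator):
        self.branches = [_Branch(spec, in_channels, n_maps, rng) for spec in branches]
        self.n_maps = n_maps
        self.out_channels = n_maps * len(self.branches)

    def forward(self, x, training, rng):
        outs = [b.forward(x, training, rng) for b in self.branches]
        out = np.concatenate(outs, axis=1)
        if out.shape[2:] != x.shape[2:]:
            raise ValueError("a branch changed the spatial shape; check kernel/dilation")
        return out

    def backward(self, dy):
        dx = None
        for i, branch in enumerate(self.branches):
            chunk = dy[:, i * self.n_maps:(i + 1) * self.n_maps]
            d = branch.backward(chunk)
            dx = d if dx is None else dx + d
        return dx


class RarefyNet:
    """Residual-inception NDVI refinement network (pure NumPy).

    ``forward`` accepts a single :class:`~rarefynet.raster_io.PatchTensor`,
    a (2, 3, 3) array, or a batch (N, 2, 3, 3); it returns a scalar or an
    (N,) array of refined NDVI values (non-negative by the output ReLU).
    """

    def __init__(self, config: RarefyNetConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.config = config or RarefyNetConfig()
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.block1 = _InceptionBlock(2, cfg.block1_branches, cfg.maps_block1, rng)
        self.block2 = _InceptionBlock(self.block1.out_channels, cfg.block2_branches,
                                      cfg.maps_block2, rng)
        self.gap = GlobalAvgPool()
        self.dense1 = Dense(self.block2.out_channels, cfg.dense_width, rng)
        self.act1 = ELU()
        self.dropout = Dropout(cfg.dropout_p)
        self.dense2 = Dense(cfg.dense_width, 1, rng)
        self.act2 = ELU()
        self.dense3 = Dense(1, 1, rng)
        # identity init for the final offset unit: a random negative weight
        # would silence the output ReLU and kill every gradient at step 0
        self.dense3.params["weight"][...] = 1.0
        self.dense3.params["bias"][...] = 0.0
        self.act3 = ReLU()
        for _, layer in self.named_layers():
            layer.params = {k: v.astype(self.dtype) for k, v in layer.params.items()}
            layer.state = {k: v.astype(self.dtype) for k, v in layer.state.items()}

    # ------------------------------------------------------------------ plumbing
    def named_layers(self):
        for bi, block in enumerate((self.block1, self.block2), start=1):
            for ri, branch in enumerate(block.branches):
                for li, layer in enumerate(branch.layers):
                    yield f"block{bi}.branch{ri}.layer{li}", layer
        yield "dense1", self.dense1
        yield "dense2", self.dense2
        yield "dense3", self.dense3

    def parameters(self) -> dict[str, np.ndarray]:
        """Trainable parameters, keyed by layer path (live references)."""
        return {f"{name}.{key}": arr
                for name, layer in self.named_layers()
                for key, arr in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{name}.{key}": arr
                for name, layer in self.named_layers()
                for key, arr in layer.grads.items()}

    def flatten_parameters(self) -> np.ndarray:
        """Repack all trainable parameters as views into one flat buffer.

        Returns the buffer; in-place updates to it propagate to the layers.
        Used by the training loop so the optimizer runs a single vectorised
        update instead of one per parameter array.
        """
        params = self.parameters()
        flat = np.empty(sum(p.size for p in params.values()), dtype=self.dtype)
        offset = 0
        for _, layer in self.named_layers():
            for key, p in layer.params.items():
                view = flat[offset:offset + p.size].reshape(p.shape)
                view[...] = p
                layer.params[key] = view
                offset += p.size
        return flat

    def flat_gradients(self) -> np.ndarray:
        """Gradients concatenated in ``flatten_parameters`` order."""
        return np.concatenate([
            layer.grads[key].ravel()
            for _, layer in self.named_layers()
            for key in layer.params
        ])

    def stats(self) -> dict[str, np.ndarray]:
        return {f"{name}.{key}": arr
                for name, layer in self.named_layers()
                for key, arr in layer.state.items()}

    # ------------------------------------------------------------------ compute
    def _as_batch(self, x) -> tuple[np.ndarray, bool]:
        if isinstance(x, PatchTensor):
            x = x.array
        x = np.asarray(x, dtype=self.dtype)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != (2, 3, 3):
            raise ValueError(f"expected input of shape (N, 2, 3, 3), got {x.shape}")
        return x, single

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None):
        x, single = self._as_batch(x)
        self._xc = x[:, 0, 1, 1]  # raw central NDVI, the residual input
        h = self.block1.forward(x, training, rng)
        h = self.block2.forward(h, training, rng)
        g = self.gap.forward(h, training, rng)
        a = self.act1.forward(self.dense1.forward(g, training, rng), training, rng)
        d = self.dropout.forward(a, training, rng)
        z = self.act2.forward(self.dense2.forward(d, training, rng), training, rng)
        r = z + self._xc[:, None]
        out = self.act3.forward(self.dense3.forward(r, training, rng), training, rng)
        out = out[:, 0]
        return float(out[0]) if single else out

    def backward(self, dout: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output); gradients are left on the layers."""
        d = self.act3.backward(np.asarray(dout, dtype=self.dtype)[:, None])
        d = self.dense3.backward(d)
        # the residual sum routes the gradient unchanged into the dense head;
        # the branch into the raw input pixel is not needed
        d = self.dense2.backward(self.act2.backward(d))
        d = self.dropout.backward(d)
        d = self.dense1.backward(self.act1.backward(d))
        d = self.gap.backward(d)
        d = self.block2.backward(d)
        self.block1.backward(d)

    def predict(self, x: np.ndarray, chunk_size: int = 4096) -> np.ndarray:
        """Inference-mode forward in chunks (running BN stats, no dropout)."""
        x = np.asarray(x, dtype=np.float64)
        out = np.empty(len(x))
        for start in range(0, len(x), chunk_size):
            out[start:start + chunk_size] = self.forward(x[start:start + chunk_size])
        return out

    def copy(self) -> "RarefyNet":
        return copy.deepcopy(self)


def build_model(config: RarefyNetConfig | None = None, seed: int = 0,
                dtype=np.float32) -> RarefyNet:
    """Build a network with deterministic weight initialisation for ``seed``."""
    return RarefyNet(config, seed, dtype)


def forward(model: RarefyNet, x):
    """Evaluate the network on one patch tensor or a batch (inference mode)."""
    return model.forward(x)


def count_parameters(model: RarefyNet) -> int:
    """Total trainable scalars: conv/dense weights+biases and BN gamma/beta.

    Batch-norm running statistics are state, not parameters, and are excluded.
    """
    return int(sum(layer.n_params for _, layer in model.named_layers()))


def save_checkpoint(model: RarefyNet, path) -> None:
    """Serialise parameters, BN statistics and the config to an .npz file."""
    payload = {f"param/{k}": v for k, v in model.parameters().items()}
    payload.update({f"stat/{k}": v for k, v in model.stats().items()})
    config_json = json.dumps({"config": model.config.to_dict(), "seed": model.seed})
    payload["meta"] = np.frombuffer(config_json.encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path) -> RarefyNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        model = RarefyNet(RarefyNetConfig.from_dict(meta["config"]), seed=meta["seed"])
        params = model.parameters()
        stats = model.stats()
        for key in data.files:
            if key.startswith("param/"):
                params[key[6:]][...] = data[key]
            elif key.startswith("stat/"):
                stats[key[5:]][...] = data[key]
    return model
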