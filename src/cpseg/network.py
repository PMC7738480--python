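"""Per-plane U-Net encoder-decoder networks.

The architecture follows the pre-activation variant used for fetal
cortical-plate segmentation: each block is three repetitions of
(batch norm -> ELU -> 3x3 zero-padded convolution), downsampling is 2x2 max
pooling with stride 2, upsampling is a stride-2 transposed convolution whose
output is concatenated with the *last* feature map of the same-resolution
encoder block, and a final 1x1 convolution followed by softmax produces the
per-pixel label probabilities. Feature widths double at every level: with a
base width of 32 and four pooling levels the bottleneck carries 512 feature
maps; the 3D comparison variant starts at 8 and peaks at 128.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import conv_nd, max_pool_nd, softmax_op
from .nn.layers import BatchNorm, Conv, ConvTranspose, Module, elu


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one plane network.

    base_features: width of the first block (32 for the full model, 8 for
        the tiny CPU preset and the 3D variant).
    depth: number of pooling levels; widths double per level.
    in_shape: spatial input shape, e.g. (128, 128); must be divisible by
        2**depth in every axis.
    out_labels: 5 for axial/coronal, 3 for sagittal.
    convs_per_block: BN-ELU-conv repetitions per block.
    dims: 2 for slice networks, 3 for the volumetric comparison baseline.
    """

    base_features: int = 32
    depth: int = 4
    in_shape: tuple = (128, 128)
    out_labels: int = 5
    convs_per_block: int = 3
    dims: int = 2

    def __post_init__(self):
        if self.out_labels not in (3, 5):
            raise ValueError("out_labels must be 3 or 5")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if len(self.in_shape) != self.dims:
            raise ValueError("in_shape rank must equal dims")
        if any(s % (2**self.depth) for s in self.in_shape):
            raise ValueError(
                f"input shape {self.in_shape} not divisible by 2^depth = {2 ** self.depth}"
            )

    @property
    def bottleneck_features(self) -> int:
        return self.base_features * 2**self.depth

    def to_dict(self) -> dict:
        d = asdict(self)
        d["in_shape"] = list(self.in_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["in_shape"] = tuple(d["in_shape"])
        return cls(**d)


TINY_2D = NetworkConfig(base_features=8, depth=3, in_shape=(64, 64), out_labels=5)


class _Block(Module):
    """convs_per_block x (BN -> ELU -> conv); returns its last feature map."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, dims: int, rng):
        super().__init__()
        self.norms = [BatchNorm(in_ch if i == 0 else out_ch) for i in range(n_convs)]
        self.convs = [
            Conv(in_ch if i == 0 else out_ch, out_ch, 3, dims, rng) for i in range(n_convs)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for bn, cv in zip(self.norms, self.convs):
            x = cv(elu(bn(x)))
        return x


class UNet(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d, nc, dims = config.depth, config.convs_per_block, config.dims
        widths = [config.base_features * 2**i for i in range(d + 1)]
        self.enc = [
            _Block(1 if i == 0 else widths[i - 1], widths[i], nc, dims, rng) for i in range(d)
        ]
        self.bottleneck = _Block(widths[d - 1], widths[d], nc, dims, rng)
        self.upconvs = [ConvTranspose(widths[i + 1], widths[i], 3, dims, rng) for i in range(d)]
        self.dec = [_Block(2 * widths[i], widths[i], nc, dims, rng) for i in range(d)]
        self.head = Conv(widths[0], config.out_labels, 1, dims, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)  # the block's last feature map feeds the skip
            x = max_pool_nd(x, 2)
        x = self.bottleneck(x)
        for i in reversed(range(self.config.depth)):
            x = self.upconvs[i](x)
            if x.shape[2:] != skips[i].shape[2:]:
                raise AssertionError(
                    f"decoder/skip shape mismatch at level {i}: {x.shape} vs {skips[i].shape}"
                )
            x = nn.concat_channels([x, skips[i]])
            x = self.dec[i](x)
        logits = self.head(x)
        return softmax_op(logits, axis=1)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_unet(config: NetworkConfig, seed: int = 0) -> UNet:
    """Construct a seeded, He-uniform-initialized U-Net for `config`."""
    return UNet(config, seed=seed)


def predict_stack(model: UNet, slices: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Run the network over a stack of slices in inference mode.

    slices: (n, H, W) float array matching the model's input shape.
    Returns (n, out_labels, H, W) softmax maps. Deterministic: batch norm
    uses its running statistics and no tape is built.
    """
    slices = np.asarray(slices, dtype=np.float32)
    if slices.shape[1:] != tuple(model.config.in_shape):
        raise ValueError(
            f"slice shape {slices.shape[1:]} does not match model input {model.config.in_shape}"
        )
    model.eval()
    outs = []
    with nn.no_grad():
        for start in range(0, len(slices), batch_size):
            batch = slices[start : start + batch_size][:, None]
            outs.append(model(Tensor(batch)).data)
    return np.concatenate(outs, axis=0) if outs else np.zeros((0,), dtype=np.float32)


def save_checkpoint(model: UNet, path: str | Path, extra: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = [z[f"a{i}"] for i in range(sum(1 for k in z.files if k.startswith("a")))]
    model = UNet(NetworkConfig.from_dict(meta["config"]))
    model.load_state_arrays(arrays)
    model.eval()
    return model, meta["extra"]
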