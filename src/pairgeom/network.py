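"""The trainable geometry head and the end-to-end model wrapper.

Architecture (channels-last, all 'same' padding):

* reduction: three 1x1 convolutions with 256, 128, 64 kernels, each followed
  by instance normalization and ReLU, taking the 400-channel pair features
  down to 64;
* trunk: 28 pre-activation residual blocks (IN -> ReLU -> Conv3x3 -> ReLU ->
  Conv3x3 -> skip), 64 channels, dilation cycling 1, 2, 4 across blocks and
  shared by both convolutions of a block;
* heads: four independent 1x1 convolutions predicting binned inter-residue
  geometries — theta (25), phi (13), omega (25), distance (37 classes).

``GeometryModel`` composes the pair-feature builder (which owns the trainable
query MLP) with this head so training updates both while the embedder stays
frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .embedder import EmbedderOutput
from .errors import SchemaError, ShapeError
from .features import TOTAL_CHANNELS, PairFeatureBuilder
from .nn import Conv2d, InstanceNorm, Layer, Param, ReLU, ResidualBlock, Sequential, softmax

CHECKPOINT_FORMAT_VERSION = "1.0"

#: Class counts per objective, fixed by the binning scheme.
HEAD_BINS = {"theta": 25, "phi": 13, "omega": 25, "dist": 37}
OBJECTIVES = ("theta", "phi", "omega", "dist")
#: Objectives that are symmetric functions of the residue pair.
SYMMETRIC_OBJECTIVES = ("omega", "dist")


@dataclass
class NetConfig:
    reduction_channels: tuple[int, ...] = (256, 128, 64)
    trunk_blocks: int = 28
    trunk_channels: int = 64
    dilation_cycle: tuple[int, ...] = (1, 2, 4)
    head_bins: dict = field(default_factory=lambda: dict(HEAD_BINS))
    seed: int = 0

    def __post_init__(self):
        if self.trunk_blocks < 1:
            raise ValueError("trunk_blocks must be >= 1")
        if isinstance(self.reduction_channels, list):
            self.reduction_channels = tuple(self.reduction_channels)
        if isinstance(self.dilation_cycle, list):
            self.dilation_cycle = tuple(self.dilation_cycle)
        if self.reduction_channels[-1] != self.trunk_channels:
            raise ValueError(
                "last reduction channel count must equal trunk_channels "
                f"({self.reduction_channels[-1]} != {self.trunk_channels})"
            )


@dataclass(frozen=True)
class GeometryLogits:
    theta: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    dist: np.ndarray

    def __post_init__(self):
        c = self.theta.shape[0]
        for name in OBJECTIVES:
            a = getattr(self, name)
            if a.shape[:2] != (c, c):
                raise ShapeError(f"{name} head output is not c x c: {a.shape}")
            if not np.isfinite(a).all():
                raise ShapeError(f"{name} logits contain NaN/Inf")

    @property
    def c(self) -> int:
        return self.theta.shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in OBJECTIVES}


@dataclass(frozen=True)
class GeometryPosteriors:
    theta: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    dist: np.ndarray

    @property
    def c(self) -> int:
        return self.theta.shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in OBJECTIVES}


class GeometryNet(Layer):
    """Reduction + dilated-ResNet trunk + four 1x1 classification heads."""

    def __init__(self, cfg: NetConfig | None = None, dtype=np.float32,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg or NetConfig()
        self.dtype = dtype
        if rng is None:
            rng = np.random.default_rng(np.random.SeedSequence([0xA11, self.cfg.seed]))
        layers: list[Layer] = []
        cin = TOTAL_CHANNELS
        for i, cout in enumerate(self.cfg.reduction_channels):
            layers += [
                Conv2d(cin, cout, 1, rng, dtype=dtype, prefix=f"red{i}.conv"),
                InstanceNorm(cout, dtype=dtype, prefix=f"red{i}.inorm"),
                ReLU(),
            ]
            cin = cout
        self.reduction = Sequential(layers)
        cycle = self.cfg.dilation_cycle
        self.blocks = [
            ResidualBlock(cin, cycle[k % len(cycle)], rng, dtype=dtype,
                          prefix=f"block{k:02d}")
            for k in range(self.cfg.trunk_blocks)
        ]
        self.trunk = Sequential(self.blocks)
        self.heads = {
            name: Conv2d(cin, bins, 1, rng, dtype=dtype, prefix=f"head.{name}")
            for name, bins in self.cfg.head_bins.items()
        }

    def params(self) -> list[Param]:
        ps = self.reduction.params() + self.trunk.params()
        for name in OBJECTIVES:
            ps += self.heads[name].params()
        return ps

    def forward(self, features: np.ndarray) -> GeometryLogits:
        f = np.asarray(features, dtype=self.dtype)
        if f.ndim != 3 or f.shape[2] != TOTAL_CHANNELS:
            raise ShapeError(
                f"pair features must be (c, c, {TOTAL_CHANNELS}), got {f.shape}"
            )
        x = self.trunk.forward(self.reduction.forward(f))
        return GeometryLogits(
            **{name: self.heads[name].forward(x) for name in OBJECTIVES}
        )

    def backward(self, dlogits: dict[str, np.ndarray]) -> np.ndarray:
        dx = None
        for name in OBJECTIVES:
            g = self.heads[name].backward(dlogits[name])
            dx = g if dx is None else dx + g
        return self.reduction.backward(self.trunk.backward(dx))


def logits_to_posteriors(logits: GeometryLogits,
                         symmetrize_symmetric_heads: bool = True) -> GeometryPosteriors:
    """Per-pair softmax; optionally average dist/omega with their transpose."""
    post = {}
    for name in OBJECTIVES:
        p = softmax(getattr(logits, name).astype(np.float64), axis=-1)
        if symmetrize_symmetric_heads and name in SYMMETRIC_OBJECTIVES:
            p = 0.5 * (p + p.transpose(1, 0, 2))
        post[name] = p.astype(np.float32)
    return GeometryPosteriors(**post)


class GeometryModel:
    """Pair-feature builder + geometry head; the full trainable model.

    The embedder is outside this class and frozen: its output enters
    :meth:`forward` as plain arrays and receives no gradient.
    """

    def __init__(self, cfg: NetConfig | None = None, dtype=np.float32):
        self.cfg = cfg or NetConfig()
        feat_rng = np.random.default_rng(np.random.SeedSequence([0xFEA7, self.cfg.seed]))
        self.builder = PairFeatureBuilder(feat_rng, dtype=dtype)
        self.net = GeometryNet(self.cfg, dtype=dtype)
        self.dtype = dtype

    def params(self) -> list[Param]:
        return self.builder.params() + self.net.params()

    def forward(self, e: EmbedderOutput) -> GeometryLogits:
        return self.net.forward(self.builder.build(e))

    def backward(self, dlogits: dict[str, np.ndarray]) -> None:
        self.builder.backward(self.net.backward(dlogits))

    def predict_posteriors(self, e: EmbedderOutput,
                           symmetrize: bool = True) -> GeometryPosteriors:
        return logits_to_posteriors(self.forward(e), symmetrize)

    # -- checkpointing ----------------------------------------------------

    def save(self, path, metadata: dict | None = None) -> None:
        names = [p.name for p in self.params()]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate parameter names in checkpoint")
        arrays = {f"param/{p.name}": p.value for p in self.params()}
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "net_config": asdict(self.cfg),
            "metadata": metadata or {},
        }
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GeometryModel":
        path = Path(path)
        with np.load(path) as data:
            if "__meta__" not in data:
                raise SchemaError(f"{path} is not a pairgeom checkpoint (no metadata)")
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            major = str(meta.get("format_version", "")).split(".")[0]
            if major != CHECKPOINT_FORMAT_VERSION.split(".")[0]:
                raise SchemaError(
                    f"unsupported checkpoint format version {meta.get('format_version')!r}"
                )
            cfgd = dict(meta["net_config"])
            model = cls(NetConfig(**cfgd))
            for p in model.params():
                key = f"param/{p.name}"
                if key not in data:
                    raise SchemaError(f"checkpoint missing parameter {p.name!r}")
                val = data[key]
                if val.shape != p.value.shape:
                    raise SchemaError(
                        f"parameter {p.name!r} has shape {val.shape}, "
                        f"expected {p.value.shape}"
                    )
                p.value = val.astype(p.value.dtype)
                p.grad = np.zeros_like(p.value)
        model._rebind()
        return model

    def _rebind(self):
        """No-op hook kept for symmetry; params are rebound in-place on load."""
        return None
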