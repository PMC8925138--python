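"""Pair-feature construction: embedder output -> c x c x 400 feature map.

Channel layout (fixed, checkpoint-relevant):

* ``[0:256)``  — outer-concatenated query features: the query row of the MSA
  features is reduced 768 -> 384 -> 192 -> 128 by a position-wise MLP (ReLU
  between layers, none after the last), then ``out[i, j] = concat(q[i], q[j])``.
* ``[256:400)`` — row attentions symmetrized as ``M + M^T``, stacked
  layer-major then head (12 x 12 = 144 channels).  Exactly symmetric.

The MLP is trainable; the attention channels carry no gradient (the embedder
is frozen).
"""

from __future__ import annotations

import numpy as np

from .embedder import FEATURE_DIM, N_HEADS, N_LAYERS, EmbedderOutput
from .errors import ShapeError
from .nn import Layer, Linear, ReLU, Sequential

MLP_SIZES = (384, 192, 128)
QUERY_CHANNELS = 2 * MLP_SIZES[-1]          # 256
ATTENTION_CHANNELS = N_LAYERS * N_HEADS     # 144
TOTAL_CHANNELS = QUERY_CHANNELS + ATTENTION_CHANNELS  # 400


class QueryReducer(Sequential):
    """Position-wise 768 -> 384 -> 192 -> 128 MLP over the query row."""

    def __init__(self, rng: np.random.Generator, dtype=np.float32):
        sizes = (FEATURE_DIM, *MLP_SIZES)
        layers: list[Layer] = []
        for i, (din, dout) in enumerate(zip(sizes[:-1], sizes[1:])):
            layers.append(Linear(din, dout, rng, dtype=dtype, prefix=f"mlp.l{i}"))
            if i < len(MLP_SIZES) - 1:
                layers.append(ReLU())
        super().__init__(layers)


def reduce_query_features(msa_features: np.ndarray, mlp: QueryReducer) -> np.ndarray:
    """Apply the reduction MLP to the query row; returns (c, 128)."""
    f = np.asarray(msa_features)
    if f.ndim != 3 or f.shape[2] != FEATURE_DIM:
        raise ShapeError(f"expected (r, c, {FEATURE_DIM}) MSA features, got {f.shape}")
    return mlp.forward(f[0])


def outer_concatenate(q: np.ndarray) -> np.ndarray:
    """out[i, j] = concat(q[i], q[j]); (c, d) -> (c, c, 2d)."""
    c, d = q.shape
    out = np.empty((c, c, 2 * d), dtype=q.dtype)
    out[:, :, :d] = q[:, None, :]
    out[:, :, d:] = q[None, :, :]
    return out


def outer_concatenate_backward(dout: np.ndarray) -> np.ndarray:
    """Gradient of :func:`outer_concatenate` w.r.t. q."""
    d = dout.shape[2] // 2
    return dout[:, :, :d].sum(axis=1) + dout[:, :, d:].sum(axis=0)


def symmetrize_attentions(row_attentions: np.ndarray) -> np.ndarray:
    """Stack per-head maps as M + M^T channels; (12, 12, c, c) -> (c, c, 144)."""
    a = np.asarray(row_attentions)
    if a.ndim != 4 or a.shape[:2] != (N_LAYERS, N_HEADS):
        raise ShapeError(
            f"expected ({N_LAYERS}, {N_HEADS}, c, c) attentions, got {a.shape}"
        )
    sym = a + a.transpose(0, 1, 3, 2)
    c = a.shape[-1]
    return np.moveaxis(sym.reshape(ATTENTION_CHANNELS, c, c), 0, -1)


class PairFeatureBuilder:
    """Owns the trainable MLP; builds and backpropagates the feature map."""

    def __init__(self, rng: np.random.Generator, dtype=np.float32):
        self.mlp = QueryReducer(rng, dtype=dtype)
        self.dtype = dtype

    def params(self):
        return self.mlp.params()

    def build(self, e: EmbedderOutput) -> np.ndarray:
        q = reduce_query_features(e.msa_features.astype(self.dtype), self.mlp)
        attn = symmetrize_attentions(e.row_attentions.astype(self.dtype))
        if q.shape[0] != attn.shape[0]:
            raise ShapeError(
                f"query branch has c={q.shape[0]} but attention branch "
                f"has c={attn.shape[0]}"
            )
        return np.concatenate([outer_concatenate(q), attn], axis=2)

    def backward(self, dpf: np.ndarray) -> None:
        """Propagate feature-map gradients into the MLP (attention slice dropped)."""
        dq = outer_concatenate_backward(dpf[:, :, :QUERY_CHANNELS])
        self.mlp.backward(dq)


def build_pair_features(e: EmbedderOutput,
                        builder: PairFeatureBuilder | None = None,
                        seed: int = 0) -> np.ndarray:
    """Convenience wrapper: build the (c, c, 400) map with a fresh or given MLP."""
    if builder is None:
        builder = PairFeatureBuilder(np.random.default_rng(seed))
    return builder.build(e)
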