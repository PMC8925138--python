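"""MSA embedding contract: per-token features plus row-attention maps.

Every embedder maps a tokenized ``r x c`` MSA to

* ``msa_features`` — an ``r x c x 768`` real tensor (the language model's last
  attention-block output), and
* ``row_attentions`` — a ``12 x 12 x c x c`` tensor (layers x heads), each
  ``c x c`` slice row-stochastic over the key axis.

The package ships a deterministic stub that honors this contract for testing
and desk-scale training, and an optional adapter to a pretrained MSA
transformer (extra dependency).  The embedder is frozen everywhere: no
gradients flow into it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, CapacityError
from .msa import VOCAB_SIZE, TokenizedMsa

FEATURE_DIM = 768
N_LAYERS = 12
N_HEADS = 12


@dataclass(frozen=True)
class EmbedderOutput:
    msa_features: np.ndarray   # (r, c, 768)
    row_attentions: np.ndarray  # (12, 12, c, c)

    def __post_init__(self):
        f, a = np.asarray(self.msa_features), np.asarray(self.row_attentions)
        if f.ndim != 3 or f.shape[2] != FEATURE_DIM:
            raise ValueError(f"msa_features must be (r, c, {FEATURE_DIM}), got {f.shape}")
        c = f.shape[1]
        if a.shape != (N_LAYERS, N_HEADS, c, c):
            raise ValueError(
                f"row_attentions must be ({N_LAYERS}, {N_HEADS}, {c}, {c}), got {a.shape}"
            )
        if not (np.isfinite(f).all() and np.isfinite(a).all()):
            raise ValueError("embedder output contains NaN/Inf")
        if a.min() < 0:
            raise ValueError("attention weights must be non-negative")
        sums = a.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-4):
            raise ValueError("attention rows must sum to 1 within 1e-4")

    @property
    def r(self) -> int:
        return self.msa_features.shape[0]

    @property
    def c(self) -> int:
        return self.msa_features.shape[1]


class StubEmbedder:
    """Seeded content-dependent test double for the language model.

    Features are a fixed random projection of one-hot tokens plus a positional
    term; attention scores are bilinear forms over per-column residue-frequency
    profiles, softmax-normalized over keys.  All weights come from a
    ``numpy.random.Generator(PCG64)`` seeded at construction, so outputs are
    bit-reproducible across runs and platforms and depend on sequence content,
    not only on shape.
    """

    name = "stub"
    max_positions = 1024
    _score_dim = 16

    def __init__(self, seed: int = 0):
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([0x5EED, seed]))
        self._w_tok = rng.standard_normal((VOCAB_SIZE, FEATURE_DIM)).astype(np.float32)
        self._w_pos = (
            0.3 * rng.standard_normal((self.max_positions, FEATURE_DIM))
        ).astype(np.float32)
        self._w_q = rng.standard_normal(
            (N_LAYERS, N_HEADS, VOCAB_SIZE, self._score_dim)
        ).astype(np.float32)
        self._w_k = rng.standard_normal(
            (N_LAYERS, N_HEADS, VOCAB_SIZE, self._score_dim)
        ).astype(np.float32)

    def embed(self, tokens: TokenizedMsa) -> EmbedderOutput:
        r, c = tokens.r, tokens.c
        if c > self.max_positions:
            raise CapacityError(
                f"stub embedder supports at most {self.max_positions} columns, got {c}"
            )
        feats = self._w_tok[tokens.tokens] + self._w_pos[:c][None, :, :]
        # per-column residue frequency profile (depends on every MSA row)
        profile = np.zeros((c, VOCAB_SIZE), dtype=np.float32)
        np.add.at(profile, (np.tile(np.arange(c), r), tokens.tokens.ravel()), 1.0)
        profile /= r
        q = np.einsum("cv,lhvd->lhcd", profile, self._w_q)
        k = np.einsum("cv,lhvd->lhcd", profile, self._w_k)
        scores = np.einsum("lhid,lhjd->lhij", q, k) / np.sqrt(self._score_dim)
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        return EmbedderOutput(
            msa_features=feats.astype(np.float32),
            row_attentions=attn.astype(np.float32),
        )

    __call__ = embed


def load_pretrained_adapter(weights_locator: str = "esm_msa1b_t12_100M_UR50S"):
    """Return an embed-conforming callable backed by the pretrained model.

    The adapter remaps the package vocabulary to the external model's and
    strips the model's prepended begin-of-sequence token so attentions come
    back exactly ``c x c``.  Requires the ``esm`` extra.
    """
    try:
        import esm  # type: ignore
    except ImportError as exc:
        raise CapabilityError(
            "the pretrained MSA-transformer adapter requires the optional "
            "'esm' extra (pip install pairgeom[esm]); it is not installed"
        ) from exc
    import torch  # noqa: F401  (esm implies torch)

    model, alphabet = esm.pretrained.load_model_and_alphabet(weights_locator)
    model.eval()
    converter = alphabet.get_batch_converter()
    from .msa import detokenize

    def _embed(tokens: TokenizedMsa) -> EmbedderOutput:
        msa = detokenize(tokens)
        data = [(f"seq{i}", s) for i, s in enumerate(msa.sequences)]
        _, _, batch_tokens = converter(data)
        with torch.no_grad():
            out = model(
                batch_tokens, repr_layers=[12], need_head_weights=True
            )
        feats = out["representations"][12][0, :, 1:, :]  # strip BOS column
        attn = out["row_attentions"][0, :, :, 1:, 1:]
        return EmbedderOutput(
            msa_features=feats.numpy(),
            row_attentions=attn.numpy(),
        )

    _embed.name = "msa-transformer"  # type: ignore[attr-defined]
    return _embed


_REGISTRY = {
    "stub": lambda seed=0: StubEmbedder(seed=seed),
    "msa-transformer": lambda seed=0: load_pretrained_adapter(),
}


def get_embedder(name: str, seed: int = 0):
    """Look up a registered embedder by name ('stub' or 'msa-transformer')."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise CapabilityError(
            f"unknown embedder {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(seed=seed)
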