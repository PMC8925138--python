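"""Loss and optimization loop for the geometry head (embedder frozen).

The loss is the equal-weight sum of four categorical cross-entropies (theta,
phi, omega, distance), each averaged over valid off-diagonal residue pairs;
no-contact pairs are trained with label 0.  Optimization follows the study
conditions: RAdam at learning rate 1e-3 with an effective batch of 16
examples assembled by gradient accumulation over micro-batches of one
(variable sequence lengths preclude padding-free batching).  Proteins longer
than 1023 residues are skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .embedder import StubEmbedder, get_embedder
from .errors import ShapeError
from .geometry import GeometryLabels
from .msa import Msa, tokenize
from .network import OBJECTIVES, GeometryLogits, GeometryModel, NetConfig
from .nn import RAdam, softmax
from .subsample import SubsampleConfig, subsample_training

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    effective_batch: int = 16
    epochs: int = 1
    max_length: int = 1023
    max_micro_steps: int | None = None
    loss_weights: dict = field(default_factory=lambda: {k: 1.0 for k in OBJECTIVES})
    embedder: str = "stub"
    seed: int = 0

    def __post_init__(self):
        if self.effective_batch < 1:
            raise ValueError("effective_batch must be >= 1")
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2")


def geometry_loss(logits: GeometryLogits, labels: GeometryLabels,
                  weights: dict | None = None, with_grad: bool = False):
    """Equal-weight categorical cross-entropy over off-diagonal pairs.

    Returns ``(loss, breakdown)`` or ``(loss, breakdown, dlogits)`` where
    ``dlogits`` is the gradient of the scalar loss w.r.t. each head's logits.
    """
    c = logits.c
    if labels.length != c:
        raise ShapeError(
            f"labels are for length {labels.length}, logits for {c}"
        )
    weights = weights or {k: 1.0 for k in OBJECTIVES}
    mask = ~np.eye(c, dtype=bool)
    npairs = int(mask.sum())
    total = 0.0
    breakdown = {}
    grads = {}
    ldict, ydict = logits.as_dict(), labels.as_dict()
    for name in OBJECTIVES:
        lg = ldict[name].astype(np.float64)
        y = ydict[name]
        p = softmax(lg, axis=-1)
        picked = np.take_along_axis(p, y[..., None], axis=-1)[..., 0]
        ce = -np.log(np.clip(picked[mask], 1e-300, None)).mean()
        breakdown[name] = float(ce)
        total += weights[name] * ce
        if with_grad:
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, y[..., None], 1.0, axis=-1)
            g = (p - onehot) * mask[..., None] * (weights[name] / npairs)
            grads[name] = g.astype(ldict[name].dtype)
    if with_grad:
        return float(total), breakdown, grads
    return float(total), breakdown


@dataclass
class TrainResult:
    model: GeometryModel
    epoch_losses: list
    step_losses: list


def train_model(dataset: list, cfg: TrainConfig | None = None,
                model: GeometryModel | None = None,
                net_config: NetConfig | None = None,
                embedder=None, log_path=None) -> TrainResult:
    """Train the geometry model on (Msa, GeometryLabels) pairs.

    One epoch is a pass over the dataset in seeded shuffled order; each
    example is MSA-subsampled, embedded (no gradient), featurized and scored,
    and gradients are accumulated for ``effective_batch`` examples before an
    optimizer step.  Deterministic for a fixed seed.  Resumable by passing a
    previously trained/loaded ``model``.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    usable = []
    for msa, labels in dataset:
        if msa.c > cfg.max_length:
            logger.warning("skipping %d-residue example (max_length=%d)",
                           msa.c, cfg.max_length)
            continue
        if labels.length != msa.c:
            raise ShapeError(
                f"labels length {labels.length} != query length {msa.c}"
            )
        usable.append((msa, labels))
    if not usable:
        raise ValueError("no training examples within max_length")

    if model is None:
        model = GeometryModel(net_config or NetConfig(seed=cfg.seed))
    if embedder is None:
        embedder = (StubEmbedder(seed=cfg.seed) if cfg.embedder == "stub"
                    else get_embedder(cfg.embedder, seed=cfg.seed))
    opt = RAdam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([0x7124, cfg.seed]))

    step_losses: list[float] = []
    epoch_losses: list[float] = []
    micro = 0
    pending = 0
    log_fh = open(log_path, "a") if log_path else None
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(usable))
            epoch_sum = 0.0
            for idx in order:
                msa, labels = usable[idx]
                sub_seed = int(rng.integers(2**31))
                sub = subsample_training(
                    msa, SubsampleConfig(seed=sub_seed),
                    rng=np.random.default_rng(sub_seed),
                )
                e = embedder.embed(tokenize(sub))   # frozen: plain arrays out
                logits = model.forward(e)
                loss, breakdown, grads = geometry_loss(
                    logits, labels, cfg.loss_weights, with_grad=True
                )
                scale = 1.0 / cfg.effective_batch
                model.backward({k: g * scale for k, g in grads.items()})
                step_losses.append(loss)
                epoch_sum += loss
                micro += 1
                pending += 1
                if log_fh:
                    log_fh.write(json.dumps(
                        {"epoch": epoch, "micro_step": micro, "loss": loss,
                         **{f"ce_{k}": v for k, v in breakdown.items()}}
                    ) + "\n")
                if pending == cfg.effective_batch:
                    opt.step()
                    opt.zero_grad()
                    pending = 0
                if cfg.max_micro_steps and micro >= cfg.max_micro_steps:
                    break
            epoch_losses.append(epoch_sum / max(1, len(order)))
            if cfg.max_micro_steps and micro >= cfg.max_micro_steps:
                break
        if pending:  # flush a final partial accumulation window
            opt.step()
            opt.zero_grad()
    finally:
        if log_fh:
            log_fh.close()
    return TrainResult(model=model, epoch_losses=epoch_losses,
                       step_losses=step_losses)
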