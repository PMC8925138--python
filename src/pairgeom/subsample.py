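"""MSA row subsampling.

Training uses a random subsample bounded by a token budget: the row count is
the deterministic clamp ``min(r, max(16, floor(2**14 / c)))`` and only the
choice of rows is random.  Inference uses greedy diversity *minimization* to
256 rows — repeatedly adding the sequence with the lowest average Hamming
fraction to the rows already selected — and a diversity-*maximizing* variant
(greedy max-min) is provided for ablations.  The query is always kept in
row 0.

Hamming fraction treats the gap as an ordinary 23rd symbol and divides the
mismatch count by the full column count ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import Msa, tokenize


@dataclass
class SubsampleConfig:
    train_token_budget: int = 2**14
    train_min_rows: int = 16
    inference_rows: int = 256
    strategy: str = "diversity_min"  # random | diversity_min | diversity_max
    seed: int = 0

    def __post_init__(self):
        if self.train_min_rows < 1 or self.inference_rows < 1:
            raise ValueError("row minimums must be >= 1")
        if self.train_token_budget < self.train_min_rows:
            raise ValueError("token budget below the minimum row count")
        if self.strategy not in {"random", "diversity_min", "diversity_max"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")


def hamming_fraction(a: str, b: str) -> float:
    """Fraction of mismatching columns between two aligned rows."""
    if len(a) != len(b) or len(a) == 0:
        raise ValueError(
            f"aligned sequences must have equal nonzero length ({len(a)} vs {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b)) / len(a)


def training_row_count(r: int, c: int, cfg: SubsampleConfig | None = None) -> int:
    """Deterministic training subsample size: min(r, max(16, floor(2^14/c)))."""
    cfg = cfg or SubsampleConfig()
    return min(r, max(cfg.train_min_rows, cfg.train_token_budget // c))


def subsample_training(msa: Msa, cfg: SubsampleConfig | None = None,
                       rng: np.random.Generator | None = None) -> Msa:
    """Random training subsample under the token budget, query kept first."""
    cfg = cfg or SubsampleConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = training_row_count(msa.r, msa.c, cfg)
    if n >= msa.r:
        return msa.take_rows(range(msa.r))
    others = rng.choice(np.arange(1, msa.r), size=n - 1, replace=False)
    return msa.take_rows([0, *sorted(others.tolist())])


def _pairwise_hamming(msa: Msa) -> np.ndarray:
    """r x r matrix of Hamming fractions (vectorized over token codes)."""
    toks = tokenize(msa).tokens
    # broadcasting r x r x c would be large for big r; chunk over rows
    r = toks.shape[0]
    out = np.empty((r, r), dtype=np.float64)
    for i in range(r):
        out[i] = (toks[i] != toks).mean(axis=1)
    return out


def subsample_inference(msa: Msa, cfg: SubsampleConfig | None = None) -> Msa:
    """Greedy diversity minimization to ``inference_rows`` sequences.

    Starting from the query, repeatedly add the unselected row with the lowest
    mean Hamming fraction to all currently selected rows; ties go to the
    lowest original row index.  Deterministic.
    """
    cfg = cfg or SubsampleConfig()
    n = min(cfg.inference_rows, msa.r)
    return msa.take_rows(_greedy_select(msa, n, minimize=True))


def subsample_diversity_max(msa: Msa, n: int) -> Msa:
    """Greedy max-min diversity selection (ablation counterpart)."""
    n = min(n, msa.r)
    return msa.take_rows(_greedy_select(msa, n, minimize=False))


def _greedy_select(msa: Msa, n: int, minimize: bool) -> list[int]:
    if n >= msa.r:
        return list(range(msa.r))
    dist = _pairwise_hamming(msa)
    selected = [0]
    candidates = np.ones(msa.r, dtype=bool)
    candidates[0] = False
    if minimize:
        # running sum of distances to the selected set -> mean is sum/len
        score = dist[0].copy()
        while len(selected) < n:
            masked = np.where(candidates, score, np.inf)
            pick = int(np.argmin(masked))  # argmin takes the lowest index on ties
            selected.append(pick)
            candidates[pick] = False
            score += dist[pick]
    else:
        # max-min: keep the minimum distance to the selected set
        score = dist[0].copy()
        while len(selected) < n:
            masked = np.where(candidates, score, -np.inf)
            pick = int(np.argmax(masked))
            selected.append(pick)
            candidates[pick] = False
            score = np.minimum(score, dist[pick])
    return selected


def subsample(msa: Msa, strategy: str, n: int, seed: int = 0) -> Msa:
    """Dispatch helper used by the CLI."""
    if strategy == "random":
        if n >= msa.r:
            return msa.take_rows(range(msa.r))
        rng = np.random.default_rng(seed)
        others = rng.choice(np.arange(1, msa.r), size=n - 1, replace=False)
        return msa.take_rows([0, *sorted(others.tolist())])
    if strategy in {"min", "diversity_min"}:
        return msa.take_rows(_greedy_select(msa, min(n, msa.r), minimize=True))
    if strategy in {"max", "diversity_max"}:
        return subsample_diversity_max(msa, n)
    raise ValueError(f"unknown strategy {strategy!r}")
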