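"""Contact extraction and evaluation metrics.

Contacts follow the CASP convention: a residue pair is in contact when its
CB-CB distance is strictly below 8 A; long-range means sequence separation
``|i - j| >= 24``.  Predicted contact probability collapses the distance
posterior over the bins fully below the cutoff (bins 1-12 of the 37-class
scheme).  Top L/k precision ranks eligible pairs by probability (ties broken
lexicographically) and scores the top ``max(1, floor(L * k))``.

The per-objective Pearson correlation compares the argmax predicted bin index
with the ground-truth bin index over off-diagonal pairs whose true label is
not the no-contact class.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError, UndefinedMetricError
from .geometry import GeometryLabels, GeometryMaps
from .network import OBJECTIVES, GeometryPosteriors

CONTACT_CUTOFF = 8.0
LONG_RANGE_SEP = 24


def contact_probability(post: GeometryPosteriors,
                        bin_edges: np.ndarray | None = None,
                        cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Collapse the distance posterior to P(contact); symmetric, 0 diagonal."""
    if bin_edges is None:
        bin_edges = np.arange(2.0, 20.0 + 1e-9, 0.5)
    # distance bin k (k >= 1) covers [edges[k-1], edges[k]); include bins whose
    # upper edge is <= cutoff
    include = np.nonzero(bin_edges[1:] <= cutoff + 1e-9)[0] + 1
    p = post.dist[..., include].sum(axis=-1)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 0.0)
    return np.clip(p, 0.0, 1.0)


def true_contacts(g: GeometryMaps, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Boolean CB-CB < cutoff map, symmetric, False diagonal."""
    m = (g.d < cutoff) & g.valid
    return m & m.T


def _eligible_pairs(c: int, min_sep: int):
    i, j = np.triu_indices(c, k=max(1, min_sep))
    return i, j


def top_k_precision(pred: np.ndarray, truth: np.ndarray, k_fraction: float = 1.0,
                    min_sep: int = LONG_RANGE_SEP) -> float:
    """Precision of the top ``max(1, floor(L * k_fraction))`` eligible pairs.

    Raises :class:`UndefinedMetricError` when no pair satisfies the
    separation constraint (rather than returning 0).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 2 or pred.shape[0] != pred.shape[1]:
        raise ShapeError(f"prediction/truth shapes disagree: {pred.shape} vs {truth.shape}")
    L = pred.shape[0]
    ii, jj = _eligible_pairs(L, min_sep)
    if len(ii) == 0:
        raise UndefinedMetricError(
            f"no residue pairs with separation >= {min_sep} for length {L}"
        )
    # sort by probability descending, ties by (i, j) lexicographic ascending
    order = np.lexsort((jj, ii, -pred[ii, jj]))
    n = max(1, int(L * k_fraction))
    n = min(n, len(order))
    top = order[:n]
    return float(truth[ii[top], jj[top]].sum() / n)


def precision_report(pred: np.ndarray, truth: np.ndarray,
                     min_sep: int = LONG_RANGE_SEP) -> dict:
    """Top L / L/2 / L/5 precisions plus pair counts."""
    L = pred.shape[0]
    ii, jj = _eligible_pairs(L, min_sep)
    report = {
        "length": L,
        "min_sep": min_sep,
        "eligible_pairs": int(len(ii)),
        "true_contacts": int(np.asarray(truth, dtype=bool)[ii, jj].sum()) if len(ii) else 0,
    }
    for label, frac in (("top_L", 1.0), ("top_L2", 0.5), ("top_L5", 0.2)):
        report[label] = top_k_precision(pred, truth, frac, min_sep)
    return report


def maxbin_correlation(post: GeometryPosteriors, labels: GeometryLabels) -> dict:
    """Pearson r between argmax predicted bin and true bin, per objective.

    Pairs with ground-truth label 0 (no contact) and the diagonal are
    excluded; a constant vector or fewer than 2 pairs raises
    :class:`UndefinedMetricError`.
    """
    c = post.c
    if labels.length != c:
        raise ShapeError(f"labels length {labels.length} != posterior length {c}")
    offdiag = ~np.eye(c, dtype=bool)
    out = {}
    for name in OBJECTIVES:
        y = labels.as_dict()[name]
        include = offdiag & (y != 0)
        if include.sum() < 2:
            raise UndefinedMetricError(
                f"{name}: fewer than 2 contact pairs to correlate"
            )
        pred_idx = post.as_dict()[name].argmax(axis=-1)[include].astype(np.float64)
        true_idx = y[include].astype(np.float64)
        if pred_idx.std() == 0 or true_idx.std() == 0:
            raise UndefinedMetricError(f"{name}: constant bin-index vector")
        out[name] = float(np.corrcoef(pred_idx, true_idx)[0, 1])
    return out


# ---------------------------------------------------------------------------
# CASP RR contact format

def write_rr(pred: np.ndarray, path, sequence: str | None = None,
             min_sep: int = 1, d1: float = 0.0, d2: float = CONTACT_CUTOFF) -> None:
    """Write contacts as CASP RR records: ``i j d1 d2 prob`` (1-based)."""
    pred = np.asarray(pred)
    L = pred.shape[0]
    ii, jj = np.triu_indices(L, k=min_sep)
    order = np.lexsort((jj, ii, -pred[ii, jj]))
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        if sequence:
            for k in range(0, len(sequence), 50):
                fh.write(sequence[k:k + 50] + "\n")
        for idx in order:
            i, j = int(ii[idx]), int(jj[idx])
            fh.write(f"{i + 1} {j + 1} {d1:.1f} {d2:.1f} {pred[i, j]:.6f}\n")
        fh.write("END\n")


def read_rr(path, length: int | None = None) -> np.ndarray:
    """Read an RR file back into a symmetric probability matrix."""
    records = []
    max_idx = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 5:
                try:
                    i, j = int(parts[0]), int(parts[1])
                except ValueError:
                    continue
                p = float(parts[4])
                records.append((i - 1, j - 1, p))
                max_idx = max(max_idx, i, j)
    L = length if length is not None else max_idx
    out = np.zeros((L, L))
    for i, j, p in records:
        out[i, j] = out[j, i] = p
    return out
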