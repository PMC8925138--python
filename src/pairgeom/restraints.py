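"""Restraint container: per-pair geometry posteriors handed downstream.

The file is a compressed named-array archive whose keys match what the
external structure-realization scripts expect — ``dist`` (c x c x 37),
``omega`` (c x c x 25), ``theta`` (c x c x 25), ``phi`` (c x c x 13) — plus
JSON metadata (query sequence, package version, embedder name, subsample
strategy) and a format version.  Readers re-validate normalization and
reject unknown major versions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .errors import RestraintValidationError, SchemaError
from .network import HEAD_BINS, OBJECTIVES, GeometryPosteriors

RESTRAINT_FORMAT_VERSION = "1.0"
_NORM_ATOL = 1e-5


def _validate(arrays: dict) -> None:
    c = arrays["dist"].shape[0]
    for name in OBJECTIVES:
        a = arrays[name]
        expected = (c, c, HEAD_BINS[name])
        if a.shape != expected:
            raise RestraintValidationError(
                f"{name} array has shape {a.shape}, expected {expected}"
            )
        if not np.isfinite(a).all() or a.min() < -_NORM_ATOL:
            raise RestraintValidationError(f"{name} array is not a valid posterior")
        sums = a.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_NORM_ATOL):
            raise RestraintValidationError(
                f"{name} posteriors do not sum to 1 (max dev "
                f"{np.abs(sums - 1).max():.2e})"
            )


def write_restraints(post: GeometryPosteriors, meta: dict | None, path) -> None:
    """Serialize posteriors (float32) + metadata to a compressed archive."""
    arrays = {k: np.asarray(v, dtype=np.float32) for k, v in post.as_dict().items()}
    _validate(arrays)
    payload = {
        "format_version": RESTRAINT_FORMAT_VERSION,
        "package_version": __version__,
        **(meta or {}),
    }
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(payload).encode(), dtype=np.uint8),
        **arrays,
    )


def read_restraints(path) -> tuple[GeometryPosteriors, dict]:
    """Load and re-validate a restraint archive; returns (posteriors, meta)."""
    path = Path(path)
    with np.load(path) as data:
        if "__meta__" not in data:
            raise SchemaError(f"{path}: missing metadata block")
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        version = str(meta.get("format_version", ""))
        major = version.split(".")[0]
        if major != RESTRAINT_FORMAT_VERSION.split(".")[0]:
            raise SchemaError(f"{path}: unsupported restraint format version {version!r}")
        arrays = {}
        for name in OBJECTIVES:
            if name not in data:
                raise SchemaError(f"{path}: missing restraint array {name!r}")
            arrays[name] = data[name]
    _validate(arrays)
    return GeometryPosteriors(**arrays), meta
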