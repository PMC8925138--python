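"""Multiple sequence alignment parsing and tokenization.

An MSA is an ``r x c`` character matrix over the 20 standard amino acids,
``X`` (unknown) and ``-`` (gap), with the query sequence in row 0.  A3M input
follows the HHblits convention: lowercase letters are insertions relative to
the query and are removed (together with ``.``) so that every retained row has
exactly ``c = len(query)`` columns.

Tokenization maps symbols to integer ids through a fixed table shipped with
the package; any remapping to an external language model's vocabulary is the
responsibility of the embedder adapter, not of this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AlphabetError, MalformedAlignmentError, MsaParseError

logger = logging.getLogger(__name__)

#: Canonical symbol order: 20 standard residues, unknown, gap.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X" + "-"

#: Fixed bidirectional symbol <-> id table.
TOKEN_TO_ID = {s: i for i, s in enumerate(ALPHABET)}
ID_TO_TOKEN = {i: s for i, s in enumerate(ALPHABET)}
VOCAB_SIZE = len(ALPHABET)
GAP_ID = TOKEN_TO_ID["-"]
UNKNOWN_ID = TOKEN_TO_ID["X"]

#: Non-standard residue codes coerced to 'X' (ambiguity codes and the two
#: genetically encoded rarities selenocysteine/pyrrolysine).
NONSTANDARD = {"B", "Z", "J", "U", "O"}


@dataclass(frozen=True)
class Msa:
    """Aligned sequences, query first.

    Attributes
    ----------
    sequences:
        Uppercase aligned rows, all of identical length.
    headers:
        Opaque labels taken from the FASTA headers (same length as
        ``sequences``).
    query_index:
        Always 0 after parsing; kept explicit for clarity.
    """

    sequences: tuple[str, ...]
    headers: tuple[str, ...] = field(default=())
    query_index: int = 0

    def __post_init__(self):
        if len(self.sequences) < 1:
            raise MsaParseError("an MSA needs at least one row (the query)")
        c = len(self.sequences[0])
        if c < 1:
            raise MsaParseError("query sequence is empty")
        for i, row in enumerate(self.sequences):
            if len(row) != c:
                raise MalformedAlignmentError(
                    f"row {i} has {len(row)} aligned columns, expected {c}"
                )
            bad = set(row) - set(ALPHABET)
            if bad:
                raise AlphabetError(
                    f"row {i} contains illegal symbol(s) {sorted(bad)}"
                )
        if not self.headers:
            object.__setattr__(
                self, "headers", tuple(f"seq{i}" for i in range(len(self.sequences)))
            )
        elif len(self.headers) != len(self.sequences):
            raise MsaParseError("headers and sequences differ in length")

    @property
    def r(self) -> int:
        """Number of rows (sequences)."""
        return len(self.sequences)

    @property
    def c(self) -> int:
        """Number of columns (aligned length)."""
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def take_rows(self, indices) -> "Msa":
        """Row subset in the given order (used by the subsamplers)."""
        return Msa(
            sequences=tuple(self.sequences[i] for i in indices),
            headers=tuple(self.headers[i] for i in indices),
        )


@dataclass(frozen=True)
class TokenizedMsa:
    """Integer ``r x c`` matrix plus the vocabulary it was encoded with."""

    tokens: np.ndarray
    vocab: str = ALPHABET

    def __post_init__(self):
        t = np.asarray(self.tokens)
        if t.ndim != 2:
            raise MsaParseError("token matrix must be 2-D")
        if t.min() < 0 or t.max() >= len(self.vocab):
            raise AlphabetError("token id outside the vocabulary")
        object.__setattr__(self, "tokens", t.astype(np.int64))

    @property
    def r(self) -> int:
        return self.tokens.shape[0]

    @property
    def c(self) -> int:
        return self.tokens.shape[1]


def _clean_a3m_row(raw: str, row_index: int) -> str:
    """Remove A3M insertion characters and coerce non-standard residues.

    Lowercase letters (insertions relative to the query) and '.' are dropped;
    '-' is retained as an ordinary column.
    """
    kept = []
    for ch in raw:
        if ch == "." or ch.islower():
            continue
        if ch in NONSTANDARD:
            logger.warning(
                "row %d: non-standard residue %r mapped to 'X'", row_index, ch
            )
            kept.append("X")
        elif ch in TOKEN_TO_ID:
            kept.append(ch)
        else:
            raise AlphabetError(
                f"illegal symbol {ch!r} in row {row_index}"
            )
    return "".join(kept)


def _parse_fasta_records(text: str):
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].strip() or "unnamed"
            chunks = []
        else:
            if header is None:
                raise MsaParseError("sequence data before the first '>' header")
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_a3m(path) -> Msa:
    """Parse an A3M (or aligned FASTA) file into an :class:`Msa`.

    The first record is the query; every other row must align to the query's
    column count after lowercase/'.' removal.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise MsaParseError(f"cannot read alignment file {path}: {exc}") from exc
    headers, rows = [], []
    for i, (header, seq) in enumerate(_parse_fasta_records(text)):
        headers.append(header)
        rows.append(_clean_a3m_row(seq, i))
    if not rows:
        raise MsaParseError(f"no sequence records in {path}")
    c = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != c:
            raise MalformedAlignmentError(
                f"row {i} ({headers[i]!r}) has {len(row)} aligned columns, "
                f"expected {c} (query length)"
            )
    return Msa(sequences=tuple(rows), headers=tuple(headers))


# Aligned FASTA has no insertion states, so the same reader applies.
read_aligned_fasta = read_a3m


def write_aligned_fasta(msa: Msa, path) -> None:
    """Write the alignment as uppercase aligned FASTA (gaps as '-')."""
    with open(path, "w") as fh:
        for header, seq in zip(msa.headers, msa.sequences):
            fh.write(f">{header}\n{seq}\n")


def tokenize(msa: Msa) -> TokenizedMsa:
    """Encode the alignment with the package's fixed vocabulary."""
    table = np.full(128, -1, dtype=np.int64)
    for s, i in TOKEN_TO_ID.items():
        table[ord(s)] = i
    rows = np.frombuffer(
        "".join(msa.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(msa.r, msa.c)
    return TokenizedMsa(tokens=table[rows])


def detokenize(tok: TokenizedMsa) -> Msa:
    """Inverse of :func:`tokenize`; exact round trip."""
    rows = tuple(
        "".join(tok.vocab[i] for i in row) for row in tok.tokens
    )
    return Msa(sequences=rows)
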