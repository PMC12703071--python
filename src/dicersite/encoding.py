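"""3-mer tokenization and input-stream assembly.

Sequences and dot-bracket structures are tokenized into overlapping 3-mers.
The last two positions cannot form a complete 3-mer, so they are completed
with placeholder symbols ("<PH>"): a string of length n always yields
exactly n tokens.  Over the RNA alphabet this produces a vocabulary of
4^3 + 4^2 + 4 = 84 tokens; over the structure alphabet {(, ), .} it gives
3^3 + 3^2 + 3 = 39.  Token id 0 is reserved for padding and is not counted
in the vocabulary size.

Each token is embedded into a 32-dimensional vector; per position the
sequence embedding is concatenated with the structure embedding (d_model
= 64) and a sinusoidal positional encoding is added.  Full hairpins are
padded to a fixed length with an invalidity mask; fixed-size patterns need
no padding.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np

from .io_formats import ValidationError

__all__ = [
    "PLACEHOLDER",
    "Vocabulary",
    "TokenSequence",
    "FeatureTensor",
    "tokenize_3mer",
    "detokenize",
    "build_vocab",
    "sinusoidal_pe",
    "assemble_stream",
]

PLACEHOLDER = "<PH>"

_ALPHABETS = {"sequence": "ACGU", "structure": "()."}

#: Default per-token embedding width; the joint per-position width is twice this.
EMBED_DIM = 32


@dataclasses.dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> id map for one input kind; id 0 is padding."""

    kind: str
    tokens: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValidationError("duplicate tokens in vocabulary")

    @property
    def size(self) -> int:
        """Number of real tokens (padding id excluded)."""
        return len(self.tokens)

    def token_to_id(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise ValidationError(f"token {token!r} not in {self.kind} vocabulary")

    @property
    def _index(self) -> dict[str, int]:
        # ids start at 1; 0 is the pad id
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {t: i + 1 for i, t in enumerate(self.tokens)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def encode(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.token_to_id(t) for t in tokens], dtype=np.int64)

    def decode_id(self, token_id: int) -> str:
        return self.tokens[token_id - 1]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"kind": self.kind, "tokens": list(self.tokens)}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], tokens=tuple(d["tokens"]))


@dataclasses.dataclass(frozen=True)
class TokenSequence:
    """Token ids for one string; always as many tokens as characters."""

    ids: np.ndarray
    length: int

    def __post_init__(self):
        if len(self.ids) != self.length:
            raise ValidationError("token count must equal original length")


@dataclasses.dataclass
class FeatureTensor:
    """Per-position features [positions x d_model] with a validity mask."""

    values: np.ndarray
    mask: np.ndarray  # bool, True = real position

    def __post_init__(self):
        if self.values.shape[0] != self.mask.shape[0]:
            raise ValidationError("values and mask disagree on position count")


def tokenize_3mer(text: str, kind: str) -> list[str]:
    """Split ``text`` into overlapping 3-mers with placeholder completion."""
    alphabet = _alphabet(kind)
    for pos, ch in enumerate(text):
        if ch not in alphabet:
            raise ValidationError(
                f"character {ch!r} at position {pos} outside {kind} alphabet")
    n = len(text)
    if n == 0:
        raise ValidationError("cannot tokenize an empty string")
    tokens = [text[i:i + 3] for i in range(max(n - 2, 0))]
    if n >= 2:
        tokens.append(text[n - 2:] + PLACEHOLDER)
    tokens.append(text[n - 1:] + PLACEHOLDER + PLACEHOLDER)
    return tokens


def detokenize(tokens: list[str]) -> str:
    """Invert :func:`tokenize_3mer` (first character of each token)."""
    return "".join(t[0] for t in tokens)


def _alphabet(kind: str) -> str:
    try:
        return _ALPHABETS[kind]
    except KeyError:
        raise ValidationError(f"unknown kind {kind!r}; expected sequence|structure")


def build_vocab(kind: str) -> Vocabulary:
    """Enumerate every token the 3-mer scheme can produce, in lexicographic
    order: all full 3-mers, then all 2-mers + one placeholder, then all
    single characters + two placeholders."""
    alphabet = sorted(_alphabet(kind))
    tokens = ["".join(t) for t in itertools.product(alphabet, repeat=3)]
    tokens += ["".join(t) + PLACEHOLDER for t in itertools.product(alphabet, repeat=2)]
    tokens += [c + PLACEHOLDER + PLACEHOLDER for c in alphabet]
    return Vocabulary(kind=kind, tokens=tuple(tokens))


def sinusoidal_pe(length: int, dim: int) -> np.ndarray:
    """Standard sinusoidal positional encoding (positions start at 0)."""
    if dim % 2 != 0:
        raise ValidationError(f"positional-encoding dim must be even, got {dim}")
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(dim // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / dim)
    pe = np.empty((length, dim), dtype=np.float32)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def assemble_stream(seq_ids: np.ndarray, struct_ids: np.ndarray,
                    seq_embedding: np.ndarray, struct_embedding: np.ndarray,
                    pad_to: int | None = None) -> FeatureTensor:
    """Build one model input stream from token ids and embedding tables.

    Per position the sequence embedding (row ``seq_ids[i]``) is concatenated
    with the structure embedding and the sinusoidal positional encoding is
    added.  With ``pad_to`` set, positions beyond the original length are
    zero vectors flagged invalid; the positional encoding is not added
    there, so the result is independent of the pad length.
    """
    seq_ids = np.asarray(seq_ids)
    struct_ids = np.asarray(struct_ids)
    if seq_ids.shape != struct_ids.shape:
        raise ValidationError(
            f"sequence/structure token length mismatch: "
            f"{seq_ids.shape} vs {struct_ids.shape}")
    n = len(seq_ids)
    total = n if pad_to is None else pad_to
    if n > total:
        raise ValidationError(f"length {n} exceeds pad_to={pad_to}")
    d_model = seq_embedding.shape[1] + struct_embedding.shape[1]
    values = np.zeros((total, d_model), dtype=np.float32)
    joint = np.concatenate(
        [seq_embedding[seq_ids], struct_embedding[struct_ids]], axis=1)
    values[:n] = joint + sinusoidal_pe(total, d_model)[:n]
    mask = np.zeros(total, dtype=bool)
    mask[:n] = True
    return FeatureTensor(values=values, mask=mask)
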