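"""Character-level tokenization and the pluggable embedding contract.

The ensemble's diversity mechanism is different input representations per
member.  Here each member owns an independently seeded trainable character
embedding table (optionally with a different dimension); the contract —
text in, an L x dim real matrix out — also admits external pre-trained
encoders, but none is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD_ID = 0
UNK_ID = 1


@dataclass(frozen=True)
class Vocabulary:
    """Character-to-id map with reserved PAD (0) and UNK (1) ids."""

    token_to_id: dict[str, int]

    def __post_init__(self) -> None:
        ids = sorted(self.token_to_id.values())
        if ids != list(range(2, 2 + len(ids))):
            raise ValueError("character ids must be dense starting at 2")

    @property
    def size(self) -> int:
        """Total table size including PAD and UNK."""
        return len(self.token_to_id) + 2

    def id_of(self, char: str) -> int:
        return self.token_to_id.get(char, UNK_ID)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(self.token_to_id, ensure_ascii=False), encoding="utf-8"
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))


def build_vocabulary(texts: Iterable[str]) -> Vocabulary:
    """Build a character vocabulary from training-split texts.

    Ids are assigned by first occurrence (ties cannot arise), so two calls
    on the same text sequence give identical assignments.  Characters unseen
    in training tokenize to UNK.
    """
    token_to_id: dict[str, int] = {}
    next_id = 2
    empty = True
    for text in texts:
        empty = False
        for ch in text:
            if ch not in token_to_id:
                token_to_id[ch] = next_id
                next_id += 1
    if empty:
        raise ValueError("cannot build a vocabulary from an empty training set")
    return Vocabulary(token_to_id)


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length id sequence with a binary mask of real positions."""

    ids: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.ids.shape != self.mask.shape:
            raise ValueError("ids and mask must share shape")
        if np.any((self.mask == 0) & (self.ids != PAD_ID)):
            raise ValueError("masked-out positions must hold the PAD id")
        if not self.mask.any():
            raise ValueError("a token sequence needs at least one real position")


def tokenize(text: str, vocab: Vocabulary, max_length: int) -> TokenSequence:
    """Map a unicode string to a fixed-length TokenSequence.

    Truncation keeps the left edge (the first ``max_length`` characters);
    shorter texts are right-padded with PAD.  Empty text yields a single
    UNK position so tokenization is total.
    """
    if max_length < 5:
        raise ValueError("max_length must be >= 5 (largest convolution kernel)")
    chars = list(text[:max_length])
    ids = np.full(max_length, PAD_ID, dtype=np.int64)
    mask = np.zeros(max_length, dtype=np.int64)
    if not chars:
        ids[0] = UNK_ID
        mask[0] = 1
        return TokenSequence(ids=ids, mask=mask)
    for i, ch in enumerate(chars):
        ids[i] = vocab.id_of(ch)
        mask[i] = 1
    return TokenSequence(ids=ids, mask=mask)


def tokenize_batch(
    texts: Sequence[str], vocab: Vocabulary, max_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-text TokenSequences into (ids, mask) arrays of shape B x L."""
    seqs = [tokenize(t, vocab, max_length) for t in texts]
    return np.stack([s.ids for s in seqs]), np.stack([s.mask for s in seqs])


@dataclass(frozen=True)
class EncoderConfig:
    """Shape and identity of one member's character encoder.

    ``encoder_id`` names the variant; its hash seeds the embedding init so
    distinct members start from distinct representations.
    """

    embedding_dim: int = 16
    max_length: int = 64
    encoder_id: str = "char-emb-0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")
        if self.max_length < 5:
            raise ValueError("max_length must be >= 5 (largest kernel width)")


def init_embedding(vocab: Vocabulary, config: EncoderConfig) -> np.ndarray:
    """Seeded Gaussian init of the embedding table; the PAD row is zero.

    The PAD row stays frozen at zero throughout training (the training loop
    zeroes its gradient), so padded positions contribute nothing.
    """
    rng = np.random.default_rng(config.seed)
    table = rng.normal(0.0, 0.1, size=(vocab.size, config.embedding_dim))
    table[PAD_ID] = 0.0
    return table


def embed(tokens: TokenSequence, table: np.ndarray) -> np.ndarray:
    """Look up token embeddings: row i is the embedding of position i's id."""
    if tokens.ids.max() >= table.shape[0]:
        raise ValueError("token id outside embedding table")
    return table[tokens.ids]
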