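"""Corpus data model, I/O, diagnostics, and synthetic imbalanced corpora.

A corpus is a flat list of :class:`LabeledText` records governed by a
:class:`CategorySchema`.  Labels live on disk as strings and in memory as
dense integer indices; index assignment is by lexicographic sort of the
distinct label names, so the mapping is reproducible without a side-channel
schema file.

The synthetic generator emulates the structure of clinical eligibility
criteria corpora: many categories, a Zipf-like long-tailed class-size
distribution, short unsegmented character sequences built from
class-indicative pseudo-tokens mixed with shared noise tokens.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SPLITS = ("train", "valid", "test")


@dataclass(frozen=True)
class LabeledText:
    """One corpus record: a short text, its category index, and split tag."""

    text: str
    label: int
    split: str = "train"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("text must be non-empty after stripping whitespace")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        if self.label < 0:
            raise ValueError("label index must be non-negative")


@dataclass(frozen=True)
class CategorySchema:
    """Ordered, unique category names; index of a name is stable for a run."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("category names must be unique")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "CategorySchema":
        return cls(tuple(sorted(set(labels))))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic imbalanced-corpus generator.

    ``imbalance_exponent`` is the Zipf exponent over class sizes: the
    expected size of class k is proportional to ``(k+1)**-exponent``
    (0 gives a balanced corpus).  Each text is a space-free concatenation
    of multi-character pseudo-tokens; a token is drawn from the shared
    noise pool with probability ``noise_rate``, otherwise from the class's
    private vocabulary.  With ``noise_rate=0`` the private vocabularies are
    disjoint, so the corpus is perfectly separable by construction.
    """

    n_classes: int = 8
    total_samples: int = 2000
    imbalance_exponent: float = 1.5
    class_vocab_size: int = 20
    shared_vocab_size: int = 50
    noise_rate: float = 0.3
    length_range: tuple[int, int] = (4, 12)
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.total_samples < 1:
            raise ValueError("total_samples must be positive")
        if self.imbalance_exponent < 0:
            raise ValueError("imbalance_exponent must be non-negative")
        if self.class_vocab_size < 1 or self.shared_vocab_size < 1:
            raise ValueError("vocabulary sizes must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")

    def zipf_weights(self) -> np.ndarray:
        """Normalized expected class proportions, largest class first."""
        ranks = np.arange(1, self.n_classes + 1, dtype=float)
        w = ranks ** (-self.imbalance_exponent)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_TSV_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_TSV_UNESCAPES = {"\\\\": "\\", "\\t": "\t", "\\n": "\n", "\\r": "\r"}


def _tsv_escape(s: str) -> str:
    for raw, esc in _TSV_ESCAPES.items():
        s = s.replace(raw, esc)
    return s


def _tsv_unescape(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s) and s[i : i + 2] in _TSV_UNESCAPES:
            out.append(_TSV_UNESCAPES[s[i : i + 2]])
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


class CorpusFormatError(ValueError):
    """Malformed corpus file or record."""


def read_corpus(
    path: str | Path, format: str = "jsonl"
) -> tuple[list[LabeledText], CategorySchema]:
    """Read a labeled corpus from TSV or JSON-lines.

    Label strings are mapped to dense indices via a schema built from the
    sorted distinct labels in the file.  A missing split tag defaults to
    ``train``.  Raises :class:`CorpusFormatError` with the offending line
    number for records missing text or label.
    """
    path = Path(path)
    if format not in ("tsv", "jsonl"):
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'jsonl'")
    raw: list[tuple[str, str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if format == "tsv":
                cols = line.split("\t")
                if len(cols) < 2:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: expected text<TAB>label[<TAB>split]"
                    )
                text = _tsv_unescape(cols[0])
                label = cols[1]
                split = cols[2] if len(cols) > 2 and cols[2] else "train"
            else:
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}:{lineno}: invalid JSON") from exc
                if "text" not in obj or "label" not in obj:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: record needs 'text' and 'label'"
                    )
                text, label = obj["text"], str(obj["label"])
                split = obj.get("split") or "train"
            if not text.strip():
                raise CorpusFormatError(f"{path}:{lineno}: empty text field")
            raw.append((text, label, split))
    if not raw:
        logger.warning("read empty corpus from %s", path)
        return [], CategorySchema(())
    schema = CategorySchema.from_labels(lbl for _, lbl, _ in raw)
    records = [
        LabeledText(text=t, label=schema.index(lbl), split=s) for t, lbl, s in raw
    ]
    return records, schema


def write_corpus(
    records: Sequence[LabeledText],
    schema: CategorySchema,
    path: str | Path,
    format: str = "jsonl",
) -> Path:
    """Write records to TSV or JSON-lines so that ``read_corpus`` round-trips.

    In TSV output, backslash, tab, newline and carriage return inside text
    are backslash-escaped; ``read_corpus`` reverses the escaping.
    """
    path = Path(path)
    if format not in ("tsv", "jsonl"):
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'jsonl'")
    for rec in records:
        if rec.label >= schema.n:
            raise ValueError(f"label {rec.label} outside schema of {schema.n} classes")
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            name = schema.names[rec.label]
            if format == "tsv":
                fh.write(f"{_tsv_escape(rec.text)}\t{name}\t{rec.split}\n")
            else:
                fh.write(
                    json.dumps(
                        {"text": rec.text, "label": name, "split": rec.split},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    return path


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def class_distribution(
    records: Sequence[LabeledText], schema: CategorySchema
) -> np.ndarray:
    """Per-class record counts (zero-count classes included)."""
    counts = np.zeros(schema.n, dtype=int)
    for rec in records:
        counts[rec.label] += 1
    return counts


def split_records(
    records: Sequence[LabeledText], split: str
) -> list[LabeledText]:
    if split not in SPLITS:
        raise ValueError(f"unknown split {split!r}")
    return [r for r in records if r.split == split]


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

# 40 CJK ideographs used as the character alphabet for pseudo-tokens.
_ALPHABET = [chr(0x4E00 + i) for i in range(40)]
_TOKEN_CHARS = 3


def _token_string(token_id: int) -> str:
    """Deterministic 3-character string for a global token id."""
    base = len(_ALPHABET)
    chars = []
    for _ in range(_TOKEN_CHARS):
        chars.append(_ALPHABET[token_id % base])
        token_id //= base
    return "".join(chars)


def class_private_tokens(spec: SyntheticSpec, k: int) -> list[str]:
    """The private pseudo-token vocabulary of class k (disjoint across classes)."""
    start = spec.shared_vocab_size + k * spec.class_vocab_size
    return [_token_string(i) for i in range(start, start + spec.class_vocab_size)]


def shared_tokens(spec: SyntheticSpec) -> list[str]:
    return [_token_string(i) for i in range(spec.shared_vocab_size)]


def generate_synthetic_corpus(
    spec: SyntheticSpec,
) -> tuple[list[LabeledText], CategorySchema]:
    """Generate a synthetic imbalanced short-text corpus.

    Class sizes are one multinomial draw over the normalized Zipf weights.
    Texts are space-free concatenations of 3-character pseudo-tokens: each
    token comes from the shared noise pool with probability ``noise_rate``,
    otherwise from the class's private vocabulary.  Splits are stratified
    per class by the split fractions; classes with fewer than 3 records go
    entirely to train.  Deterministic for a fixed spec (including seed).
    """
    if spec.total_samples < spec.n_classes:
        raise ValueError("total_samples must be >= n_classes to stratify splits")
    rng = np.random.default_rng(spec.seed)
    weights = spec.zipf_weights()
    sizes = rng.multinomial(spec.total_samples, weights)

    names = tuple(f"C{k:02d}" for k in range(spec.n_classes))
    schema = CategorySchema(names)
    shared = shared_tokens(spec)
    lo, hi = spec.length_range

    records: list[LabeledText] = []
    for k in range(spec.n_classes):
        private = class_private_tokens(spec, k)
        n_k = int(sizes[k])
        lengths = rng.integers(lo, hi + 1, size=n_k)
        class_records = []
        for length in lengths:
            use_shared = rng.random(length) < spec.noise_rate
            toks = [
                shared[rng.integers(len(shared))]
                if s
                else private[rng.integers(len(private))]
                for s in use_shared
            ]
            class_records.append("".join(toks))
        for text, split in zip(
            class_records, _stratified_splits(n_k, spec.split_fractions, rng)
        ):
            records.append(LabeledText(text=text, label=k, split=split))
    return records, schema


def _stratified_splits(
    n_k: int, fractions: tuple[float, float, float], rng: np.random.Generator
) -> list[str]:
    """Assign n_k records of one class to splits by a shuffled partition."""
    if n_k == 0:
        return []
    if n_k < 3:
        return ["train"] * n_k
    n_valid = int(round(n_k * fractions[1]))
    n_test = int(round(n_k * fractions[2]))
    n_train = n_k - n_valid - n_test
    if n_train < 1:  # tiny classes keep at least one training record
        n_train, n_valid = 1, max(0, n_valid - 1)
        n_test = n_k - n_train - n_valid
    tags = ["train"] * n_train + ["valid"] * n_valid + ["test"] * n_test
    perm = rng.permutation(n_k)
    out = [""] * n_k
    for pos, tag in zip(perm, tags):
        out[pos] = tag
    return out


def subsample_training_set(
    records: Sequence[LabeledText], fraction: float, seed: int
) -> list[LabeledText]:
    """Uniformly subsample the training split without replacement.

    Validation and test splits pass through untouched.  Emits a warning if
    a class vanishes from the reduced training split.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    train = [r for r in records if r.split == "train"]
    rest = [r for r in records if r.split != "train"]
    if fraction == 1.0:
        return list(records)
    rng = np.random.default_rng(seed)
    keep = int(round(len(train) * fraction))
    idx = rng.choice(len(train), size=keep, replace=False)
    kept = [train[i] for i in sorted(idx)]
    lost = {r.label for r in train} - {r.label for r in kept}
    if lost:
        logger.warning("classes %s vanished from the training split", sorted(lost))
    return kept + rest
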