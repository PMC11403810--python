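"""Byte-pair encoding with dropout regularization and offset tracking.

A :class:`BPEModel` stores only the base alphabet and the ordered list of
merge operations (rank 0 = highest priority); encoding applies merges
greedily by rank.  Dropout encoding vetoes each candidate merge
application independently with probability ``p``, producing a different
segmentation of the same text on every draw — the data-augmentation
effect used during training.  Inference always uses deterministic
encoding.

Character intervals into the source text are tracked for every subword so
entity spans can be decoded back to exact character offsets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import TagSequence, tokenize_words

PAD, UNK = "<pad>", "<unk>"


@dataclass
class BPEModel:
    alphabet: frozenset[str]
    merges: list[tuple[str, str]]
    specials: tuple[str, ...] = (PAD, UNK)
    ranks: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self):
        self.ranks = {pair: r for r, pair in enumerate(self.merges)}

    def vocabulary(self) -> list[str]:
        """Specials + alphabet + merge products, in deterministic order."""
        vocab = list(self.specials) + sorted(self.alphabet)
        seen = set(vocab)
        for a, b in self.merges:
            s = a + b
            if s not in seen:
                vocab.append(s)
                seen.add(s)
        return vocab

    def save_merges(self, path: str | Path) -> None:
        lines = [f"{a} {b}" for a, b in self.merges]
        alpha = " ".join(sorted(self.alphabet))
        Path(path).write_text(
            f"#alphabet {alpha}\n" + "\n".join(lines) + ("\n" if lines else ""),
            encoding="utf-8")

    @classmethod
    def load_merges(cls, path: str | Path) -> "BPEModel":
        alphabet: set[str] = set()
        merges: list[tuple[str, str]] = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line.startswith("#alphabet"):
                alphabet.update(line.split()[1:])
                continue
            if not line.strip():
                continue
            a, b = line.split(" ", 1)
            merges.append((a, b))
            alphabet.update(a + b)
        return cls(frozenset(alphabet), merges)


@dataclass
class SubwordSequence:
    tokens: list[str]
    intervals: list[tuple[int, int]]
    word_start_flags: list[bool]

    def __len__(self):
        return len(self.tokens)

    def restore(self, source: str) -> str:
        """Token strings spliced back between the original inter-token
        characters; equals ``source`` iff the segmentation is valid."""
        if not self.tokens:
            return source
        out, prev_end = [source[:self.intervals[0][0]]], None
        for tok, (a, b) in zip(self.tokens, self.intervals):
            if prev_end is not None:
                out.append(source[prev_end:a])
            out.append(tok)
            prev_end = b
        out.append(source[prev_end:])
        return "".join(out)


@dataclass(frozen=True)
class DropoutConfig:
    p: float
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"dropout probability {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# learning
# ---------------------------------------------------------------------------

def learn_bpe(corpus: Iterable[str], num_merges: int) -> BPEModel:
    """Learn merge operations by greedy pair-frequency counting.

    Ties are broken lexicographically so learning is deterministic for a
    given corpus order.
    """
    word_freq: Counter[tuple[str, ...]] = Counter()
    alphabet: set[str] = set()
    n_sent = 0
    for sent in corpus:
        n_sent += 1
        for a, b in tokenize_words(sent):
            word = sent[a:b]
            word_freq[tuple(word)] += 1
            alphabet.update(word)
    if n_sent == 0:
        raise ValueError("cannot learn BPE from an empty corpus")

    merges: list[tuple[str, str]] = []
    words = dict(word_freq)
    for _ in range(num_merges):
        pair_freq: Counter[tuple[str, str]] = Counter()
        for sym, freq in words.items():
            for p in zip(sym[:-1], sym[1:]):
                pair_freq[p] += freq
        if not pair_freq:
            break
        best = min(pair_freq.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        merges.append(best)
        merged: dict[tuple[str, ...], int] = {}
        for sym, freq in words.items():
            sym = _merge_symbols(list(sym), best)
            merged[tuple(sym)] = merged.get(tuple(sym), 0) + freq
        words = merged
    return BPEModel(frozenset(alphabet), merges)


def _merge_symbols(symbols: list[str], pair: tuple[str, str]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(symbols):
        if i + 1 < len(symbols) and (symbols[i], symbols[i + 1]) == pair:
            out.append(symbols[i] + symbols[i + 1])
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return out


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _encode_word(word: str, model: BPEModel,
                 rng: np.random.Generator | None, p: float
                 ) -> list[tuple[str, int, int]]:
    """Encode one word; returns (token, local_start, local_end) triples.

    Each iteration gathers all candidate merge positions, independently
    vetoes each with probability ``p`` (the BPE-dropout rule), and applies
    the surviving merge of best rank (leftmost on ties); dropped merges
    may re-enter at later iterations.  Out-of-alphabet characters remain
    single-character tokens, preserving the concatenation invariant.
    """
    syms = list(word)
    bounds = list(range(len(word) + 1))  # len(syms)+1 cut points
    while len(syms) > 1:
        candidates = [(model.ranks[(syms[i], syms[i + 1])], i)
                      for i in range(len(syms) - 1)
                      if (syms[i], syms[i + 1]) in model.ranks]
        if not candidates:
            break
        if p > 0.0 and rng is not None:
            keep = rng.random(len(candidates)) >= p
            candidates = [c for c, k in zip(candidates, keep) if k]
            if not candidates:
                break
        _, i = min(candidates)
        syms[i:i + 2] = [syms[i] + syms[i + 1]]
        del bounds[i + 1]
    return [(s, bounds[i], bounds[i + 1]) for i, s in enumerate(syms)]


def encode(text: str, model: BPEModel) -> SubwordSequence:
    """Deterministic BPE encoding with character intervals."""
    return _encode_impl(text, model, rng=None, p=0.0)


def encode_dropout(text: str, model: BPEModel, cfg: DropoutConfig,
                   rng: np.random.Generator | None = None) -> SubwordSequence:
    """BPE-dropout encoding; reproducible given ``cfg.rng_seed`` (or an
    externally supplied generator, for use inside a training loop)."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    return _encode_impl(text, model, rng=rng, p=cfg.p)


def _encode_impl(text: str, model: BPEModel,
                 rng: np.random.Generator | None, p: float) -> SubwordSequence:
    tokens: list[str] = []
    intervals: list[tuple[int, int]] = []
    flags: list[bool] = []
    for ws, we in tokenize_words(text):
        pieces = _encode_word(text[ws:we], model, rng, p)
        for j, (tok, a, b) in enumerate(pieces):
            tokens.append(tok)
            intervals.append((ws + a, ws + b))
            flags.append(j == 0)
    return SubwordSequence(tokens, intervals, flags)


# ---------------------------------------------------------------------------
# label alignment
# ---------------------------------------------------------------------------

def align_labels(subwords: SubwordSequence, tags: TagSequence,
                 supervise_continuations: bool = False
                 ) -> tuple[list[str], list[int]]:
    """Project word-level BIO tags onto a subword sequence.

    The first subword of each word carries the word's tag (supervised);
    continuation subwords carry ``I-<label>`` inside entities and ``O``
    outside.  Continuations are masked out of the loss unless
    ``supervise_continuations``.  Decoding reads only word-start subwords.
    """
    word_intervals = [(a, b) for (a, b), f
                      in zip(subwords.intervals, subwords.word_start_flags) if f]
    # word k of the subword sequence must sit inside word k of the tags
    if len(word_intervals) != len(tags.tags):
        raise ValueError(
            f"word count mismatch: {len(word_intervals)} subword words vs "
            f"{len(tags.tags)} tags")
    for (a, _), (ta, tb) in zip(word_intervals, tags.intervals):
        if not (ta <= a < tb):
            raise ValueError(f"subword interval ({a},..) outside word ({ta},{tb})")

    out_tags: list[str] = []
    mask: list[int] = []
    word_idx = -1
    for flag in subwords.word_start_flags:
        if flag:
            word_idx += 1
            out_tags.append(tags.tags[word_idx])
            mask.append(1)
        else:
            word_tag = tags.tags[word_idx]
            cont = "I-" + word_tag[2:] if word_tag != "O" else "O"
            out_tags.append(cont)
            mask.append(1 if supervise_continuations else 0)
    return out_tags, mask


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class BPETokenizer(BaseEstimator):
    """sklearn-style wrapper: ``fit`` learns merges, ``transform`` encodes.

    Parameters
    ----------
    num_merges : number of merge operations to learn.
    dropout : merge-veto probability used by :meth:`transform_dropout`.
    """

    def __init__(self, num_merges: int = 200, dropout: float = 0.1):
        self.num_merges = num_merges
        self.dropout = dropout

    def fit(self, X: Sequence[str], y=None) -> "BPETokenizer":
        self.model_ = learn_bpe(X, self.num_merges)
        return self

    def transform(self, X: Sequence[str]) -> list[SubwordSequence]:
        return [encode(t, self.model_) for t in X]

    def transform_dropout(self, X: Sequence[str], seed: int = 0
                          ) -> list[SubwordSequence]:
        rng = np.random.default_rng(seed)
        return [encode_dropout(t, self.model_,
                               DropoutConfig(self.dropout), rng=rng) for t in X]
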