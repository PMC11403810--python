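"""Documents, standoff annotations, sentence segmentation and BIO codec.

Conventions (BRAT / SympTEMIST style):

* character offsets are 0-based, end-exclusive;
* standoff files are UTF-8 TSV with header
  ``filename\tlabel\tstart_span\tend_span\ttext``;
* the default entity label is ``SINTOMA``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STANDOFF_COLUMNS = ["filename", "label", "start_span", "end_span", "text"]
DEFAULT_LABEL = "SINTOMA"


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A labelled character interval inside a document."""

    doc_id: str
    start: int
    end: int
    label: str = DEFAULT_LABEL
    text: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) in doc {self.doc_id!r}"
            )

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Identity used for strict matching and ensemble voting."""
        return (self.doc_id, self.start, self.end, self.label)

    def overlaps(self, other: "EntitySpan") -> bool:
        return (self.doc_id == other.doc_id
                and self.start < other.end and other.start < self.end)


@dataclass
class Document:
    doc_id: str
    text: str
    spans: list[EntitySpan] = field(default_factory=list)

    def validate(self) -> None:
        for sp in self.spans:
            if sp.end > len(self.text):
                raise ValueError(f"span {sp} exceeds document {self.doc_id!r}")
            if sp.text and self.text[sp.start:sp.end] != sp.text:
                raise ValueError(
                    f"span text mismatch in {self.doc_id!r}: "
                    f"{self.text[sp.start:sp.end]!r} != {sp.text!r}"
                )


@dataclass
class Sentence:
    """A sentence slice of a document; spans use sentence-local offsets."""

    doc_id: str
    start: int
    end: int
    text: str
    spans: list[EntitySpan] = field(default_factory=list)

    def absolute_spans(self) -> list[EntitySpan]:
        """Spans re-based to document offsets."""
        return [replace(sp, start=sp.start + self.start, end=sp.end + self.start)
                for sp in self.spans]


@dataclass
class TagSequence:
    """BIO tags with per-tag character intervals (local offsets)."""

    tags: list[str]
    intervals: list[tuple[int, int]]

    def __post_init__(self):
        if len(self.tags) != len(self.intervals):
            raise ValueError("tags and intervals length mismatch")

    def is_valid_bio(self) -> bool:
        prev = "O"
        for tag in self.tags:
            if tag.startswith("I-"):
                lab = tag[2:]
                if prev == "O" or (prev != "O" and prev[2:] != lab):
                    return False
            prev = tag
        return True


# ---------------------------------------------------------------------------
# standoff I/O
# ---------------------------------------------------------------------------

def read_standoff(ann_table: str | Path | io.TextIOBase,
                  documents: Mapping[str, str]) -> list[Document]:
    """Parse a SympTEMIST-style standoff TSV against a doc_id->text map.

    Every row is validated against the substring invariant; violations
    raise with the offending doc_id and row index rather than being
    silently repaired.
    """
    if isinstance(ann_table, (str, Path)) and "\t" not in str(ann_table):
        df = pd.read_csv(ann_table, sep="\t", dtype=str, keep_default_na=False)
    else:
        buf = ann_table if isinstance(ann_table, io.TextIOBase) else io.StringIO(str(ann_table))
        df = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in STANDOFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"standoff table missing columns {missing}")

    docs = {doc_id: Document(doc_id, text) for doc_id, text in documents.items()}
    for i, row in enumerate(df.itertuples(index=False)):
        doc_id = row.filename
        if doc_id not in docs:
            raise ValueError(f"row {i}: unknown doc_id {doc_id!r}")
        start, end = int(row.start_span), int(row.end_span)
        text = docs[doc_id].text
        if not (0 <= start < end <= len(text)):
            raise ValueError(f"row {i}: offsets [{start},{end}) outside doc {doc_id!r}")
        if text[start:end] != row.text:
            raise ValueError(
                f"row {i}: doc {doc_id!r} substring {text[start:end]!r} != {row.text!r}"
            )
        docs[doc_id].spans.append(
            EntitySpan(doc_id, start, end, row.label, row.text))
    return list(docs.values())


def write_standoff(documents: Iterable[Document] | Iterable[EntitySpan],
                   path: str | Path | None = None) -> str:
    """Serialise spans to the standoff TSV format; returns the text."""
    spans: list[EntitySpan] = []
    for item in documents:
        if isinstance(item, Document):
            spans.extend(item.spans)
        else:
            spans.append(item)
    rows = [(sp.doc_id, sp.label, sp.start, sp.end, sp.text)
            for sp in sorted(spans, key=lambda s: (s.doc_id, s.start, s.end))]
    df = pd.DataFrame(rows, columns=STANDOFF_COLUMNS)
    out = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(out, encoding="utf-8")
    return out


def load_corpus(directory: str | Path) -> list[Document]:
    """Load ``<dir>/*.txt`` plus a single ``*.tsv`` standoff table."""
    directory = Path(directory)
    texts = {p.stem: p.read_text(encoding="utf-8")
             for p in sorted(directory.glob("*.txt"))}
    tsvs = sorted(directory.glob("*.tsv"))
    if not tsvs:
        return [Document(d, t) for d, t in texts.items()]
    return read_standoff(tsvs[0], texts)


def save_corpus(documents: Sequence[Document], directory: str | Path,
                ann_name: str = "annotations.tsv") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in documents:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    write_standoff(documents, directory / ann_name)


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

_BOUNDARY_RE = re.compile(r"[.?!]+\s+")


def default_splitter(text: str) -> list[int]:
    """Rule-based boundary proposals: after sentence punctuation + space."""
    return [m.end() for m in _BOUNDARY_RE.finditer(text)]


def segment_sentences(doc: Document,
                      splitter: Callable[[str], list[int]] | None = None
                      ) -> list[Sentence]:
    """Split a document at proposed boundaries, never inside an entity.

    A proposed boundary that falls strictly inside any entity span is
    discarded, merging the two candidate sentences — labelled entities are
    never split.  Leading/trailing whitespace is trimmed off each sentence
    (the trimmed characters are the inter-sentence material).
    """
    splitter = splitter or default_splitter
    boundaries = sorted(set(b for b in splitter(doc.text) if 0 < b < len(doc.text)))
    boundaries = [b for b in boundaries
                  if not any(sp.start < b < sp.end for sp in doc.spans)]
    edges = [0] + boundaries + [len(doc.text)]

    sentences: list[Sentence] = []
    for seg_start, seg_end in zip(edges[:-1], edges[1:]):
        chunk = doc.text[seg_start:seg_end]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = seg_start + (len(chunk) - len(chunk.lstrip()))
        end = seg_end - (len(chunk) - len(chunk.rstrip()))
        local = [replace(sp, start=sp.start - start, end=sp.end - start)
                 for sp in doc.spans if start <= sp.start and sp.end <= end]
        sentences.append(Sentence(doc.doc_id, start, end, doc.text[start:end], local))
    return sentences


# ---------------------------------------------------------------------------
# word tokenization + BIO codec
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize_words(text: str) -> list[tuple[int, int]]:
    """Word/punctuation token intervals (whitespace discarded)."""
    return [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def bio_encode(sentence: Sentence,
               tokenization: Sequence[tuple[int, int]] | None = None
               ) -> TagSequence:
    """Character-offset spans -> per-token BIO tags.

    Raises when spans overlap (BIO cannot represent overlaps) or when an
    entity boundary falls strictly inside a token.
    """
    intervals = list(tokenization) if tokenization is not None \
        else tokenize_words(sentence.text)
    spans = sorted(sentence.spans, key=lambda s: s.start)
    for a, b in zip(spans[:-1], spans[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping spans [{a.start},{a.end}) and [{b.start},{b.end}) "
                f"in {sentence.doc_id!r}: BIO cannot represent overlaps")
    tags = ["O"] * len(intervals)
    for sp in spans:
        covered = []
        for i, (ts, te) in enumerate(intervals):
            if ts < sp.end and sp.start < te:  # overlap
                if ts < sp.start < te or ts < sp.end < te:
                    raise ValueError(
                        f"entity boundary [{sp.start},{sp.end}) inside token "
                        f"[{ts},{te}) in {sentence.doc_id!r}")
                covered.append(i)
        for j, i in enumerate(covered):
            tags[i] = ("B-" if j == 0 else "I-") + sp.label
    return TagSequence(tags, intervals)


def bio_decode(tags: TagSequence, text: str = "", doc_id: str = ""
               ) -> list[EntitySpan]:
    """Per-token BIO tags -> spans, tolerating invalid sequences.

    Orphan ``I-`` tags (after O, sequence start, or a different label) are
    promoted to ``B-`` — the recall-maximising repair.
    """
    spans: list[EntitySpan] = []
    cur_label, cur_start, cur_end = None, 0, 0
    for tag, (ts, te) in zip(tags.tags, tags.intervals):
        if tag == "O":
            kind, lab = "O", None
        else:
            kind, lab = tag[0], tag[2:]
        if kind == "I" and lab == cur_label:
            cur_end = te
            continue
        if cur_label is not None:
            spans.append(EntitySpan(doc_id, cur_start, cur_end, cur_label,
                                    text[cur_start:cur_end] if text else ""))
            cur_label = None
        if kind in ("B", "I"):  # orphan I opens a new span
            cur_label, cur_start, cur_end = lab, ts, te
    if cur_label is not None:
        spans.append(EntitySpan(doc_id, cur_start, cur_end, cur_label,
                                text[cur_start:cur_end] if text else ""))
    return spans


def write_conll(sentences: Sequence[Sentence], path: str | Path | None = None
                ) -> str:
    """Token<TAB>tag lines, blank line between sentences."""
    lines: list[str] = []
    for sent in sentences:
        ts = bio_encode(sent)
        for tag, (a, b) in zip(ts.tags, ts.intervals):
            lines.append(f"{sent.text[a:b]}\t{tag}")
        lines.append("")
    out = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(out, encoding="utf-8")
    return out


# ---------------------------------------------------------------------------
# dataset partition
# ---------------------------------------------------------------------------

def split_dataset(sentences: Sequence, sizes: tuple[int, int, int], seed: int
                  ) -> tuple[list, list, list]:
    """Deterministic disjoint (train, valid, test) partition."""
    n_train, n_valid, n_test = sizes
    if n_train + n_valid + n_test != len(sentences):
        raise ValueError(
            f"sizes {sizes} do not sum to {len(sentences)} sentences")
    order = np.random.default_rng(seed).permutation(len(sentences))
    items = [sentences[i] for i in order]
    return (items[:n_train],
            items[n_train:n_train + n_valid],
            items[n_train + n_valid:])
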