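"""Seeded synthetic clinical-note generator with controllable difficulty.

Emulates the shape of a symptom-NER corpus — short documents of a few
sentences, each sentence a run of distractor words into which multi-word
symptom phrases from a gazetteer are inserted as labelled spans — so the
whole stack is testable without any external download.  ``ambiguity_rate``
injects single gazetteer *tokens* as unlabelled distractor text, which
defeats context-free memorization: the model must use context and span
structure, which is exactly where the CRF and its transition bias earn
their keep.

``corrupt_predictions`` perturbs a gold standard into a prediction set
with known expected precision/recall, giving the evaluation module
inputs with analytically known behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Document, EntitySpan

DEFAULT_GAZETTEER = (
    "dolor torácico", "tos seca", "fiebre alta", "dolor abdominal",
    "cefalea intensa", "náuseas matutinas", "disnea de esfuerzo",
    "tos productiva", "fiebre intermitente", "dolor lumbar",
    "astenia marcada", "mareo postural", "palpitaciones frecuentes",
    "sudoración nocturna",
)

DEFAULT_DISTRACTORS = (
    "paciente", "varón", "mujer", "años", "acude", "consulta", "refiere",
    "presenta", "desde", "hace", "días", "semanas", "sin", "antecedentes",
    "interés", "exploración", "física", "normal", "analítica", "muestra",
    "valores", "dentro", "rango", "tratamiento", "domicilio", "control",
    "evolución", "favorable", "alta", "ingreso", "urgencias", "historia",
    "clínica", "durante", "episodio", "tras", "persiste", "mejoría",
)


@dataclass
class GenConfig:
    n_docs: int = 40
    sentences_per_doc: tuple[int, int] = (4, 8)   # uniform inclusive range
    gazetteer: tuple[str, ...] = DEFAULT_GAZETTEER
    distractors: tuple[str, ...] = DEFAULT_DISTRACTORS
    entity_rate: float = 0.6        # P(a sentence carries an entity)
    ambiguity_rate: float = 0.0     # P(sentence gets a bare gazetteer token)
    words_per_sentence: tuple[int, int] = (6, 12)
    label: str = "SINTOMA"
    seed: int = 0

    def __post_init__(self):
        for r in (self.entity_rate, self.ambiguity_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.entity_rate > 0 and not self.gazetteer:
            raise ValueError("entity_rate > 0 needs a non-empty gazetteer")
        if self.words_per_sentence[0] < 1:
            raise ValueError("sentences need at least one word")


def _make_sentence(cfg: GenConfig, rng: np.random.Generator
                   ) -> tuple[str, list[tuple[int, int, str]]]:
    """One sentence; returns text + (start, end, phrase) entity triples."""
    n_words = int(rng.integers(cfg.words_per_sentence[0],
                               cfg.words_per_sentence[1] + 1))
    words = [str(rng.choice(cfg.distractors)) for _ in range(n_words)]
    entity_here = rng.random() < cfg.entity_rate
    if rng.random() < cfg.ambiguity_rate and cfg.gazetteer:
        # a lone gazetteer token as plain text: memorization trap
        phrase = str(rng.choice(cfg.gazetteer))
        token = phrase.split()[int(rng.integers(len(phrase.split())))]
        words.insert(int(rng.integers(len(words) + 1)), token)
    spans: list[tuple[int, int, str]] = []
    if entity_here:
        phrase = str(rng.choice(cfg.gazetteer))
        pos = int(rng.integers(len(words) + 1))
        words.insert(pos, phrase)
        prefix = " ".join(words[:pos])
        start = len(prefix) + (1 if prefix else 0)
        spans.append((start, start + len(phrase), phrase))
    return " ".join(words), spans


def generate(cfg: GenConfig) -> list[Document]:
    """Deterministic document set; every span passes the substring
    invariant and sentences end with '.' so the default splitter fires."""
    rng = np.random.default_rng(cfg.seed)
    docs: list[Document] = []
    for d in range(cfg.n_docs):
        doc_id = f"syn{d:04d}"
        n_sent = int(rng.integers(cfg.sentences_per_doc[0],
                                  cfg.sentences_per_doc[1] + 1))
        parts: list[str] = []
        spans: list[EntitySpan] = []
        offset = 0
        for _ in range(n_sent):
            text, local = _make_sentence(cfg, rng)
            text = text + "."
            for a, b, phrase in local:
                spans.append(EntitySpan(doc_id, offset + a, offset + b,
                                        cfg.label, phrase))
            parts.append(text)
            offset += len(text) + 1  # joined by a single space
        doc = Document(doc_id, " ".join(parts), spans)
        doc.validate()
        docs.append(doc)
    return docs


def corrupt_predictions(gold: Sequence[EntitySpan],
                        documents: Mapping[str, str],
                        offset_noise: int = 0,
                        drop_rate: float = 0.0,
                        spurious_rate: float = 0.0,
                        seed: int = 0) -> list[EntitySpan]:
    """Perturb a gold standard into predictions with known expected P/R.

    * each gold span is dropped with probability ``drop_rate``
      (expected strict recall = 1 - drop_rate when noise is 0);
    * surviving spans get each endpoint shifted by a uniform draw in
      [-offset_noise, offset_noise], clamped so the span stays non-empty,
      inside the document, and overlapping its origin (o_F1 stays 1 when
      only noise is applied);
    * per gold span, with probability ``spurious_rate`` an extra random
      span over distractor text is added.
    """
    for r in (drop_rate, spurious_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate {r} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[EntitySpan] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for sp in gold:
        occupied.setdefault(sp.doc_id, []).append((sp.start, sp.end))
    for sp in gold:
        if rng.random() < drop_rate:
            continue
        start, end = sp.start, sp.end
        if offset_noise > 0:
            text = documents[sp.doc_id]
            width = end - start
            ds = int(rng.integers(-offset_noise, offset_noise + 1))
            de = int(rng.integers(-offset_noise, offset_noise + 1))
            start = int(np.clip(sp.start + ds, 0, sp.end - 1))
            end = int(np.clip(sp.end + de, start + 1, len(text)))
            if end <= sp.start:   # keep overlap with the origin
                end = sp.start + 1
        text_src = documents.get(sp.doc_id, "")
        out.append(EntitySpan(sp.doc_id, start, end, sp.label,
                              text_src[start:end] if text_src else ""))
        if rng.random() < spurious_rate:
            text = documents[sp.doc_id]
            for _ in range(20):  # rejection-sample a free interval
                a = int(rng.integers(0, max(len(text) - 5, 1)))
                b = min(a + int(rng.integers(3, 9)), len(text))
                if b <= a:
                    continue
                if not any(a < e and s < b for s, e in occupied[sp.doc_id]):
                    out.append(EntitySpan(sp.doc_id, a, b, sp.label, text[a:b]))
                    occupied[sp.doc_id].append((a, b))
                    break
    return out
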