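"""Majority-vote combination of span predictions from multiple models.

A span is emitted iff at least ``threshold`` member models predicted the
identical span (exact start, end, label in the same document); the
default threshold is a strict majority, floor(n/2)+1 — 2 of 3, 4 of 6,
7 of 12.  If surviving spans overlap, the span with more votes wins;
ties go to the longer span, then to the earlier start.  Voting operates
on plain span sets, so it works file-level on any systems' standoff
output as well as on in-memory predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sklearn.base import BaseEstimator

from .corpus import EntitySpan


@dataclass(frozen=True)
class VoteConfig:
    n_models: int
    threshold: int | None = None

    def __post_init__(self):
        t = self.effective_threshold
        if not 1 <= t <= self.n_models:
            raise ValueError(
                f"threshold {t} outside [1, {self.n_models}]")

    @property
    def effective_threshold(self) -> int:
        return (self.n_models // 2 + 1 if self.threshold is None
                else self.threshold)


def majority_vote(predictions: Sequence[Sequence[EntitySpan]],
                  cfg: VoteConfig | None = None) -> list[EntitySpan]:
    """Vote over per-model span sets (each inner sequence = one model)."""
    if not predictions:
        raise ValueError("no model predictions to vote over")
    cfg = cfg or VoteConfig(len(predictions))
    if cfg.n_models != len(predictions):
        raise ValueError(
            f"VoteConfig.n_models={cfg.n_models} but {len(predictions)} "
            "prediction sets were given")
    votes: dict[tuple, int] = {}
    rep: dict[tuple, EntitySpan] = {}
    for model_spans in predictions:
        for key in {sp.key for sp in model_spans}:  # de-dup within a model
            votes[key] = votes.get(key, 0) + 1
    for model_spans in predictions:
        for sp in model_spans:
            rep.setdefault(sp.key, sp)
    kept = [rep[k] for k, v in votes.items() if v >= cfg.effective_threshold]
    kept.sort(key=lambda s: (s.doc_id, s.start, s.end, s.label))
    return _resolve_overlaps(kept, votes)


def _resolve_overlaps(spans: list[EntitySpan], votes: dict[tuple, int]
                      ) -> list[EntitySpan]:
    """Keep higher-vote span; tie -> longer; tie -> earlier start."""
    order = sorted(spans, key=lambda s: (-votes[s.key],
                                         -(s.end - s.start), s.doc_id, s.start))
    chosen: list[EntitySpan] = []
    for sp in order:
        if not any(sp.overlaps(c) for c in chosen):
            chosen.append(sp)
    chosen.sort(key=lambda s: (s.doc_id, s.start, s.end, s.label))
    return chosen


def pool_configurations(model_groups: Sequence[Sequence[Sequence[EntitySpan]]]
                        ) -> list[list[EntitySpan]]:
    """Flatten groups of per-model predictions into one voter pool,
    preserving model identity (two groups of 3 -> 6 voters)."""
    if not model_groups:
        raise ValueError("no model groups")
    return [list(model) for group in model_groups for model in group]


class MajorityVoteEnsemble(BaseEstimator):
    """Estimator facade over fitted taggers: predict = vote over members."""

    def __init__(self, threshold: int | None = None):
        self.threshold = threshold

    def fit(self, X: Sequence, y=None) -> "MajorityVoteEnsemble":
        """X is a sequence of fitted models exposing ``predict``."""
        if not X:
            raise ValueError("ensemble needs at least one member model")
        self.members_ = list(X)
        return self

    def predict(self, X) -> list[EntitySpan]:
        per_model = [[sp for group in m.predict(X) for sp in group]
                     for m in self.members_]
        cfg = VoteConfig(len(self.members_), self.threshold)
        return majority_vote(per_model, cfg)
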