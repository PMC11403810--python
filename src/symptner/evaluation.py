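"""Entity-level strict and overlapping P/R/F1 plus multi-run aggregation.

Strict matching counts a prediction as true positive iff it matches a
gold span exactly on (doc, start, end, label).  Overlapping matching
(the ``o_``-prefixed scores) pairs predictions and gold spans of the
same document and label whose character intervals intersect, under a
one-to-one greedy maximal matching: candidate pairs are taken in order
of decreasing overlap length, ties broken by earlier gold start then
earlier pred start.  Both conventions define P=R=F1=1 when gold and
predictions are both empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus import EntitySpan


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    o_tp: int
    o_fp: int
    o_fn: int

    @staticmethod
    def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        if tp + fp + fn == 0:          # empty gold and empty predictions
            return 1.0, 1.0, 1.0
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    @property
    def precision(self):
        return self._prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self):
        return self._prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self):
        return self._prf(self.tp, self.fp, self.fn)[2]

    @property
    def o_precision(self):
        return self._prf(self.o_tp, self.o_fp, self.o_fn)[0]

    @property
    def o_recall(self):
        return self._prf(self.o_tp, self.o_fp, self.o_fn)[1]

    @property
    def o_f1(self):
        return self._prf(self.o_tp, self.o_fp, self.o_fn)[2]

    def as_dict(self) -> dict:
        return {"P": self.precision, "R": self.recall, "F1": self.f1,
                "o_P": self.o_precision, "o_R": self.o_recall,
                "o_F1": self.o_f1,
                "counts": {"strict": [self.tp, self.fp, self.fn],
                           "overlap": [self.o_tp, self.o_fp, self.o_fn]}}


def strict_counts(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
                  ) -> tuple[int, int, int]:
    """Exact (doc, start, end, label) matching; duplicates match 1:1."""
    from collections import Counter
    g = Counter(sp.key for sp in gold)
    p = Counter(sp.key for sp in pred)
    tp = sum((g & p).values())
    return tp, sum(p.values()) - tp, sum(g.values()) - tp


def overlap_counts(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
                   ) -> tuple[int, int, int]:
    """One-to-one maximum-cardinality matching on interval intersection.

    Spans are grouped by (document, label); within a group the matched
    count is the maximum bipartite matching of the overlap graph, so the
    counts never depend on greedy pairing order.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    groups: dict[tuple[str, str], tuple[list, list]] = {}
    for sp in gold:
        groups.setdefault((sp.doc_id, sp.label), ([], []))[0].append(sp)
    for sp in pred:
        groups.setdefault((sp.doc_id, sp.label), ([], []))[1].append(sp)
    tp = 0
    for (doc, lab), (gs, ps) in sorted(groups.items()):
        if not gs or not ps:
            continue
        gs = sorted(gs, key=lambda s: (s.start, s.end))
        ps = sorted(ps, key=lambda s: (s.start, s.end))
        adj = np.zeros((len(gs), len(ps)), dtype=np.int8)
        for gi, g in enumerate(gs):
            for pi, p in enumerate(ps):
                if min(g.end, p.end) > max(g.start, p.start):
                    adj[gi, pi] = 1
        match = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
        tp += int(np.sum(match >= 0))
    return tp, len(pred) - tp, len(gold) - tp


def evaluate(gold: Sequence[EntitySpan], pred: Sequence[EntitySpan]
             ) -> EvaluationReport:
    tp, fp, fn = strict_counts(gold, pred)
    otp, ofp, ofn = overlap_counts(gold, pred)
    return EvaluationReport(tp, fp, fn, otp, ofp, ofn)


def strict_metrics(gold, pred) -> dict:
    r = evaluate(gold, pred)
    return {"P": r.precision, "R": r.recall, "F1": r.f1}


def overlap_metrics(gold, pred) -> dict:
    r = evaluate(gold, pred)
    return {"o_P": r.o_precision, "o_R": r.o_recall, "o_F1": r.o_f1}


@dataclass
class RunAggregate:
    mean: float
    sd: float
    min: float
    max: float

    def __str__(self):
        return f"{self.mean:.2f} ±{self.sd:.2f}  [{self.min:.2f}, {self.max:.2f}]"


def aggregate_runs(values: Iterable[float]) -> RunAggregate:
    """Mean, sample SD (n-1 denominator; 0 for a single run), min, max."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no run values to aggregate")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RunAggregate(float(vals.mean()), sd, float(vals.min()), float(vals.max()))


def format_report(report: EvaluationReport) -> str:
    """Formatted line matching the shared-task column naming."""
    d = report.as_dict()
    head = "  ".join(f"{k:>6}" for k in ("P", "R", "F1", "o_P", "o_R", "o_F1"))
    row = "  ".join(f"{d[k]:6.4f}" for k in ("P", "R", "F1", "o_P", "o_R", "o_F1"))
    return head + "\n" + row
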