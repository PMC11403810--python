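"""End-to-end recipes: dataset assembly, the ablation ladder, ensembling.

These are the desk-scale reproduction drivers behind the CLI's
``reproduce-ablation`` command and the acceptance checks: generate a
synthetic corpus, segment and split it, train the configuration ladder
(softmax -> +BPE-dropout -> CRF -> +transition bias -> +SSW features)
over several seeds, and aggregate strict F1 as Mean (SD)/Min/Max rows.
"""

from __future__ import annotations

from typing import Sequence

from .corpus import EntitySpan, Sentence, segment_sentences, split_dataset
from .ensemble import majority_vote
from .evaluation import RunAggregate, aggregate_runs, evaluate
from .model import NERTagger
from .synthetic import GenConfig, generate

# ablation arms: name -> NERTagger overrides
ARMS: dict[str, dict] = {
    "softmax": {"head": "softmax", "crf_bias": False, "bpe_dropout": 0.0},
    "softmax_bped": {"head": "softmax", "crf_bias": False, "bpe_dropout": 0.1},
    "crf_bped": {"head": "crf", "crf_bias": False, "bpe_dropout": 0.1},
    "crf_bped_bias": {"head": "crf", "crf_bias": True, "bpe_dropout": 0.1},
    "crf_bped_bias_sswf": {"head": "crf", "crf_bias": True, "bpe_dropout": 0.1,
                           "embeddings": "ssw", "ssw_hidden": 64,
                           "ssw_K": 256},
}
CORE_ARMS = ("softmax", "crf_bped", "crf_bped_bias")


def make_dataset(n_docs: int = 40, entity_rate: float = 0.6,
                 ambiguity_rate: float = 0.0, seed: int = 0,
                 valid_frac: float = 0.15, test_frac: float = 0.15
                 ) -> tuple[list[Sentence], list[Sentence], list[Sentence]]:
    """Synthetic corpus -> segmented sentences -> disjoint splits."""
    docs = generate(GenConfig(n_docs=n_docs, entity_rate=entity_rate,
                              ambiguity_rate=ambiguity_rate, seed=seed))
    sentences = [s for d in docs for s in segment_sentences(d)]
    n = len(sentences)
    n_valid = max(1, int(n * valid_frac))
    n_test = max(1, int(n * test_frac))
    return split_dataset(sentences, (n - n_valid - n_test, n_valid, n_test),
                         seed)


def gold_spans(sentences: Sequence[Sentence]) -> list[EntitySpan]:
    return [sp for s in sentences for sp in s.absolute_spans()]


def train_arm(arm: str, train_s, valid_s, *, seed: int, epochs: int = 12,
              lr: float = 3e-3, batch_size: int = 15) -> NERTagger:
    """Fit one ablation configuration with the desk-scale recipe."""
    est = NERTagger(**ARMS[arm], epochs=epochs, learning_rate=lr,
                    batch_size=batch_size, seed=seed)
    est.fit(train_s, validation=valid_s)
    return est


def run_ablation(seeds: Sequence[int], *, epochs: int = 12, lr: float = 3e-3,
                 ambiguity_rate: float = 0.35, n_docs: int = 40,
                 entity_rate: float = 0.6, data_seed: int = 0,
                 with_ssw: bool = False, arms: Sequence[str] | None = None
                 ) -> dict:
    """Train the ladder over seeds on one shared dataset.

    Returns ``{arm: RunAggregate}`` plus a ``"_details"`` entry holding
    per-seed F1 lists, per-seed test predictions (for ensembling) and the
    test gold spans.
    """
    if arms is None:
        arms = list(ARMS if with_ssw else
                    ("softmax", "softmax_bped", "crf_bped", "crf_bped_bias"))
    train_s, valid_s, test_s = make_dataset(
        n_docs=n_docs, entity_rate=entity_rate,
        ambiguity_rate=ambiguity_rate, seed=data_seed)
    gold = gold_spans(test_s)
    out: dict = {}
    details: dict = {"gold": gold, "f1": {}, "preds": {}, "models": {},
                     "test_sentences": test_s}
    for arm in arms:
        f1s, preds, models = [], [], []
        for seed in seeds:
            est = train_arm(arm, train_s, valid_s, seed=seed,
                            epochs=epochs, lr=lr)
            spans = [sp for g in est.predict(test_s) for sp in g]
            preds.append(spans)
            models.append(est)
            f1s.append(evaluate(gold, spans).f1)
        out[arm] = aggregate_runs(f1s)
        details["f1"][arm] = f1s
        details["preds"][arm] = preds
        details["models"][arm] = models
    out["_details"] = details
    return out


def ensemble_f1(details: dict, arm: str) -> tuple[float, list[float]]:
    """Majority-vote the per-seed models of one arm; returns the ensemble
    strict F1 and the member F1s."""
    preds = details["preds"][arm]
    voted = majority_vote(preds)
    return evaluate(details["gold"], voted).f1, details["f1"][arm]
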