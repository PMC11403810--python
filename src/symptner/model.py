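"""Token-classification model assembly, training loop and span prediction.

The architecture mirrors the usual transformer token-classifier recipe at
desk scale: a BPE tokenizer feeds a tiny trainable transformer encoder
(default 2 layers, width 64, 2 heads) whose per-subword states are
projected to per-label emission scores; the output head is either an
independent softmax per position or a linear-chain CRF (optionally with
biased transition initialization that disallows invalid BIO
transitions).  Embeddings come from a free lookup table or from the
sub-subword FTE network.  A pretrained encoder can replace the tiny one
by supplying its merge list and embedding matrix; nothing in the package
requires one.

Supervision is placed on word-start subwords only: word-level BIO tags
are aligned onto the first subword of each word, continuation subwords
are masked out of the loss, and decoding reads word-start positions, so
predicted tags map back to exact character offsets.

Training follows the standard fine-tuning loop: AdamW, shuffled
mini-batches, BPE-dropout re-segmentation of the training sentences each
epoch (inference always uses deterministic encoding), per-epoch strict-F1
evaluation on a validation set, and best-on-validation checkpoint
selection, with an optional single extra epoch on train+validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from . import bpe as bpe_mod
from . import crf as crf_mod
from . import ssw as ssw_mod
from .autodiff import Tensor, take_rows
from .bpe import BPEModel, DropoutConfig, PAD, UNK
from .corpus import EntitySpan, Sentence, TagSequence, bio_decode, bio_encode
from .evaluation import evaluate

DEFAULT_LABELS = ("O", "B-SINTOMA", "I-SINTOMA")


@dataclass
class ModelConfig:
    """Ablation axes plus encoder geometry."""

    head: str = "crf"                 # "softmax" | "crf"
    embeddings: str = "lookup"        # "lookup" | "ssw"
    crf_bias: bool = True
    crf_bias_mode: str = "all"        # "all" | "o_to_i"
    bpe_dropout: float = 0.1
    labels: tuple[str, ...] = DEFAULT_LABELS
    n_layers: int = 2
    d_model: int = 64
    n_heads: int = 2
    d_ff: int = 128
    max_len: int = 256
    num_merges: int = 200
    ssw_K: int = 512
    ssw_n_range: tuple[int, int] = (1, 3)
    ssw_hidden: int = 3072
    supervise_continuations: bool = False

    def __post_init__(self):
        if self.head not in ("softmax", "crf"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.embeddings not in ("lookup", "ssw"):
            raise ValueError(f"unknown embeddings {self.embeddings!r}")
        if self.crf_bias and self.head != "crf":
            raise ValueError("crf_bias requires head='crf'")
        if not 0.0 <= self.bpe_dropout <= 1.0:
            raise ValueError("bpe_dropout outside [0, 1]")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the fine-tuning
    recipe: 25 epochs, batches of 15 sentences, lr 2e-5, AdamW, keep the
    best model by validation strict F1).  From-scratch desk-scale
    training uses a larger learning rate — see the reproduction recipes."""

    epochs: int = 25
    batch_size: int = 15
    learning_rate: float = 2e-5
    weight_decay: float = 0.01
    seed: int = 0
    selection: str = "best"           # "best" | "none"
    extra_epoch_on_train_plus_valid: bool = False

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate must be positive")
        if self.selection not in ("best", "none"):
            raise ValueError(f"unknown selection {self.selection!r}")


def _layernorm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * g + b


class NERTagger(BaseEstimator):
    """Trainable symptom tagger: ``fit`` on Sentences, ``predict`` spans.

    Parameters mirror :class:`ModelConfig` + :class:`TrainConfig`; fitted
    state lives in trailing-underscore attributes (``tokenizer_``,
    ``params_``, ``history_``, ``n_parameters_``).
    """

    def __init__(self, head: str = "crf", embeddings: str = "lookup",
                 crf_bias: bool = True, crf_bias_mode: str = "all",
                 bpe_dropout: float = 0.1, labels: tuple = DEFAULT_LABELS,
                 n_layers: int = 2, d_model: int = 64, n_heads: int = 2,
                 d_ff: int = 128, max_len: int = 256, num_merges: int = 200,
                 ssw_K: int = 512, ssw_n_range: tuple = (1, 3),
                 ssw_hidden: int = 3072, supervise_continuations: bool = False,
                 epochs: int = 25, batch_size: int = 15,
                 learning_rate: float = 2e-5, weight_decay: float = 0.01,
                 seed: int = 0, selection: str = "best",
                 extra_epoch_on_train_plus_valid: bool = False):
        self.head = head
        self.embeddings = embeddings
        self.crf_bias = crf_bias
        self.crf_bias_mode = crf_bias_mode
        self.bpe_dropout = bpe_dropout
        self.labels = labels
        self.n_layers = n_layers
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.max_len = max_len
        self.num_merges = num_merges
        self.ssw_K = ssw_K
        self.ssw_n_range = ssw_n_range
        self.ssw_hidden = ssw_hidden
        self.supervise_continuations = supervise_continuations
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.seed = seed
        self.selection = selection
        self.extra_epoch_on_train_plus_valid = extra_epoch_on_train_plus_valid

    # -- construction -----------------------------------------------------
    def model_config(self) -> ModelConfig:
        return ModelConfig(
            head=self.head, embeddings=self.embeddings, crf_bias=self.crf_bias,
            crf_bias_mode=self.crf_bias_mode, bpe_dropout=self.bpe_dropout,
            labels=tuple(self.labels), n_layers=self.n_layers,
            d_model=self.d_model, n_heads=self.n_heads, d_ff=self.d_ff,
            max_len=self.max_len, num_merges=self.num_merges,
            ssw_K=self.ssw_K, ssw_n_range=tuple(self.ssw_n_range),
            ssw_hidden=self.ssw_hidden,
            supervise_continuations=self.supervise_continuations)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            seed=self.seed, selection=self.selection,
            extra_epoch_on_train_plus_valid=self.extra_epoch_on_train_plus_valid)

    def initialize(self, corpus: Sequence[str] | None = None,
                   bpe_model: BPEModel | None = None,
                   fte_init: ssw_mod.FTEParams | None = None) -> "NERTagger":
        """Deterministically build tokenizer, vocabulary and parameters.

        ``bpe_model`` lets an externally trained merge list stand in for
        the learned one (the pretrained-encoder plug-in path);
        ``fte_init`` injects MSE-pre-fitted FTE weights.
        """
        cfg = self.model_config()  # validates
        if bpe_model is not None:
            self.bpe_ = bpe_model
        else:
            if not corpus:
                raise ValueError("initialize needs a corpus or a BPEModel")
            self.bpe_ = bpe_mod.learn_bpe(corpus, cfg.num_merges)
        self.vocab_ = self.bpe_.vocabulary()
        self.vocab_index_ = {s: i for i, s in enumerate(self.vocab_)}
        rng = np.random.default_rng(self.seed)
        d, L = cfg.d_model, len(cfg.labels)
        params: dict[str, Tensor] = {}

        def par(name, shape, scale=0.02):
            params[name] = Tensor(rng.normal(0.0, scale, shape))

        if cfg.embeddings == "lookup":
            par("tok_emb", (len(self.vocab_), d))
        else:
            self.inventory_ = ssw_mod.select_features(
                self.vocab_, cfg.ssw_K, cfg.ssw_n_range)
            self.features_ = ssw_mod.featurize_vocab(self.vocab_, self.inventory_)
            fte = fte_init or ssw_mod.init_fte(
                self.inventory_.size, d, cfg.ssw_hidden, seed=self.seed)
            for i, (w, b) in enumerate(zip(fte.weights, fte.biases)):
                params[f"fte_w{i}"] = Tensor(w.copy())
                params[f"fte_b{i}"] = Tensor(b.copy())
        par("pos_emb", (cfg.max_len, d))
        for l in range(cfg.n_layers):
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                par(f"l{l}_{nm}", (d, d))
            params[f"l{l}_ln1_g"] = Tensor(np.ones(d))
            params[f"l{l}_ln1_b"] = Tensor(np.zeros(d))
            par(f"l{l}_Wff1", (d, cfg.d_ff))
            params[f"l{l}_bff1"] = Tensor(np.zeros(cfg.d_ff))
            par(f"l{l}_Wff2", (cfg.d_ff, d))
            params[f"l{l}_bff2"] = Tensor(np.zeros(d))
            params[f"l{l}_ln2_g"] = Tensor(np.ones(d))
            params[f"l{l}_ln2_b"] = Tensor(np.zeros(d))
        params["lnf_g"] = Tensor(np.ones(d))
        params["lnf_b"] = Tensor(np.zeros(d))
        par("out_W", (d, L))
        params["out_b"] = Tensor(np.zeros(L))
        if cfg.head == "crf":
            if cfg.crf_bias:
                cp = crf_mod.init_transitions(
                    cfg.labels, seed=self.seed, mode=cfg.crf_bias_mode)
            else:
                cp = crf_mod.random_transitions(cfg.labels, seed=self.seed)
            params["crf_trans"] = Tensor(cp.transitions)
            params["crf_start"] = Tensor(cp.start_scores)
            params["crf_end"] = Tensor(cp.end_scores)
        self.params_ = params
        self.n_parameters_ = int(sum(p.data.size for p in params.values()))
        self.history_ = []
        return self

    # -- forward ----------------------------------------------------------
    def _ids(self, tokens: list[str]) -> np.ndarray:
        unk = self.vocab_index_[UNK]
        return np.array([self.vocab_index_.get(t, unk) for t in tokens], dtype=int)

    def _embed(self, ids: np.ndarray) -> Tensor:
        if self.model_config().embeddings == "lookup":
            return take_rows(self.params_["tok_emb"], ids)
        weights = [self.params_[f"fte_w{i}"] for i in range(4)]
        biases = [self.params_[f"fte_b{i}"] for i in range(4)]
        feats = Tensor(self.features_[ids])
        return ssw_mod.fte_forward_t(feats, weights, biases)

    def _encode_states(self, ids: np.ndarray) -> Tensor:
        cfg = self.model_config()
        P = self.params_
        T = len(ids)
        x = self._embed(ids) + take_rows(P["pos_emb"], np.arange(T))
        H, dh = cfg.n_heads, cfg.d_model // cfg.n_heads
        for l in range(cfg.n_layers):
            h = _layernorm(x, P[f"l{l}_ln1_g"], P[f"l{l}_ln1_b"])
            q = (h @ P[f"l{l}_Wq"]).reshape(T, H, dh).transpose(1, 0, 2)
            k = (h @ P[f"l{l}_Wk"]).reshape(T, H, dh).transpose(1, 0, 2)
            v = (h @ P[f"l{l}_Wv"]).reshape(T, H, dh).transpose(1, 0, 2)
            scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
            attn = ad.softmax(scores, axis=-1)
            ctx = (attn @ v).transpose(1, 0, 2).reshape(T, cfg.d_model)
            x = x + ctx @ P[f"l{l}_Wo"]
            h = _layernorm(x, P[f"l{l}_ln2_g"], P[f"l{l}_ln2_b"])
            ff = ((h @ P[f"l{l}_Wff1"] + P[f"l{l}_bff1"]).relu()
                  @ P[f"l{l}_Wff2"] + P[f"l{l}_bff2"])
            x = x + ff
        x = _layernorm(x, P["lnf_g"], P["lnf_b"])
        return x @ P["out_W"] + P["out_b"]

    def _crf_parameters(self) -> crf_mod.CRFParameters:
        return crf_mod.CRFParameters(
            tuple(self.labels), self.params_["crf_trans"].data,
            self.params_["crf_start"].data, self.params_["crf_end"].data)

    # -- loss ---------------------------------------------------------------
    def _sentence_loss(self, sentence: Sentence,
                       rng: np.random.Generator | None) -> Tensor | None:
        cfg = self.model_config()
        if rng is not None and cfg.bpe_dropout > 0:
            sub = bpe_mod.encode_dropout(
                sentence.text, self.bpe_, DropoutConfig(cfg.bpe_dropout), rng=rng)
        else:
            sub = bpe_mod.encode(sentence.text, self.bpe_)
        if len(sub) == 0:
            return None
        if len(sub) > cfg.max_len:
            sub = bpe_mod.SubwordSequence(
                sub.tokens[:cfg.max_len], sub.intervals[:cfg.max_len],
                sub.word_start_flags[:cfg.max_len])
        word_tags = bio_encode(sentence)
        n_words = sum(sub.word_start_flags)
        if n_words < len(word_tags.tags):  # truncation cut words off
            word_tags = TagSequence(word_tags.tags[:n_words],
                                    word_tags.intervals[:n_words])
        sub_tags, mask = bpe_mod.align_labels(
            sub, word_tags, cfg.supervise_continuations)
        emissions = self._encode_states(self._ids(sub.tokens))
        label_idx = {lab: i for i, lab in enumerate(cfg.labels)}
        if cfg.head == "crf":
            pos = [i for i, f in enumerate(sub.word_start_flags) if f]
            tag_idx = np.array([label_idx[word_tags.tags[w]]
                                for w in range(len(pos))], dtype=int)
            em = take_rows(emissions, np.array(pos, dtype=int))
            return crf_mod.crf_nll(em, tag_idx, self.params_["crf_trans"],
                                   self.params_["crf_start"],
                                   self.params_["crf_end"])
        # softmax head: masked cross-entropy
        tag_idx = np.array([label_idx[t] for t in sub_tags], dtype=int)
        m = np.asarray(mask, dtype=float)
        onehot = np.zeros((len(sub), len(cfg.labels)))
        onehot[np.arange(len(sub)), tag_idx] = 1.0
        lse = ad.logsumexp(emissions, axis=1)
        picked = (emissions * onehot).sum(axis=1)
        return ((lse - picked) * m).sum() * (1.0 / max(m.sum(), 1.0))

    # -- fit ----------------------------------------------------------------
    def fit(self, X: Sequence[Sentence], y=None,
            validation: Sequence[Sentence] | None = None) -> "NERTagger":
        """Train on labelled Sentences; ``validation`` drives best-model
        selection (required unless ``selection='none'``)."""
        tc = self.train_config()
        if not X:
            raise ValueError("empty training set")
        if tc.selection == "best" and not validation:
            raise ValueError("selection='best' requires a validation set")
        if not hasattr(self, "params_"):
            self.initialize(corpus=[s.text for s in X])
        opt = ad.AdamW(self.params_, lr=tc.learning_rate,
                       weight_decay=tc.weight_decay)
        rng = np.random.default_rng(tc.seed)
        best_f1, best_state = -1.0, None
        self.history_ = []
        train = list(X)
        for epoch in range(tc.epochs):
            loss = self._run_epoch(train, opt, rng)
            rec = {"epoch": epoch, "train_loss": loss}
            if validation:
                rec["valid_strict_f1"] = self._strict_f1(validation)
                if tc.selection == "best" and rec["valid_strict_f1"] > best_f1:
                    best_f1 = rec["valid_strict_f1"]
                    best_state = {k: p.data.copy()
                                  for k, p in self.params_.items()}
            self.history_.append(rec)
        if best_state is not None:
            for k, p in self.params_.items():
                p.data = best_state[k]
        if tc.extra_epoch_on_train_plus_valid and validation:
            self._run_epoch(train + list(validation), opt, rng)
            self.history_.append({"epoch": tc.epochs, "extra": True})
        return self

    def _run_epoch(self, sentences: list[Sentence], opt: ad.AdamW,
                   rng: np.random.Generator) -> float:
        tc = self.train_config()
        order = rng.permutation(len(sentences))
        total, count = 0.0, 0
        for ofs in range(0, len(order), tc.batch_size):
            batch = [sentences[i] for i in order[ofs:ofs + tc.batch_size]]
            opt.zero_grad()
            losses = []
            for sent in batch:
                loss = self._sentence_loss(sent, rng)
                if loss is None:
                    continue
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss on {sent.doc_id!r} "
                        f"(epoch step {ofs}): {loss.data}")
                (loss * (1.0 / len(batch))).backward()
                losses.append(float(loss.data))
            if losses:
                opt.step()
                total += float(np.sum(losses))
                count += len(losses)
        return total / max(count, 1)

    def _strict_f1(self, sentences: Sequence[Sentence]) -> float:
        gold = [sp for s in sentences for sp in
                Sentence(s.doc_id, s.start, s.end, s.text, s.spans).absolute_spans()]
        pred = [sp for group in self.predict(sentences) for sp in group]
        return evaluate(gold, pred).f1

    # -- predict ------------------------------------------------------------
    def predict(self, X: Sequence[Sentence]) -> list[list[EntitySpan]]:
        """Deterministic span prediction, document-absolute offsets."""
        cfg = self.model_config()
        out: list[list[EntitySpan]] = []
        for sent in X:
            sub = bpe_mod.encode(sent.text, self.bpe_)
            if len(sub) == 0:
                out.append([])
                continue
            if len(sub) > cfg.max_len:
                sub = bpe_mod.SubwordSequence(
                    sub.tokens[:cfg.max_len], sub.intervals[:cfg.max_len],
                    sub.word_start_flags[:cfg.max_len])
            emissions = self._encode_states(self._ids(sub.tokens)).data
            pos = [i for i, f in enumerate(sub.word_start_flags) if f]
            # word interval = the full word, not just its first subword
            word_iv = []
            for j, i in enumerate(pos):
                last = pos[j + 1] - 1 if j + 1 < len(pos) else len(sub) - 1
                word_iv.append((sub.intervals[i][0], sub.intervals[last][1]))
            em = emissions[pos]
            if cfg.head == "crf":
                tags, _ = crf_mod.viterbi_decode(em, self._crf_parameters())
            else:
                tags = [cfg.labels[i] for i in np.argmax(em, axis=1)]
            seq = TagSequence(tags, word_iv)
            local = bio_decode(seq, text=sent.text, doc_id=sent.doc_id)
            out.append([EntitySpan(sp.doc_id, sp.start + sent.start,
                                   sp.end + sent.start, sp.label, sp.text)
                        for sp in local])
        return out

    def predict_tags(self, X: Sequence[Sentence]) -> list[list[str]]:
        """Word-level decoded tag sequences (for transition diagnostics)."""
        cfg = self.model_config()
        out = []
        for sent in X:
            sub = bpe_mod.encode(sent.text, self.bpe_)
            if len(sub) == 0:
                out.append([])
                continue
            emissions = self._encode_states(self._ids(sub.tokens)).data
            pos = [i for i, f in enumerate(sub.word_start_flags) if f]
            em = emissions[pos]
            if cfg.head == "crf":
                tags, _ = crf_mod.viterbi_decode(em, self._crf_parameters())
            else:
                tags = [cfg.labels[i] for i in np.argmax(em, axis=1)]
            out.append(tags)
        return out

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint archive (config + merges + params)."""
        meta = {
            "params": self.get_params(),
            "labels": list(self.labels),
            "vocab": self.vocab_,
            "alphabet": sorted(self.bpe_.alphabet),
            "merges": [list(m) for m in self.bpe_.merges],
            "history": self.history_,
        }
        arrays = {k: p.data for k, p in self.params_.items()}
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "NERTagger":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            arrays = {k: z[k] for k in z.files if k != "__meta__"}
        est = cls(**{**meta["params"],
                     "labels": tuple(meta["params"]["labels"]),
                     "ssw_n_range": tuple(meta["params"]["ssw_n_range"])})
        est.bpe_ = BPEModel(frozenset(meta["alphabet"]),
                            [tuple(m) for m in meta["merges"]])
        est.vocab_ = meta["vocab"]
        est.vocab_index_ = {s: i for i, s in enumerate(est.vocab_)}
        est.params_ = {k: Tensor(v) for k, v in arrays.items()}
        est.n_parameters_ = int(sum(v.size for v in arrays.values()))
        est.history_ = meta["history"]
        if est.embeddings == "ssw":
            est.inventory_ = ssw_mod.select_features(
                est.vocab_, est.ssw_K, tuple(est.ssw_n_range))
            est.features_ = ssw_mod.featurize_vocab(est.vocab_, est.inventory_)
        return est


# ---------------------------------------------------------------------------
# functional facade
# ---------------------------------------------------------------------------

def build_model(cfg: ModelConfig, seed: int,
                corpus: Sequence[str] | None = None,
                bpe_model: BPEModel | None = None) -> NERTagger:
    """Untrained tagger with deterministic seeded initialization."""
    est = NERTagger(**{**asdict(cfg), "labels": tuple(cfg.labels),
                       "ssw_n_range": tuple(cfg.ssw_n_range)}, seed=seed)
    est.initialize(corpus=corpus, bpe_model=bpe_model)
    return est


def train(model: NERTagger, train_sentences: Sequence[Sentence],
          valid_sentences: Sequence[Sentence] | None,
          tc: TrainConfig) -> NERTagger:
    for k, v in asdict(tc).items():
        setattr(model, k, v)
    return model.fit(train_sentences, validation=valid_sentences)


def predict(model: NERTagger, sentences: Sequence[Sentence]
            ) -> list[list[EntitySpan]]:
    return model.predict(sentences)
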