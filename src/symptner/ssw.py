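"""Sub-subword (SSW) feature embeddings.

Instead of a free per-subword lookup table, each subword's embedding is
computed from its character n-gram features: the subword is wrapped in
boundary markers (``^tos$``), its n-grams of orders ``n_range`` are
counted against a fixed feature inventory, and a feed-forward
feature-to-embedding (FTE) network with three hidden layers maps the
count vector into embedding space.  The FTE can be pre-fitted by MSE to
an existing embedding matrix before joint training, so the host model
starts from embeddings close to the ones it would otherwise look up.

The feature inventory is selected before training: all order-1 n-grams
are always included (a coverage floor guaranteeing every subword has at
least one active feature), and the remaining budget goes to the
highest-frequency higher-order n-grams of the vocabulary.  This
frequency heuristic is a documented, replaceable stand-in for fancier
selection algorithms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad

BOUNDARY_START, BOUNDARY_END = "^", "$"
DEFAULT_HIDDEN = 3072
N_HIDDEN_LAYERS = 3  # fixed architecture


def mark(subword: str) -> str:
    return BOUNDARY_START + subword + BOUNDARY_END


def extract_features(subword: str, n_range: tuple[int, int] = (1, 4)
                     ) -> Counter:
    """Multiset of character n-grams of the boundary-marked subword."""
    if not subword:
        raise ValueError("empty subword")
    lo, hi = n_range
    marked = mark(subword)
    feats: Counter[str] = Counter()
    for n in range(lo, hi + 1):
        for i in range(len(marked) - n + 1):
            feats[marked[i:i + n]] += 1
    return feats


@dataclass
class SSWInventory:
    features: list[str]
    n_range: tuple[int, int]
    index: dict[str, int] | None = None

    def __post_init__(self):
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in inventory")
        lo, hi = self.n_range
        for f in self.features:
            if not lo <= len(f) <= hi:
                raise ValueError(f"feature {f!r} outside n_range {self.n_range}")
        self.index = {f: k for k, f in enumerate(self.features)}

    @property
    def size(self) -> int:
        return len(self.features)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.features) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, n_range: tuple[int, int]) -> "SSWInventory":
        feats = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([f for f in feats if f], n_range)


def select_features(vocabulary: Sequence[str], K: int,
                    n_range: tuple[int, int] = (1, 4)) -> SSWInventory:
    """Frequency-ranked inventory with an all-unigrams coverage floor.

    Deterministic: unigrams first (sorted), then higher-order n-grams by
    descending total count over the vocabulary, ties lexicographic.
    """
    counts: Counter[str] = Counter()
    for sub in vocabulary:
        counts.update(extract_features(sub, n_range))
    unigrams = sorted(f for f in counts if len(f) == 1)
    if K < len(unigrams):
        raise ValueError(
            f"K={K} below the {len(unigrams)}-unigram coverage floor")
    rest = sorted((f for f in counts if len(f) > 1),
                  key=lambda f: (-counts[f], f))
    feats = unigrams + rest[:K - len(unigrams)]
    return SSWInventory(feats, n_range)


def featurize(subword: str, inventory: SSWInventory) -> np.ndarray:
    """Count vector of length K over the inventory."""
    vec = np.zeros(inventory.size)
    for f, c in extract_features(subword, inventory.n_range).items():
        k = inventory.index.get(f)
        if k is not None:
            vec[k] = c
    return vec


def featurize_vocab(vocabulary: Sequence[str], inventory: SSWInventory
                    ) -> np.ndarray:
    return np.stack([featurize(s, inventory) for s in vocabulary])


# ---------------------------------------------------------------------------
# FTE network
# ---------------------------------------------------------------------------

@dataclass
class FTEParams:
    """Weights of the input -> 3 x hidden -> output network (tanh units)."""

    weights: list[np.ndarray]   # 4 matrices
    biases: list[np.ndarray]    # 4 vectors

    def __post_init__(self):
        if len(self.weights) != N_HIDDEN_LAYERS + 1:
            raise ValueError("FTE network must have exactly 3 hidden layers")
        for w in self.weights + self.biases:
            if not np.all(np.isfinite(w)):
                raise ValueError("non-finite FTE weights")

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]


def init_fte(input_dim: int, output_dim: int, hidden: int = DEFAULT_HIDDEN,
             seed: int = 0) -> FTEParams:
    rng = np.random.default_rng(seed)
    dims = [input_dim] + [hidden] * N_HIDDEN_LAYERS + [output_dim]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(1.0 / d_in), (d_in, d_out)))
        biases.append(np.zeros(d_out))
    return FTEParams(weights, biases)


def fte_forward(x: np.ndarray, params: FTEParams) -> np.ndarray:
    """Deterministic forward pass; accepts a vector or a (N, K) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != params.input_dim:
        raise ValueError(
            f"feature dim {x.shape[1]} != network input {params.input_dim}")
    h = x
    for w, b in zip(params.weights[:-1], params.biases[:-1]):
        h = np.tanh(h @ w + b)
    out = h @ params.weights[-1] + params.biases[-1]
    return out[0] if single else out


def fte_forward_t(x: ad.Tensor, weights: list[ad.Tensor],
                  biases: list[ad.Tensor]) -> ad.Tensor:
    """Autodiff forward pass used inside training graphs."""
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        h = (h @ w + b).tanh()
    return h @ weights[-1] + biases[-1]


def pretrain_fte(inventory: SSWInventory, vocabulary: Sequence[str],
                 target_embeddings: np.ndarray, *, hidden: int = DEFAULT_HIDDEN,
                 steps: int = 200, lr: float = 1e-3, seed: int = 0
                 ) -> tuple[FTEParams, list[float]]:
    """Fit the FTE by MSE so its outputs approximate a target embedding
    matrix (one row per vocabulary subword).  Returns params + loss history
    (history[0] is the pre-update loss)."""
    target = np.asarray(target_embeddings, dtype=float)
    if target.shape[0] != len(vocabulary):
        raise ValueError("need one target row per vocabulary subword")
    X = featurize_vocab(vocabulary, inventory)
    params = init_fte(inventory.size, target.shape[1], hidden, seed)
    weights = [ad.Tensor(w) for w in params.weights]
    biases = [ad.Tensor(b) for b in params.biases]
    named = {f"w{i}": w for i, w in enumerate(weights)}
    named.update({f"b{i}": b for i, b in enumerate(biases)})
    opt = ad.AdamW(named, lr=lr, weight_decay=0.0)
    Xt, Tt = ad.Tensor(X), ad.Tensor(target)
    history: list[float] = []
    for _ in range(steps):
        diff = fte_forward_t(Xt, weights, biases) - Tt
        loss = (diff * diff).mean()
        history.append(float(loss.data))
        if not np.isfinite(history[-1]):
            raise FloatingPointError(
                f"FTE pre-fit diverged at step {len(history) - 1}: "
                f"loss={history[-1]}")
        opt.zero_grad()
        loss.backward()
        opt.step()
    final = fte_forward_t(Xt, weights, biases) - Tt
    history.append(float((final.data ** 2).mean()))
    return FTEParams([w.data for w in weights], [b.data for b in biases]), history


class FTEEmbedder(BaseEstimator):
    """Estimator facade: ``fit(vocabulary, targets)`` selects features and
    pre-fits the network; ``transform(subwords)`` returns embeddings."""

    def __init__(self, K: int = 4096, n_range: tuple[int, int] = (1, 4),
                 hidden: int = DEFAULT_HIDDEN, steps: int = 200,
                 lr: float = 1e-3, seed: int = 0):
        self.K = K
        self.n_range = n_range
        self.hidden = hidden
        self.steps = steps
        self.lr = lr
        self.seed = seed

    def fit(self, X: Sequence[str], y: np.ndarray) -> "FTEEmbedder":
        self.inventory_ = select_features(X, self.K, self.n_range)
        self.params_, self.loss_history_ = pretrain_fte(
            self.inventory_, X, y, hidden=self.hidden, steps=self.steps,
            lr=self.lr, seed=self.seed)
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        feats = featurize_vocab(X, self.inventory_)
        return np.atleast_2d(fte_forward(feats, self.params_))
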