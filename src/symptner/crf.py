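"""Linear-chain CRF: biased transition initialization, forward algorithm,
Viterbi decoding, and an autodiff negative log-likelihood for training.

A path through tags :math:`y_1..y_T` scores

.. math::

    s(y) = \\mathrm{start}_{y_1} + \\sum_t e_{t,y_t}
         + \\sum_t A_{y_t, y_{t+1}} + \\mathrm{end}_{y_T}

with emissions :math:`e` from the encoder and transition matrix
:math:`A`.  The partition function is computed by the forward recursion
in log space; decoding maximises the path score (Viterbi).

Invalid BIO transitions (O->I, start->I, and B/I-x -> I-y for x != y) can
be biased to a large negative constant at initialization so the decoder
never produces them, while the parameters remain trainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp as _lse

from . import autodiff as ad

DEFAULT_BIAS = -10000.0


@dataclass
class CRFParameters:
    labels: tuple[str, ...]
    transitions: np.ndarray      # (L, L): score of label i -> label j
    start_scores: np.ndarray     # (L,)
    end_scores: np.ndarray       # (L,)
    bias_value: float | None = None
    frozen_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def index(self, tag: str) -> int:
        try:
            return self.labels.index(tag)
        except ValueError:
            raise KeyError(f"tag {tag!r} not in inventory {self.labels}") from None


def invalid_transition_mask(labels: tuple[str, ...], mode: str = "all"
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (L, L) matrix of invalid BIO transitions + invalid starts.

    ``mode="all"``: O->I-x, B/I-y -> I-x (y != x), and start->I-x.
    ``mode="o_to_i"``: only O->I-x (the strictly literal variant).
    """
    L = len(labels)
    trans = np.zeros((L, L), dtype=bool)
    start = np.zeros(L, dtype=bool)
    for j, to in enumerate(labels):
        if not to.startswith("I-"):
            continue
        lab = to[2:]
        for i, frm in enumerate(labels):
            if frm == "O":
                trans[i, j] = True
            elif mode == "all" and frm[2:] != lab:
                trans[i, j] = True
        if mode == "all":
            start[j] = True
    return trans, start


def init_transitions(labels: tuple[str, ...] | list[str],
                     bias_value: float = DEFAULT_BIAS,
                     seed: int = 0,
                     mode: str = "all",
                     init_scale: float = 0.01,
                     freeze_bias: bool = False) -> CRFParameters:
    """CRF parameters with invalid BIO transitions pinned to ``bias_value``.

    All other entries get a small seeded random initialization and every
    entry (biased ones included) remains trainable unless ``freeze_bias``.
    """
    labels = tuple(labels)
    if not labels:
        raise ValueError("empty label inventory")
    rng = np.random.default_rng(seed)
    L = len(labels)
    trans = rng.normal(0.0, init_scale, (L, L))
    start = rng.normal(0.0, init_scale, L)
    end = rng.normal(0.0, init_scale, L)
    bad_t, bad_s = invalid_transition_mask(labels, mode)
    trans[bad_t] = bias_value
    start[bad_s] = bias_value
    frozen = None
    if freeze_bias:
        frozen = bad_t
    return CRFParameters(labels, trans, start, end, bias_value, frozen)


def random_transitions(labels, seed: int = 0, init_scale: float = 0.01
                       ) -> CRFParameters:
    """Unbiased random initialization (the no-bias ablation arm)."""
    labels = tuple(labels)
    if not labels:
        raise ValueError("empty label inventory")
    rng = np.random.default_rng(seed)
    L = len(labels)
    return CRFParameters(labels, rng.normal(0.0, init_scale, (L, L)),
                         rng.normal(0.0, init_scale, L),
                         rng.normal(0.0, init_scale, L))


# ---------------------------------------------------------------------------
# inference (numpy)
# ---------------------------------------------------------------------------

def _check_emissions(emissions: np.ndarray, params: CRFParameters) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[0] < 1:
        raise ValueError(f"emissions must be (T>=1, L), got {emissions.shape}")
    if emissions.shape[1] != params.n_labels:
        raise ValueError(
            f"emissions have {emissions.shape[1]} labels, inventory has "
            f"{params.n_labels}")
    if not np.all(np.isfinite(emissions)):
        raise ValueError("non-finite emission scores")
    return emissions


def log_partition(emissions: np.ndarray, params: CRFParameters) -> float:
    """log sum over all label paths of exp(path score) (forward algorithm)."""
    emissions = _check_emissions(emissions, params)
    alpha = params.start_scores + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _lse(alpha[:, None] + params.transitions, axis=0) + emissions[t]
    return float(_lse(alpha + params.end_scores))


def sequence_score(emissions: np.ndarray, tags: list[str] | np.ndarray,
                   params: CRFParameters) -> float:
    """Score of one concrete tag path."""
    emissions = _check_emissions(emissions, params)
    idx = [params.index(t) if isinstance(t, str) else int(t) for t in tags]
    if len(idx) != emissions.shape[0]:
        raise ValueError("tag sequence length != emission length")
    for i in idx:
        if not 0 <= i < params.n_labels:
            raise KeyError(f"tag index {i} outside inventory")
    score = params.start_scores[idx[0]] + emissions[0, idx[0]]
    for t in range(1, len(idx)):
        score += params.transitions[idx[t - 1], idx[t]] + emissions[t, idx[t]]
    return float(score + params.end_scores[idx[-1]])


def log_likelihood(emissions: np.ndarray, tags, params: CRFParameters) -> float:
    return sequence_score(emissions, tags, params) - log_partition(emissions, params)


def viterbi_decode(emissions: np.ndarray, params: CRFParameters
                   ) -> tuple[list[str], float]:
    """Argmax-scoring tag path.  Ties break toward the lowest label index
    (numpy argmax convention), deterministically."""
    emissions = _check_emissions(emissions, params)
    T, L = emissions.shape
    delta = params.start_scores + emissions[0]
    back = np.zeros((T, L), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + params.transitions
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(L)] + emissions[t]
    delta = delta + params.end_scores
    last = int(np.argmax(delta))
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return [params.labels[i] for i in path], float(delta[last])


def count_invalid_transitions(tags: list[str]) -> int:
    """Number of I-tags not preceded by a B/I of the same label."""
    bad = 0
    prev = "O"
    for tag in tags:
        if tag.startswith("I-") and (prev == "O" or prev[2:] != tag[2:]):
            bad += 1
        prev = tag
    return bad


# ---------------------------------------------------------------------------
# training objective (autodiff)
# ---------------------------------------------------------------------------

def crf_nll(emissions: ad.Tensor, tag_idx: np.ndarray,
            transitions: ad.Tensor, start: ad.Tensor, end: ad.Tensor
            ) -> ad.Tensor:
    """Negative log-likelihood of one path, differentiable in emissions and
    CRF parameters; mirrors :func:`log_partition` / :func:`sequence_score`."""
    T = emissions.shape[0]
    tag_idx = np.asarray(tag_idx, dtype=int)
    # gold path score
    onehot = np.zeros(emissions.shape)
    onehot[np.arange(T), tag_idx] = 1.0
    score = (emissions * onehot).sum()
    score = score + ad.take_rows(start, [tag_idx[0]]).sum()
    score = score + ad.take_rows(end, [tag_idx[-1]]).sum()
    if T > 1:
        flat = transitions.reshape(-1)
        L = emissions.shape[1]
        pair_idx = tag_idx[:-1] * L + tag_idx[1:]
        score = score + ad.take_rows(flat, pair_idx).sum()
    # partition
    alpha = start + ad.take_rows(emissions, [0]).reshape(-1)
    for t in range(1, T):
        em_t = ad.take_rows(emissions, [t]).reshape(-1)
        alpha = ad.logsumexp(alpha.reshape(-1, 1) + transitions, axis=0) + em_t
    logz = ad.logsumexp(alpha + end, axis=0)
    return logz - score
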