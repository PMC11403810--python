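"""BPE learning, deterministic and dropout encoding, label alignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from symptner.bpe import (BPEModel, BPETokenizer, DropoutConfig, align_labels,
                          encode, encode_dropout, learn_bpe)
from symptner.corpus import Sentence, TagSequence, bio_encode, EntitySpan

CORPUS = ["dolor torácico agudo", "dolor abdominal difuso",
          "tos seca persistente", "fiebre alta nocturna"] * 3


@pytest.fixture(scope="module")
def model():
    return learn_bpe(CORPUS, 60)


class TestLearn:
    def test_zero_merges_encodes_base_symbols(self):
        m = learn_bpe(CORPUS, 0)
        assert m.merges == []
        assert all(len(t) == 1 for t in encode("dolor", m).tokens)

    def test_most_frequent_pair_learned_first(self):
        m = learn_bpe(["aaaa"] * 100, 1)
        assert m.merges == [("a", "a")]

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError, match="empty"):
            learn_bpe([], 10)

    def test_training_corpus_covered_by_vocabulary(self, model):
        vocab = set(model.vocabulary())
        for sent in CORPUS:
            assert all(t in vocab for t in encode(sent, model).tokens)

    def test_merge_file_round_trip(self, model, tmp_path):
        path = tmp_path / "merges.txt"
        model.save_merges(path)
        loaded = BPEModel.load_merges(path)
        assert loaded.merges == model.merges
        text = "dolor torácico"
        assert encode(text, loaded).tokens == encode(text, model).tokens


class TestEncode:
    def test_empty_string(self, model):
        assert len(encode("", model)) == 0

    def test_deterministic(self, model):
        a, b = encode("tos seca", model), encode("tos seca", model)
        assert a.tokens == b.tokens and a.intervals == b.intervals

    def test_intervals_slice_source(self, model):
        text = "fiebre alta y tos"
        seq = encode(text, model)
        for tok, (a, b) in zip(seq.tokens, seq.intervals):
            assert text[a:b] == tok

    def test_unknown_characters_pass_through(self, model):
        seq = encode("dolor 警报", model)
        assert seq.restore("dolor 警报") == "dolor 警报"

    @given(st.text(alphabet="dolrtsecafibn áí", max_size=40))
    def test_concatenation_restores_text(self, model, text):
        assert encode(text, model).restore(text) == text


class TestDropout:
    def test_p0_equals_deterministic(self, model):
        for seed in range(5):
            d = encode_dropout("dolor torácico", model, DropoutConfig(0.0, seed))
            assert d.tokens == encode("dolor torácico", model).tokens

    def test_p1_gives_base_symbols(self, model):
        d = encode_dropout("dolor torácico", model, DropoutConfig(1.0, 0))
        assert all(len(t) == 1 for t in d.tokens)

    def test_seeded_reproducibility(self, model):
        a = encode_dropout("persistente", model, DropoutConfig(0.3, 9))
        b = encode_dropout("persistente", model, DropoutConfig(0.3, 9))
        assert a.tokens == b.tokens

    def test_different_seeds_vary_segmentation(self, model):
        outs = {tuple(encode_dropout("persistente torácico abdominal", model,
                                     DropoutConfig(0.3, s)).tokens)
                for s in range(20)}
        assert len(outs) > 1

    def test_segmentation_always_valid(self, model):
        text = "dolor torácico persistente"
        for p in (0.1, 0.5, 0.9):
            for seed in range(10):
                d = encode_dropout(text, model, DropoutConfig(p, seed))
                assert d.restore(text) == text

    def test_fragmentation_monotone_in_p(self, model):
        text = "dolor torácico persistente abdominal"
        means = []
        for p in (0.0, 0.3, 0.7, 1.0):
            counts = [len(encode_dropout(text, model, DropoutConfig(p, s)))
                      for s in range(50)]
            means.append(np.mean(counts))
        assert all(a <= b + 1e-9 for a, b in zip(means[:-1], means[1:]))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            DropoutConfig(1.5, 0)


class TestAlignLabels:
    def test_entity_word_split_into_three(self, model):
        # force a multi-subword segmentation via a fresh 0-merge model
        m0 = learn_bpe(["taquicardia"], 8)
        text = "taquicardia"
        sub = encode(text, m0)
        assert len(sub) >= 3
        tags = TagSequence(["B-SINTOMA"], [(0, len(text))])
        out, mask = align_labels(sub, tags)
        assert out[0] == "B-SINTOMA"
        assert all(t == "I-SINTOMA" for t in out[1:])
        assert mask[0] == 1 and all(m == 0 for m in mask[1:])

    def test_single_subword_word_unchanged(self, model):
        sub = encode("tos", model)
        out, mask = align_labels(sub, TagSequence(["B-SINTOMA"], [(0, 3)]))
        assert out == ["B-SINTOMA"] and mask == [1]

    def test_outside_word_split_in_two(self):
        m0 = learn_bpe(["xy"], 0)
        sub = encode("xy", m0)
        out, mask = align_labels(sub, TagSequence(["O"], [(0, 2)]))
        assert out == ["O", "O"] and mask == [1, 0]

    def test_continuation_supervision_mode(self):
        m0 = learn_bpe(["xy"], 0)
        sub = encode("xy", m0)
        _, mask = align_labels(sub, TagSequence(["O"], [(0, 2)]),
                               supervise_continuations=True)
        assert mask == [1, 1]

    def test_word_count_mismatch_errors(self, model):
        sub = encode("tos seca", model)
        with pytest.raises(ValueError, match="mismatch"):
            align_labels(sub, TagSequence(["O"], [(0, 3)]))

    def test_word_start_round_trip(self, model):
        s = Sentence("d", 0, 8, "tos seca",
                     [EntitySpan("d", 0, 8, "SINTOMA", "tos seca")])
        word_tags = bio_encode(s)
        sub = encode(s.text, model)
        aligned, _ = align_labels(sub, word_tags)
        starts = [t for t, f in zip(aligned, sub.word_start_flags) if f]
        assert starts == word_tags.tags


def test_tokenizer_estimator_fit_transform():
    tok = BPETokenizer(num_merges=30, dropout=0.2)
    tok.fit(CORPUS)
    outs = tok.transform(["dolor seco"])
    assert outs[0].restore("dolor seco") == "dolor seco"
    a = tok.transform_dropout(["dolor torácico"], seed=3)
    b = tok.transform_dropout(["dolor torácico"], seed=3)
    assert a[0].tokens == b[0].tokens
    assert tok.get_params()["num_merges"] == 30
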