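"""Standoff I/O, sentence segmentation, BIO codec, dataset splits."""

import pytest
from hypothesis import given, strategies as st

from symptner.corpus import (Document, EntitySpan, Sentence, TagSequence,
                             bio_decode, bio_encode, read_standoff,
                             segment_sentences, split_dataset, tokenize_words,
                             write_conll, write_standoff)

HEADER = "filename\tlabel\tstart_span\tend_span\ttext\n"


class TestReadStandoff:
    def test_substring_violation_errors_with_location(self):
        table = HEADER + "d1\tSINTOMA\t5\t10\ttos\n"
        with pytest.raises(ValueError, match="d1"):
            read_standoff(table, {"d1": "x" * 20})

    def test_empty_table_gives_documents_without_spans(self):
        docs = read_standoff(HEADER, {"d1": "uno", "d2": "dos"})
        assert len(docs) == 2 and all(d.spans == [] for d in docs)

    def test_valid_row_parsed(self):
        text = "dolor torácico"
        table = HEADER + "d1\tSINTOMA\t0\t5\tdolor\n"
        (doc,) = read_standoff(table, {"d1": text})
        assert doc.spans[0].start == 0 and doc.spans[0].end == 5
        assert doc.spans[0].text == "dolor"

    def test_unknown_doc_id_errors(self):
        with pytest.raises(ValueError, match="unknown doc_id"):
            read_standoff(HEADER + "nope\tSINTOMA\t0\t2\tab\n", {"d1": "abc"})

    def test_offsets_outside_document_error(self):
        with pytest.raises(ValueError, match="outside"):
            read_standoff(HEADER + "d1\tSINTOMA\t0\t99\tab\n", {"d1": "abc"})

    def test_writer_reader_inverse(self, small_docs):
        tsv = write_standoff(small_docs)
        back = read_standoff(tsv, {d.doc_id: d.text for d in small_docs})
        orig = {d.doc_id: sorted(sp.key for sp in d.spans) for d in small_docs}
        got = {d.doc_id: sorted(sp.key for sp in d.spans) for d in back}
        assert orig == got


class TestSegmentation:
    def test_plain_boundary_splits(self):
        doc = Document("d", "abcdefghi jklmnopqr")
        sents = segment_sentences(doc, splitter=lambda t: [10])
        assert [s.text for s in sents] == ["abcdefghi", "jklmnopqr"]

    def test_boundary_inside_entity_is_dropped(self):
        doc = Document("d", "aaaaaaaa bbbbbb cccc",
                       [EntitySpan("d", 8, 15, "SINTOMA")])
        sents = segment_sentences(doc, splitter=lambda t: [10])
        assert len(sents) == 1

    def test_only_safe_boundary_survives(self):
        doc = Document("d", "aaaaaaaa bbbbbb cccc x",
                       [EntitySpan("d", 8, 15, "SINTOMA")])
        sents = segment_sentences(doc, splitter=lambda t: [10, 20])
        assert len(sents) == 2
        assert sents[0].end == 20 or sents[1].start == 20

    def test_degenerate_doc_single_sentence(self):
        assert len(segment_sentences(Document("d", "hola"))) == 1

    def test_conservation(self, small_docs):
        for doc in small_docs:
            sents = segment_sentences(doc)
            # spans conserved
            assert sum(len(s.spans) for s in sents) == len(doc.spans)
            # sentence intervals disjoint, ordered, text matches slices
            for a, b in zip(sents[:-1], sents[1:]):
                assert a.end <= b.start
            for s in sents:
                assert doc.text[s.start:s.end] == s.text
                for sp in s.spans:
                    assert s.text[sp.start:sp.end] == sp.text

    def test_rebased_spans_match_document(self, toy_doc):
        sents = segment_sentences(toy_doc)
        joined = [sp for s in sents for sp in s.absolute_spans()]
        assert [sp.key for sp in joined] == [sp.key for sp in toy_doc.spans]


class TestBIOCodec:
    def test_two_token_entity(self):
        s = Sentence("d", 0, 8, "tos seca",
                     [EntitySpan("d", 0, 8, "SINTOMA", "tos seca")])
        assert bio_encode(s).tags == ["B-SINTOMA", "I-SINTOMA"]

    def test_no_spans_all_outside(self):
        s = Sentence("d", 0, 8, "tos seca")
        assert bio_encode(s).tags == ["O", "O"]

    def test_adjacent_single_token_entities(self):
        s = Sentence("d", 0, 8, "tos seca",
                     [EntitySpan("d", 0, 3, "SINTOMA", "tos"),
                      EntitySpan("d", 4, 8, "SINTOMA", "seca")])
        assert bio_encode(s).tags == ["B-SINTOMA", "B-SINTOMA"]

    def test_overlapping_spans_rejected(self):
        s = Sentence("d", 0, 8, "tos seca",
                     [EntitySpan("d", 0, 5, "SINTOMA"),
                      EntitySpan("d", 4, 8, "SINTOMA")])
        with pytest.raises(ValueError, match="overlap"):
            bio_encode(s)

    def test_boundary_inside_token_rejected(self):
        s = Sentence("d", 0, 8, "tos seca", [EntitySpan("d", 0, 2, "SINTOMA")])
        with pytest.raises(ValueError, match="inside token"):
            bio_encode(s)

    def test_decode_run(self):
        seq = TagSequence(["B-S", "I-S", "O"], [(0, 3), (4, 8), (9, 12)])
        (sp,) = bio_decode(seq)
        assert (sp.start, sp.end) == (0, 8)

    def test_decode_all_outside(self):
        assert bio_decode(TagSequence(["O", "O"], [(0, 1), (2, 3)])) == []

    def test_orphan_inside_promoted_to_begin(self):
        seq = TagSequence(["O", "I-S"], [(0, 3), (4, 8)])
        (sp,) = bio_decode(seq)
        assert (sp.start, sp.end, sp.label) == (4, 8, "S")

    def test_label_switch_closes_span(self):
        seq = TagSequence(["B-A", "I-B"], [(0, 3), (4, 8)])
        spans = bio_decode(seq)
        assert [(s.start, s.end, s.label) for s in spans] == \
            [(0, 3, "A"), (4, 8, "B")]

    def test_round_trip_on_synthetic_sentences(self, small_sentences):
        for s in small_sentences:
            decoded = bio_decode(bio_encode(s), text=s.text, doc_id=s.doc_id)
            want = sorted((sp.start, sp.end, sp.label) for sp in s.spans)
            got = sorted((sp.start, sp.end, sp.label) for sp in decoded)
            assert want == got

    def test_validity_check(self):
        assert TagSequence(["B-S", "I-S"], [(0, 1), (2, 3)]).is_valid_bio()
        assert not TagSequence(["O", "I-S"], [(0, 1), (2, 3)]).is_valid_bio()

    def test_conll_export(self, toy_doc):
        sents = segment_sentences(toy_doc)
        out = write_conll(sents)
        assert "tos\tB-SINTOMA" in out and "seca\tI-SINTOMA" in out


class TestSplitDataset:
    def test_deterministic(self):
        items = list(range(10))
        a = split_dataset(items, (8, 1, 1), seed=1)
        b = split_dataset(items, (8, 1, 1), seed=1)
        assert a == b

    def test_all_in_test(self):
        tr, va, te = split_dataset(list(range(5)), (0, 0, 5), seed=0)
        assert tr == [] and va == [] and sorted(te) == list(range(5))

    def test_partition_exhaustive_disjoint(self):
        items = list(range(101))
        tr, va, te = split_dataset(items, (80, 10, 11), seed=3)
        assert sorted(tr + va + te) == items

    def test_size_mismatch_errors(self):
        with pytest.raises(ValueError, match="sum"):
            split_dataset(list(range(10)), (8, 1, 2), seed=0)


@given(st.text(alphabet=st.characters(codec="utf-8",
                                      exclude_categories=("C",)),
               max_size=60))
def test_word_tokenization_intervals_cover_nonspace(text):
    intervals = tokenize_words(text)
    rebuilt = "".join(text[a:b] for a, b in intervals)
    assert rebuilt == "".join(text.split())
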