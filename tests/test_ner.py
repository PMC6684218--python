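"""Tagger training, BIO decoding and span evaluation."""

from datetime import date

import numpy as np
import pytest

from adrsignal.corpus import Post
from adrsignal.embeddings import train_embeddings
from adrsignal.ner import (
    EntitySpan,
    TAGS,
    TaggerModel,
    annotator_agreement,
    encode_tags,
    evaluate_ner,
    read_standoff,
    tag_post,
    train_tagger,
    write_standoff,
)
from adrsignal.ner import _decode_sentence
from adrsignal.text import tokenize


def _span(post_id, start, end, surface, label="ADR"):
    return EntitySpan(post_id, start, end, surface, label)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


class TestMetrics:
    def _gold(self):
        return [_span("p1", i * 10, i * 10 + 4, "gold") for i in range(5)]

    def test_identical_sets_score_one(self):
        gold = self._gold()
        m = evaluate_ner(gold, gold, mode="strict")
        assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)

    def test_hand_computed_micro_scores(self):
        """TP=3, FP=1, FN=2 pools to P=0.75, R=0.6, F=0.6667."""
        gold = self._gold()
        pred = gold[:3] + [_span("p1", 90, 95, "spurious")]
        m = evaluate_ner(pred, gold, mode="strict")
        assert (m.tp, m.fp, m.fn) == (3, 1, 2)
        assert m.precision == 0.75
        assert m.recall == 0.6
        assert m.f_measure == pytest.approx(0.6667, abs=5e-5)

    def test_empty_prediction_convention(self):
        m = evaluate_ner([], self._gold(), mode="strict")
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)

    def test_overlap_mode_accepts_partial_spans(self):
        gold = [_span("p1", 10, 20, "x")]
        pred = [_span("p1", 14, 25, "y")]
        assert evaluate_ner(pred, gold, mode="strict").tp == 0
        assert evaluate_ner(pred, gold, mode="overlap").tp == 1

    def test_overlap_matching_is_one_to_one(self):
        gold = [_span("p1", 10, 20, "x")]
        pred = [_span("p1", 10, 20, "a"), _span("p1", 12, 18, "b")]
        m = evaluate_ner(pred, gold, mode="overlap")
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_label_mismatch_never_matches(self):
        gold = [_span("p1", 10, 20, "x", "ADR")]
        pred = [_span("p1", 10, 20, "x", "IND")]
        assert evaluate_ner(pred, gold, mode="overlap").tp == 0

    def test_unknown_post_id_rejected(self):
        with pytest.raises(ValueError, match="unknown post_id"):
            evaluate_ner(
                [_span("ghost", 0, 4, "x")], [], mode="strict", known_posts={"p1"}
            )

    def test_f_bounded_by_max_of_p_and_r(self):
        gold = self._gold()
        pred = gold[:2] + [_span("p1", 90, 95, "s1"), _span("p1", 80, 85, "s2")]
        m = evaluate_ner(pred, gold, mode="strict")
        assert 0.0 <= m.f_measure <= max(m.precision, m.recall)


class TestAgreement:
    def test_identical_annotations_agree_fully(self):
        spans = [_span("p1", 0, 4, "x"), _span("p2", 3, 9, "y", "IND")]
        assert annotator_agreement(spans, spans) == 1.0

    def test_strict_agreement_symmetric(self):
        a = [_span("p1", 0, 4, "x"), _span("p1", 10, 14, "y")]
        b = [_span("p1", 0, 4, "x"), _span("p1", 20, 24, "z")]
        assert annotator_agreement(a, b) == annotator_agreement(b, a)

    def test_four_of_five_shared_spans(self):
        b = [_span("p1", i * 10, i * 10 + 4, "s") for i in range(5)]
        a = b[:4]
        assert annotator_agreement(a, b) == pytest.approx(0.8889, abs=5e-5)


# ---------------------------------------------------------------------------
# encoding and decoding
# ---------------------------------------------------------------------------


class TestEncodeDecode:
    def test_misaligned_gold_span_snaps_outward(self):
        body = "terrible blistering today"
        sent = tokenize(body, post_id="p1")
        # span covers only part of the token "blistering"
        tags = encode_tags(sent, [_span("p1", 9, 14, "blist")])
        assert [TAGS[t] for t in tags] == ["O", "B-ADR", "O"]

    def test_span_outside_tokens_rejected(self):
        body = "a b ,, c"
        sent = tokenize(body, post_id="p1")
        with pytest.raises(ValueError, match="aligns to no token"):
            encode_tags(sent, [_span("p1", 5, 6, ",")])

    def test_orphan_inside_tag_repaired_to_single_token_span(self):
        body = "felt bad yesterday"
        sent = tokenize(body, post_id="p1")
        proba = np.full((3, 5), 0.01)
        proba[0, 0] = proba[2, 0] = 0.96  # O ... O
        proba[1, 2] = 0.96  # I-ADR with no opener
        spans = _decode_sentence(sent, proba, body)
        assert len(spans) == 1
        assert spans[0].surface == "bad"
        assert spans[0].label == "ADR"

    def test_decoded_spans_do_not_overlap(self):
        body = "one two three four"
        sent = tokenize(body, post_id="p1")
        proba = np.full((4, 5), 0.01)
        proba[0, 1] = proba[1, 2] = proba[2, 1] = proba[3, 3] = 0.96
        spans = _decode_sentence(sent, proba, body)
        assert [s.surface for s in spans] == ["one two", "three", "four"]
        for s1, s2 in zip(spans, spans[1:]):
            assert s1.char_end <= s2.char_start


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_training():
    adrs = ["rash", "itch", "blister", "headache"]
    lines, spans = [], []
    for i in range(60):
        adr = adrs[i % 4]
        body = f"my {adr} got bad after treatment"
        lines.append((f"p{i}", body))
        spans.append(_span(f"p{i}", 3, 3 + len(adr), adr))
    sentences = [tokenize(body, post_id=pid) for pid, body in lines]
    table = train_embeddings(sentences, dim=12, seed=5, epochs=3, min_count=1)
    labeled = [(s, [sp]) for s, sp in zip(sentences, spans)]
    return lines, labeled, table


class TestTraining:
    def test_loss_decreases_on_fixture(self, tiny_training):
        _, labeled, table = tiny_training
        model = train_tagger(labeled, table, seed=13, epochs=10, hidden=32)
        assert model.epoch_losses[-1] < model.epoch_losses[0]

    def test_same_seed_gives_byte_identical_archives(self, tiny_training, tmp_path):
        _, labeled, table = tiny_training
        a = train_tagger(labeled, table, seed=13, epochs=4, hidden=16)
        b = train_tagger(labeled, table, seed=13, epochs=4, hidden=16)
        a.save(tmp_path / "a.model")
        b.save(tmp_path / "b.model")
        assert (tmp_path / "a.model").read_bytes() == (tmp_path / "b.model").read_bytes()

    def test_memorizes_training_sentence(self, tiny_training):
        lines, labeled, table = tiny_training
        model = train_tagger(labeled, table, seed=13, epochs=12, hidden=32)
        pid, body = lines[0]
        post = Post(post_id=pid, user_id="u", created_at=date(2014, 1, 1), body=body)
        spans = tag_post(model, post)
        assert any(s.surface == "rash" and s.label == "ADR" for s in spans)

    def test_surface_equals_body_slice_for_all_predictions(self, tiny_training):
        lines, labeled, table = tiny_training
        model = train_tagger(labeled, table, seed=13, epochs=6, hidden=16)
        for pid, body in lines[:10]:
            post = Post(post_id=pid, user_id="u", created_at=date(2014, 1, 1), body=body)
            for s in tag_post(model, post):
                assert body[s.char_start : s.char_end] == s.surface
                assert 0.0 <= s.score <= 1.0

    def test_zero_entity_training_predicts_all_o(self, tiny_training):
        _, labeled, table = tiny_training
        unlabeled = [(s, []) for s, _ in labeled]
        model = train_tagger(unlabeled, table, seed=13, epochs=6, hidden=16)
        post = Post(post_id="px", user_id="u", created_at=date(2014, 1, 1),
                    body="my rash got bad after treatment")
        assert tag_post(model, post) == []

    def test_empty_body_gives_no_spans(self, tiny_training):
        _, labeled, table = tiny_training
        model = train_tagger(labeled, table, seed=13, epochs=2, hidden=16)
        post = Post(post_id="px", user_id="u", created_at=date(2014, 1, 1), body=" ")
        assert tag_post(model, post) == []

    def test_save_load_round_trip_predictions(self, tiny_training, tmp_path):
        lines, labeled, table = tiny_training
        model = train_tagger(labeled, table, seed=13, epochs=4, hidden=16)
        model.save(tmp_path / "m.model")
        loaded = TaggerModel.load(tmp_path / "m.model")
        sent = tokenize(lines[0][1], post_id=lines[0][0])
        np.testing.assert_array_equal(
            model.predict_proba(sent), loaded.predict_proba(sent)
        )

    def test_empty_training_set_rejected(self, tiny_training):
        _, _, table = tiny_training
        with pytest.raises(ValueError):
            train_tagger([], table)


def test_standoff_round_trip(tmp_path):
    spans = [
        _span("p1", 3, 7, "rash"),
        _span("p2", 10, 22, "lung cancer", "IND"),
    ]
    path = tmp_path / "spans.tsv"
    write_standoff(spans, path)
    back = read_standoff(path)
    assert [
        (s.post_id, s.char_start, s.char_end, s.surface, s.label) for s in back
    ] == [(s.post_id, s.char_start, s.char_end, s.surface, s.label) for s in spans]
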