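"""Answer keys, response filtering, and the word-presence scoring procedure."""

import io

import pytest

from sbarscore import (
    ResponseRecord,
    ScoreSheet,
    ValidationError,
    compile_answer_key,
    dump_answer_key,
    filter_valid_responses,
    load_answer_key,
    load_score_sheet,
    match_concept,
    score_corpus,
)
from sbarscore.scoring import PART_MAX, TOTAL_MAX, score_sheet_from_frame
from sbarscore.synth import build_answer_key, build_lexicons
from sbarscore.lexicon import merge_dictionaries


class TestAnswerKey:
    def test_exam_key_has_19_questions_18_scorable(self):
        key = build_answer_key()
        assert len(key.questions) == 19
        assert len(key.scorable_ids) == 18
        assert not key["4-3"].scorable

    def test_part_layout_5_3_5_5_scorable(self):
        key = build_answer_key()
        per_part = {p: sum(1 for q in key.questions if q.scorable and q.part == p) for p in (3, 4, 5, 6)}
        assert per_part == PART_MAX
        assert TOTAL_MAX == 18

    def test_duplicate_question_id_rejected(self):
        doc = '{"questions": [{"id": "4-1", "accept": ["a"]}, {"id": "4-1", "accept": ["b"]}]}'
        with pytest.raises(ValidationError, match="duplicate"):
            load_answer_key(doc)

    def test_scorable_question_with_empty_accept_rejected(self):
        doc = '{"questions": [{"id": "3-1", "accept": []}]}'
        with pytest.raises(ValidationError, match="empty accept"):
            load_answer_key(doc)

    def test_minimal_single_question_key(self):
        key = load_answer_key('{"questions": [{"id": "3-1", "accept": ["syncope"]}]}')
        assert key.scorable_ids == ("3-1",)

    def test_key_round_trips_through_json(self):
        key = build_answer_key()
        assert load_answer_key(dump_answer_key(key)) == key


class TestCompileAnswerKey:
    def test_single_word_accept(self, default_bundle):
        ckey = compile_answer_key(default_bundle.answer_key, default_bundle.lexicon)
        assert ("amlodipine",) in ckey.sequences["4-2"]

    def test_numeral_variants_compiled(self, default_bundle):
        # "2p" must also be reachable through roman/chinese notation
        ckey = compile_answer_key(default_bundle.answer_key, default_bundle.lexicon)
        forms = {seq for seq in ckey.sequences["5-4"] if len(seq) == 1}
        flat = {s[0] for s in forms}
        assert {"2p", "iip", "二p"} <= flat

    def test_compilation_deterministic(self, default_bundle):
        a = compile_answer_key(default_bundle.answer_key, default_bundle.lexicon)
        b = compile_answer_key(default_bundle.answer_key, default_bundle.lexicon)
        assert a.sequences == b.sequences

    def test_uncovered_accept_warns_but_compiles(self, caplog):
        key = load_answer_key('{"questions": [{"id": "3-1", "accept": ["qqq"]}]}')
        lex, _ = build_lexicons()
        with caplog.at_level("WARNING", logger="sbarscore.scoring"):
            ckey = compile_answer_key(key, lex)
        assert ("q", "q", "q") in ckey.sequences["3-1"]
        assert any("unknown characters" in r.message for r in caplog.records)


class TestFilterValidResponses:
    def test_all_empty_subject_excluded_as_nonresponse(self):
        recs = [ResponseRecord("a", p, "", "complete") for p in (3, 4, 5, 6)]
        kept, excluded = filter_valid_responses(recs)
        assert kept == [] and excluded == [("a", "nonresponse")]

    def test_any_ongoing_record_excludes_subject(self):
        recs = [
            ResponseRecord("a", 3, "text", "complete"),
            ResponseRecord("a", 4, "text", "ongoing"),
        ]
        kept, excluded = filter_valid_responses(recs)
        assert kept == [] and excluded == [("a", "ongoing")]

    def test_partial_responder_kept(self):
        recs = [
            ResponseRecord("a", 3, "syncope", "complete"),
            ResponseRecord("a", 4, "", "complete"),
        ]
        kept, excluded = filter_valid_responses(recs)
        assert len(kept) == 2 and excluded == []

    def test_empty_corpus(self):
        assert filter_valid_responses([]) == ([], [])

    def test_mixed_corpus_counts_by_reason(self):
        recs = []
        for sid in ("k1", "k2"):
            recs += [ResponseRecord(sid, p, "syncope", "complete") for p in (3, 4)]
        recs += [ResponseRecord("o1", 3, "x", "ongoing")]
        recs += [ResponseRecord("n1", p, " ", "complete") for p in (3, 4, 5, 6)]
        kept, excluded = filter_valid_responses(recs)
        assert {r.subject_id for r in kept} == {"k1", "k2"}
        assert sorted(excluded) == [("n1", "nonresponse"), ("o1", "ongoing")]


class TestMatchConcept:
    def test_single_token_accept_found_amid_fillers(self):
        tokens = ("medications", ":", " ", "amlodipine")
        matched, span = match_concept(tokens, {("amlodipine",)})
        assert matched and span == (3, 4)

    def test_out_of_list_word_never_matches(self):
        tokens = ("perform", " ", "echo")
        accepts = {("echocardiography",), ("cardiac", " ", "ultrasound")}
        matched, span = match_concept(tokens, accepts)
        assert not matched and span is None

    def test_multi_token_accept_requires_contiguity(self):
        accepts = {("cardiac", " ", "ultrasound")}
        assert match_concept(("cardiac", " ", "ultrasound"), accepts)[0]
        assert not match_concept(("cardiac", " ", "big", " ", "ultrasound"), accepts)[0]

    def test_empty_tokens_never_match(self):
        assert match_concept((), {("x",)}) == (False, None)

    def test_empty_accepts_forbidden(self):
        with pytest.raises(ValidationError):
            match_concept(("x",), set())

    def test_leftmost_match_reported(self):
        tokens = ("b", "a", "c", "a")
        matched, span = match_concept(tokens, {("a",), ("c", "a")})
        assert matched and span == (1, 2)


class TestScoreCorpus:
    def test_full_coverage_subject_totals_18(self, noiseless_bundle):
        b = noiseless_bundle
        ckey = compile_answer_key(b.answer_key, b.lexicon)
        sheet = score_corpus(b.responses, ckey, b.lexicon)
        assert all(sheet.total(s) == TOTAL_MAX for s in sheet.subjects)

    def test_missing_part_scores_zero_for_that_part(self, noiseless_bundle):
        b = noiseless_bundle
        ckey = compile_answer_key(b.answer_key, b.lexicon)
        partial = [r for r in b.responses if not (r.subject_id == "s001" and r.part == 5)]
        sheet = score_corpus(partial, ckey, b.lexicon)
        assert sheet.part_subtotal("s001", 5) == 0
        assert sheet.part_subtotal("s001", 3) == PART_MAX[3]

    def test_repeated_accept_word_still_one_point(self, noiseless_bundle):
        b = noiseless_bundle
        ckey = compile_answer_key(b.answer_key, b.lexicon)
        recs = [ResponseRecord("r", 3, "syncope syncope syncope syncope syncope", "complete")]
        sheet = score_corpus(recs, ckey, b.lexicon)
        assert sheet.point("r", "3-5") == 1
        assert sheet.total("r") == 1

    def test_part_locality(self, default_bundle, compiled_default):
        b = default_bundle
        sheet = score_corpus(b.responses, compiled_default, b.lexicon)
        edited = [
            ResponseRecord(r.subject_id, r.part, "" if r.part == 4 else r.text, r.status)
            for r in b.responses
        ]
        sheet2 = score_corpus(edited, compiled_default, b.lexicon)
        for (sid, qid), v in sheet.cells.items():
            if not qid.startswith("4-"):
                assert sheet2.cells[(sid, qid)] == v
            else:
                assert sheet2.cells[(sid, qid)] == 0

    def test_monotone_in_accept_strings(self, default_bundle):
        """Adding an accept string never decreases any cell."""
        import json

        b = default_bundle
        doc = json.loads(dump_answer_key(b.answer_key))
        base_ckey = compile_answer_key(b.answer_key, b.lexicon)
        base_sheet = score_corpus(b.responses, base_ckey, b.lexicon)
        for q in doc["questions"]:
            if q["id"] == "3-5":
                q["accept"].append("blackout")  # the oov synonym now counts
        widened = load_answer_key(json.dumps(doc))
        wide_sheet = score_corpus(
            b.responses, compile_answer_key(widened, b.lexicon), b.lexicon
        )
        assert all(
            wide_sheet.cells[cell] >= v for cell, v in base_sheet.cells.items()
        )
        assert all(
            wide_sheet.total(s) >= base_sheet.total(s) for s in base_sheet.subjects
        )

    def test_rescoring_is_idempotent(self, default_bundle, compiled_default):
        b = default_bundle
        s1 = score_corpus(b.responses, compiled_default, b.lexicon)
        s2 = score_corpus(b.responses, compiled_default, b.lexicon)
        assert s1 == s2

    def test_subtotals_within_part_bounds(self, default_bundle, compiled_default):
        b = default_bundle
        sheet = score_corpus(b.responses, compiled_default, b.lexicon)
        for s in sheet.subjects:
            for p, mx in PART_MAX.items():
                assert 0 <= sheet.part_subtotal(s, p) <= mx
            assert 0 <= sheet.total(s) <= TOTAL_MAX
            assert sheet.total(s) == sum(sheet.part_subtotal(s, p) for p in PART_MAX)


class TestScoreSheetIO:
    def test_tsv_round_trip(self, default_bundle):
        sheet = default_bundle.truth_machine
        buf = io.StringIO()
        sheet.to_tsv(buf)
        buf.seek(0)
        reloaded = load_score_sheet(buf)
        assert reloaded.cells == dict(sheet.cells)

    def test_frame_has_subtotal_columns(self, default_bundle):
        df = default_bundle.truth_machine.to_frame()
        for col in ("part3", "part4", "part5", "part6", "total"):
            assert col in df.columns
        assert (df["total"] == df[["part3", "part4", "part5", "part6"]].sum(axis=1)).all()

    def test_invalid_cell_value_rejected(self):
        with pytest.raises(ValidationError):
            ScoreSheet(("a",), ("3-1",), {("a", "3-1"): 2})

    def test_cell_set_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            ScoreSheet(("a", "b"), ("3-1",), {("a", "3-1"): 1})
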