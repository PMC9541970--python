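"""Phrase matching, code matching and encounter classification."""

import dataclasses

import numpy as np
import pytest
from sklearn.base import clone

from ipvdetect.detector import (
    DiagnosisCode,
    Encounter,
    IPVDetector,
    Note,
    classify_corpus,
    classify_encounter,
    match_icd,
    match_terms,
    preprocess_note,
)
from ipvdetect.lexicons import TermLexicon, load_default_codes


def note_encounter(text, eid="e1", pid="p1", codes=()):
    return Encounter(
        encounter_id=eid,
        patient_id=pid,
        diagnosis_codes=list(codes),
        notes=[Note(note_id=f"{eid}-n0", encounter_id=eid, text=text)],
    )


class TestMatchTerms:
    def test_simple_phrase_match(self, resources):
        seq = preprocess_note("assault by husband", resources, note_id="n")
        matches = match_terms(seq, resources.situational)
        assert [m.phrase for m in matches] == ["assault by husband"]
        assert matches[0].tier == "situational"
        assert matches[0].note_id == "n"

    def test_negated_phrase_suppressed(self, resources):
        seq = preprocess_note("patient denies domestic violence.", resources)
        assert match_terms(seq, resources.situational) == []

    def test_extended_abbreviation_match(self, resources):
        seq = preprocess_note("attack by gf", resources)
        matches = match_terms(seq, resources.combined)
        assert "attack by gf" in [m.phrase for m in matches]

    def test_inflected_temporal_form_matches(self, resources):
        seq = preprocess_note("assaulted last night by her husband", resources)
        assert [m.phrase for m in match_terms(seq, resources.situational)] == [
            "assault by husband"
        ]

    def test_overlapping_matches_all_reported(self, resources):
        # "intimate partner violence" contains no sub-phrase, but "domestic
        # violence resources" overlaps "domestic violence"
        seq = preprocess_note("domestic violence resources provided", resources)
        phrases = {m.phrase for m in match_terms(seq, resources.combined)}
        assert {"domestic violence", "domestic violence resources"} <= phrases

    def test_whole_token_matching_only(self, resources):
        # "ipv" must not fire inside another token
        seq = preprocess_note("hipvac applied to wound", resources)
        assert match_terms(seq, resources.combined) == []

    def test_exclusion_context_vetoes_match(self, resources):
        seq = preprocess_note("ipv vaccine administered", resources)
        assert match_terms(seq, resources.combined) != []
        assert (
            match_terms(seq, resources.combined, exclusions=("ipv vaccine",)) == []
        )

    def test_history_wrapped_phrase_suppressed(self, resources):
        seq = preprocess_note("hx of domestic violence.", resources)
        assert match_terms(seq, resources.combined) == []


class TestMatchIcd:
    def test_tagged_code_matches(self):
        codes = load_default_codes()
        assert match_icd([DiagnosisCode("T76.21XA", 10)], codes) == ["T7621XA"]

    def test_non_member(self):
        assert match_icd([DiagnosisCode("I10", 10)], load_default_codes()) == []

    def test_icd9_dotted(self):
        assert match_icd(["995.81"], load_default_codes()) == ["99581"]

    def test_unparseable_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = match_icd(["", None, "T74.11XA"], load_default_codes())
        assert out == ["T7411XA"]
        assert "unparseable" in caplog.text

    def test_dict_codes(self):
        out = match_icd([{"code": "t74.11xa", "revision": 10}], load_default_codes())
        assert out == ["T7411XA"]


class TestClassifyEncounter:
    def test_tier_membership_decides(self, resources):
        enc = note_encounter("strangle by partner")
        assert not classify_encounter(enc, "situational", resources).label
        assert classify_encounter(enc, "extended", resources).label

    def test_icd_only_encounter(self, resources):
        enc = Encounter(
            encounter_id="e1", patient_id="p1",
            diagnosis_codes=[DiagnosisCode("T74.11XA", 10)],
        )
        res = classify_encounter(enc, "icd", resources)
        assert res.label and res.evidence == ["T7411XA"]

    def test_empty_encounter_negative_everywhere(self, resources):
        enc = Encounter(encounter_id="e1", patient_id="p1")
        for approach in ("icd", "situational", "extended"):
            res = classify_encounter(enc, approach, resources)
            assert not res.label and res.evidence == []

    def test_label_iff_evidence(self, resources):
        for text in ("assault by husband", "ankle sprain after fall"):
            res = classify_encounter(note_encounter(text), "extended", resources)
            assert res.label == bool(res.evidence)

    def test_unknown_approach_rejected(self, resources):
        with pytest.raises(ValueError, match="unknown approach"):
            classify_encounter(note_encounter("x"), "bogus", resources)

    def test_any_note_any_hit_aggregation(self, resources):
        enc = Encounter(
            encounter_id="e1", patient_id="p1",
            notes=[
                Note("n0", "e1", text="ankle sprain."),
                Note("n1", "e1", text="assault by spouse."),
            ],
        )
        res = classify_encounter(enc, "situational", resources)
        assert res.label and res.evidence[0].note_id == "n1"


class TestClassifyCorpus:
    def test_summary_counts(self, resources):
        encounters = [
            note_encounter("assault by husband", "e1", "pA"),
            note_encounter("attack by gf", "e2", "pA"),
            note_encounter("ankle pain", "e3", "pB"),
        ]
        _, summary = classify_corpus(encounters, "extended", resources)
        assert (summary.n_encounters, summary.n_positive,
                summary.n_patients_positive) == (3, 2, 1)

    def test_empty_corpus(self, resources):
        results, summary = classify_corpus([], "extended", resources)
        assert results == []
        assert (summary.n_encounters, summary.n_positive,
                summary.n_patients_positive) == (0, 0, 0)

    def test_duplicate_encounter_id_hard_error(self, resources):
        encounters = [note_encounter("x", "e1"), note_encounter("y", "e1")]
        with pytest.raises(ValueError, match="e1"):
            classify_corpus(encounters, "extended", resources)

    def test_deterministic(self, resources):
        encounters = [note_encounter("assault by husband", "e1")]
        a, _ = classify_corpus(encounters, "extended", resources)
        b, _ = classify_corpus(encounters, "extended", resources)
        assert a == b

    def test_added_phrases_never_flip_positive_to_negative(self, resources):
        enc = note_encounter("assault by husband")
        base = classify_encounter(enc, "situational", resources)
        grown = dataclasses.replace(
            resources,
            situational=TermLexicon.from_phrases(
                "situational",
                resources.situational.phrase_texts() + ["brand new phrase"],
            ),
        )
        assert base.label
        assert classify_encounter(enc, "situational", grown).label


class TestIPVDetectorEstimator:
    def test_fit_predict(self):
        det = IPVDetector(approach="extended").fit()
        X = [
            note_encounter("assaulted last night by her husband", "e1"),
            note_encounter("patient denies domestic violence.", "e2"),
        ]
        pred = det.predict(X)
        assert pred.dtype == bool
        assert pred.tolist() == [True, False]

    def test_accepts_dict_encounters(self):
        det = IPVDetector().fit()
        obj = {
            "encounter_id": "e1",
            "patient_id": "p1",
            "notes": [{"note_id": "n0", "text": "attack by bf"}],
        }
        assert det.predict([obj]).tolist() == [True]

    def test_chief_complaint_searched(self):
        det = IPVDetector().fit()
        obj = {"encounter_id": "e1", "patient_id": "p1",
               "chief_complaint": "domestic assault"}
        assert det.predict([obj]).tolist() == [True]

    def test_sklearn_param_protocol(self):
        det = IPVDetector(approach="situational", faithful_table3=True)
        cloned = clone(det)
        assert cloned.get_params()["approach"] == "situational"
        cloned.set_params(approach="icd")
        assert cloned.approach == "icd"

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            IPVDetector().predict([note_encounter("x")])

    def test_bad_approach_rejected_at_fit(self):
        with pytest.raises(ValueError):
            IPVDetector(approach="bogus").fit()

    def test_classes_attribute(self):
        det = IPVDetector().fit()
        assert np.array_equal(det.classes_, np.array([False, True]))
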