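"""Encounter classification: phrase matching, code matching, approaches.

Three approaches label an emergency-department encounter as IPV-related:

* ``icd`` — at least one IPV-related ICD-9/ICD-10 code on the encounter;
* ``situational`` — any clinical note contains one of the 23 situational
  term phrases after pre-processing and scope suppression;
* ``extended`` — as above, over the union of the 23 situational and 49
  extended situational phrases.

An encounter is positive the moment any note (or the structured code list)
yields one piece of unsuppressed evidence; there is no scoring or ranking.

The sklearn-style :class:`IPVDetector` wraps the whole pipeline: ``fit``
compiles the packaged rule resources, ``predict`` maps encounters to boolean
labels. :class:`NoteAnnotator` is the transformer counterpart for debugging
scope annotations on raw text.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .lexicons import (
    CodeSet,
    ScopingConfig,
    TermLexicon,
    combined_lexicon,
    load_default_codes,
    load_default_lexicon,
    load_normalization_config,
    load_scoping_config,
    normalize_code,
    protected_function_words,
)
from .preprocess import (
    NormalizationConfig,
    TokenSequence,
    normalize,
    normalize_word,
    strip_punctuation,
    strip_template_blocks,
    tokenize,
)
from .scoping import mark_history, mark_negation, render_annotated

__all__ = [
    "Note",
    "Encounter",
    "DiagnosisCode",
    "TermMatch",
    "EncounterResult",
    "CorpusSummary",
    "RuleResources",
    "APPROACHES",
    "load_default_resources",
    "preprocess_note",
    "match_terms",
    "match_icd",
    "classify_encounter",
    "classify_corpus",
    "IPVDetector",
    "NoteAnnotator",
]

logger = logging.getLogger(__name__)

APPROACHES = ("icd", "situational", "extended")
AUTHOR_ROLES = ("physician_app", "nursing", "social_work", "other")


@dataclass(frozen=True)
class DiagnosisCode:
    """One coded diagnosis; revision is 9, 10, or None (unknown)."""

    code: str
    revision: int | None = None


@dataclass
class Note:
    note_id: str
    encounter_id: str
    author_role: str = "other"
    text: str = ""


@dataclass
class Encounter:
    """One ED visit: structured codes plus free-text notes.

    The chief-complaint field, when present, is treated as one more note
    with ``author_role="other"``.
    """

    encounter_id: str
    patient_id: str
    visit_date: datetime.date | None = None
    diagnosis_codes: list = field(default_factory=list)
    notes: list = field(default_factory=list)


@dataclass(frozen=True)
class TermMatch:
    """One unsuppressed lexicon-phrase occurrence inside a note."""

    phrase: str
    tier: str
    note_id: str
    span: tuple  # (first token index, last token index), original positions


@dataclass
class EncounterResult:
    encounter_id: str
    approach: str
    label: bool
    evidence: list = field(default_factory=list)  # TermMatch and/or code strings


@dataclass(frozen=True)
class CorpusSummary:
    n_encounters: int
    n_positive: int
    n_patients_positive: int


@dataclass
class RuleResources:
    """Compiled resource bundle driving all three approaches."""

    codes: CodeSet
    situational: TermLexicon
    extended_only: TermLexicon
    combined: TermLexicon
    scoping: ScopingConfig
    norm: NormalizationConfig
    template_patterns: tuple = ()
    strip_templates: bool = True
    term_exclusions: tuple = ()  # phrases like "ipv vaccine"; off by default

    def lexicon_for(self, approach: str) -> TermLexicon:
        return self.situational if approach == "situational" else self.combined


def load_default_resources(
    faithful_table3: bool = False,
    config_path=None,
    strip_templates: bool = True,
    term_exclusions: Sequence[str] = (),
) -> RuleResources:
    """Load and compile the packaged code sets, lexicons and configs.

    Function words inside lexicon phrases and the scoping cue vocabulary are
    injected into the normalizer's protected set so stop-class removal never
    destroys a matchable phrase or a cue.
    """
    situational = load_default_lexicon("situational")
    extended = load_default_lexicon("extended")
    combined = combined_lexicon(situational, extended)
    scoping = load_scoping_config(faithful_table3, config_path)
    protected = protected_function_words(combined) | scoping.cue_words()
    norm = load_normalization_config(config_path, protected_words=protected)
    return RuleResources(
        codes=load_default_codes(),
        situational=situational,
        extended_only=extended,
        combined=combined,
        scoping=scoping,
        norm=norm,
        template_patterns=norm.template_patterns,
        strip_templates=strip_templates,
        term_exclusions=tuple(term_exclusions),
    )


def preprocess_note(text: str, resources: RuleResources, note_id: str = "") -> TokenSequence:
    """Run one note through the full fixed-order pipeline.

    strip_template_blocks -> tokenize -> normalize -> mark_negation ->
    mark_history -> strip_punctuation. The result is ready for matching.
    """
    if resources.strip_templates:
        text = strip_template_blocks(text, resources.template_patterns)
    seq = tokenize(text, source_note_id=note_id)
    seq = normalize(seq, resources.norm)
    seq = mark_negation(seq, resources.scoping, resources.norm.stemming_suffixes)
    seq = mark_history(seq, resources.scoping, resources.norm.stemming_suffixes)
    return strip_punctuation(seq)


def _compile_phrases(lexicon: TermLexicon, suffixes) -> list:
    """[(normalized token tuple, phrase text)], matching space == note space."""
    return [
        (tuple(normalize_word(tok, suffixes) for tok in phrase), " ".join(phrase))
        for phrase in lexicon.terms
    ]


def _occurrences(norms: list, phrase: tuple) -> list:
    n, k = len(norms), len(phrase)
    return [i for i in range(n - k + 1) if tuple(norms[i : i + k]) == phrase]


def match_terms(
    seq: TokenSequence,
    lexicon: TermLexicon,
    suffixes=("ed", "ing", "s"),
    exclusions: Sequence[str] = (),
) -> list:
    """Every contiguous, unsuppressed occurrence of a lexicon phrase.

    Matching runs over surviving (non-removed) tokens in stemmed normalized
    space; a match is suppressed if any of its tokens is negated or flagged
    as history. Overlapping matches are all reported. ``exclusions`` are
    longer context phrases (e.g. "ipv vaccine") whose occurrences veto any
    term match fully inside them; empty by default.
    """
    surv = [t for t in seq.surviving() if t.kind == "word"]
    norms = [t.norm for t in surv]
    excl_spans = []
    for excl in exclusions:
        etoks = tuple(normalize_word(w, suffixes) for w in excl.lower().split())
        for i in _occurrences(norms, etoks):
            excl_spans.append((i, i + len(etoks) - 1))
    matches = []
    suppressed = 0
    for phrase_norm, phrase_text in _compile_phrases(lexicon, suffixes):
        for i in _occurrences(norms, phrase_norm):
            j = i + len(phrase_norm) - 1
            toks = surv[i : j + 1]
            if any(t.negated or t.in_history for t in toks):
                suppressed += 1
                continue
            if any(a <= i and j <= b for a, b in excl_spans):
                suppressed += 1
                continue
            matches.append(
                TermMatch(
                    phrase=phrase_text,
                    tier=lexicon.tier,
                    note_id=seq.source_note_id,
                    span=(toks[0].index, toks[-1].index),
                )
            )
    if suppressed:
        logger.debug(
            "note %s: %d suppressed phrase occurrence(s)", seq.source_note_id, suppressed
        )
    return matches


def _coerce_code(code) -> DiagnosisCode | None:
    if isinstance(code, DiagnosisCode):
        return code
    if isinstance(code, Mapping):
        code, revision = code.get("code", ""), code.get("revision")
    else:
        revision = None
    if not isinstance(code, str) or not code.strip():
        logger.warning("skipping unparseable diagnosis code %r", code)
        return None
    if revision is not None:
        revision = int(revision)
        if revision not in (9, 10):
            logger.warning("skipping code %r with bad revision %r", code, revision)
            return None
    return DiagnosisCode(code=code.strip(), revision=revision)


def match_icd(codes: Iterable, codeset: CodeSet) -> list:
    """Normalized encounter codes present in the IPV code set.

    Codes tagged with a revision are checked against that revision's set
    only; untagged codes are checked against both (revision tags on codes
    are more reliable than visit dates for picking the revision).
    """
    matched = []
    for raw in codes:
        dc = _coerce_code(raw)
        if dc is None:
            continue
        if codeset.contains(dc.code, dc.revision):
            matched.append(normalize_code(dc.code))
    return matched


def classify_encounter(
    enc: Encounter, approach: str, resources: RuleResources
) -> EncounterResult:
    """Label one encounter under one approach, with evidence recorded."""
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    if approach == "icd":
        evidence = match_icd(enc.diagnosis_codes, resources.codes)
    else:
        lexicon = resources.lexicon_for(approach)
        evidence = []
        for note in enc.notes:
            seq = preprocess_note(note.text, resources, note_id=note.note_id)
            evidence.extend(
                match_terms(
                    seq,
                    lexicon,
                    resources.norm.stemming_suffixes,
                    resources.term_exclusions,
                )
            )
    return EncounterResult(
        encounter_id=enc.encounter_id,
        approach=approach,
        label=bool(evidence),
        evidence=evidence,
    )


def classify_corpus(
    encounters: Iterable[Encounter], approach: str, resources: RuleResources
):
    """Classify a corpus; returns (results, summary).

    Summary counts encounters, positive encounters, and distinct patients
    with at least one positive encounter. Duplicate encounter ids are a hard
    error (the encounter is the unit of classification).
    """
    results: list[EncounterResult] = []
    seen: set[str] = set()
    positive_patients: set[str] = set()
    n_pos = 0
    for enc in encounters:
        if enc.encounter_id in seen:
            raise ValueError(f"duplicate encounter_id {enc.encounter_id!r}")
        seen.add(enc.encounter_id)
        res = classify_encounter(enc, approach, resources)
        results.append(res)
        if res.label:
            n_pos += 1
            positive_patients.add(enc.patient_id)
    summary = CorpusSummary(
        n_encounters=len(results),
        n_positive=n_pos,
        n_patients_positive=len(positive_patients),
    )
    return results, summary


def _coerce_encounter(obj) -> Encounter:
    if isinstance(obj, Encounter):
        return obj
    from .io import encounter_from_dict  # late import avoids a cycle

    return encounter_from_dict(obj)


class IPVDetector(ClassifierMixin, BaseEstimator):
    """Rule-based IPV encounter classifier with a scikit-learn surface.

    ``fit`` loads and compiles the packaged rule resources (there is nothing
    learned from data: the rules are fixed); ``predict`` takes a sequence of
    :class:`Encounter` objects (or equivalent dicts) and returns a boolean
    label per encounter.

    Parameters
    ----------
    approach : {"icd", "situational", "extended"}, default="extended"
        Evidence tier used for labeling.
    faithful_table3 : bool, default=False
        Keep "and" as a scope-termination token (published table verbatim)
        instead of the default behavior of negating through conjunctions.
    strip_templates : bool, default=True
        Remove auto-populated screening-question lines before tokenization.
    term_exclusions : sequence of str, default=()
        Context phrases (e.g. "ipv vaccine") whose occurrences veto term
        matches inside them. Off by default: the published rules carry the
        abbreviation-collision false-positive source as a known limitation.
    config_path : str or None
        Alternative scoping/normalization config file.
    """

    def __init__(
        self,
        approach: str = "extended",
        faithful_table3: bool = False,
        strip_templates: bool = True,
        term_exclusions: tuple = (),
        config_path=None,
    ):
        self.approach = approach
        self.faithful_table3 = faithful_table3
        self.strip_templates = strip_templates
        self.term_exclusions = term_exclusions
        self.config_path = config_path

    def fit(self, X=None, y=None):
        """Compile rule resources; X and y are accepted for API symmetry."""
        if self.approach not in APPROACHES:
            raise ValueError(
                f"unknown approach {self.approach!r}; expected one of {APPROACHES}"
            )
        self.resources_ = load_default_resources(
            faithful_table3=self.faithful_table3,
            config_path=self.config_path,
            strip_templates=self.strip_templates,
            term_exclusions=tuple(self.term_exclusions),
        )
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        """Boolean IPV label per encounter."""
        return np.array([r.label for r in self.predict_evidence(X)], dtype=bool)

    def predict_evidence(self, X) -> list:
        """Full :class:`EncounterResult` (label + evidence) per encounter."""
        check_is_fitted(self, "resources_")
        return [
            classify_encounter(_coerce_encounter(x), self.approach, self.resources_)
            for x in X
        ]


class NoteAnnotator(TransformerMixin, BaseEstimator):
    """Transformer: raw note text -> scope-annotated debug rendering.

    ``transform`` returns, per input text, the normalized surviving tokens
    rendered with "_neg" / "_hx" suffixes and punctuation re-attached.
    """

    def __init__(self, faithful_table3: bool = False, strip_templates: bool = False,
                 config_path=None):
        self.faithful_table3 = faithful_table3
        self.strip_templates = strip_templates
        self.config_path = config_path

    def fit(self, X=None, y=None):
        self.resources_ = load_default_resources(
            faithful_table3=self.faithful_table3,
            config_path=self.config_path,
            strip_templates=self.strip_templates,
        )
        return self

    def transform(self, X) -> list:
        check_is_fitted(self, "resources_")
        out = []
        for text in X:
            res = self.resources_
            if res.strip_templates:
                text = strip_template_blocks(text, res.template_patterns)
            seq = tokenize(text)
            seq = normalize(seq, res.norm)
            seq = mark_negation(seq, res.scoping, res.norm.stemming_suffixes)
            seq = mark_history(seq, res.scoping, res.norm.stemming_suffixes)
            out.append(render_annotated(seq))
        return out
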