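"""Synthetic labeled ED-encounter corpora for closed-loop testing.

Real IPV-related EHR data cannot be shared, so every pipeline stage is
exercised against generated corpora that exhibit exactly the text phenomena
the detector must handle: in-lexicon mentions wrapped in temporal/possessive
filler and verb inflection, negated mentions, history-of-IPV mentions,
auto-populated screening-question blocks, distractor phrases used in non-IPV
senses, and under-coded ICD fields.

Positives are machine-recoverable by construction: every positive wrapper in
the template bank is cue-free and every realized inflection is undone by the
normalizer, so with distractors and template blocks disabled the extended
approach reproduces the generated truth exactly.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from .detector import DiagnosisCode, Encounter, Note
from .lexicons import combined_lexicon, load_default_codes, load_default_lexicon

__all__ = ["SynthParams", "TruthRecord", "generate_corpus", "phrase_realizer"]

_STYLES = ("plain", "temporal_possessive", "inflected", "inflected+temporal_possessive")

# regular inflections only: each must normalize back to its head
_VERB_INFLECT = {
    "assault": "assaulted",
    "attack": "attacked",
    "strike": "striking",
    "strangle": "strangling",
}

_ICD10_SWITCH = datetime.date(2015, 10, 1)


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs; all rates are per-encounter probabilities.

    Defaults are the package's study conditions: a 1,000-encounter corpus at
    10% prevalence; an ICD coding rate of 0.013 reflecting how rarely true
    IPV encounters carry an IPV-related code; modest rates for the
    false-positive-shaped phenomena.
    """

    n_encounters: int = 1000
    prevalence: float = 0.1
    negated_mention_rate: float = 0.2
    history_mention_rate: float = 0.1
    template_block_rate: float = 0.1
    distractor_rate: float = 0.1
    icd_coding_rate: float = 0.013
    notes_per_encounter: tuple = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        for f in (
            "prevalence",
            "negated_mention_rate",
            "history_mention_rate",
            "template_block_rate",
            "distractor_rate",
            "icd_coding_rate",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        lo, hi = self.notes_per_encounter
        if not (1 <= lo <= hi):
            raise ValueError("notes_per_encounter must be a (lo, hi) range with lo >= 1")


@dataclass(frozen=True)
class TruthRecord:
    encounter_id: str
    is_ipv: bool
    phenomena: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.is_ipv and "positive_phrase" not in self.phenomena:
            raise ValueError("truth-positive encounter must carry a positive phrase")


def _load_templates() -> dict:
    import importlib.resources

    path = importlib.resources.files("ipvdetect.resources").joinpath(
        "synth_templates.yaml"
    )
    return yaml.safe_load(Path(str(path)).read_text(encoding="utf-8"))


def phrase_realizer(phrase: str, style: str = "plain") -> str:
    """Render a lexicon phrase the way it might appear in a note.

    Styles (combinable with "+"): ``plain`` keeps the phrase verbatim;
    ``temporal_possessive`` wraps it in temporal/possessive filler the
    normalizer must strip ("assault by husband" -> "assault last night by
    her husband"); ``inflected`` inflects the head verb ("assault" ->
    "assaulted") for the stemmer to undo. Only regular inflections are used
    so realization never defeats recovery.
    """
    parts = set(style.split("+"))
    unknown = parts - {"plain", "temporal_possessive", "inflected"}
    if unknown:
        raise ValueError(f"unknown realization style(s): {sorted(unknown)}")
    tokens = phrase.lower().split()
    if "inflected" in parts and tokens[0] in _VERB_INFLECT:
        tokens = [_VERB_INFLECT[tokens[0]]] + tokens[1:]
    if "temporal_possessive" in parts:
        if "by" in tokens:
            at = tokens.index("by")
            tokens = tokens[:at] + ["last", "night", "by", "her"] + tokens[at + 1 :]
        else:
            tokens = tokens + ["last", "night"]
    return " ".join(tokens)


def _pick_ipv_code(rng: random.Random, codeset, visit_date) -> DiagnosisCode:
    if visit_date >= _ICD10_SWITCH:
        return DiagnosisCode(code=rng.choice(sorted(codeset.icd10_codes)), revision=10)
    return DiagnosisCode(code=rng.choice(sorted(codeset.icd9_codes)), revision=9)


def generate_corpus(params: SynthParams):
    """Generate (encounters, truth_records), deterministic given the seed.

    Exactly ``round(prevalence * n_encounters)`` encounters are
    truth-positive (exact allocation, positions shuffled by the seed). Each
    positive embeds one uniformly chosen phrase from the combined lexicon,
    realized in a random style inside a cue-free wrapper sentence. Negative
    encounters independently receive negated mentions, history mentions,
    template blocks and distractor sentences at the configured rates.
    Truth-positive encounters carry an IPV ICD code with probability
    ``icd_coding_rate`` (revision picked by visit date).
    """
    rng = random.Random(params.seed)
    bank = _load_templates()
    lexicon = combined_lexicon(
        load_default_lexicon("situational"), load_default_lexicon("extended")
    )
    phrases = lexicon.phrase_texts()
    codeset = load_default_codes()

    n = params.n_encounters
    n_pos = round(params.prevalence * n)
    labels = [True] * n_pos + [False] * (n - n_pos)
    rng.shuffle(labels)

    n_patients = max(1, int(round(0.8 * n)))
    start = datetime.date(2012, 1, 1)
    span_days = (datetime.date(2020, 8, 31) - start).days

    encounters, truth = [], []
    for i, is_ipv in enumerate(labels):
        eid = f"E{i:06d}"
        pid = f"P{rng.randrange(n_patients):06d}"
        visit_date = start + datetime.timedelta(days=rng.randrange(span_days + 1))
        k = rng.randint(*params.notes_per_encounter)
        note_texts = [
            [rng.choice(bank["benign_sentences"])] for _ in range(k)
        ]
        codes: list[DiagnosisCode] = []
        phenomena: set[str] = set()

        if is_ipv:
            phenomena.add("positive_phrase")
            phrase = rng.choice(phrases)
            style = rng.choice(_STYLES)
            wrapper = rng.choice(bank["positive_wrappers"])
            sentence = wrapper.format(m=phrase_realizer(phrase, style))
            note_texts[rng.randrange(k)].append(sentence)
            if rng.random() < params.icd_coding_rate:
                codes.append(_pick_ipv_code(rng, codeset, visit_date))
                phenomena.add("icd_coded")
        else:
            if rng.random() < params.negated_mention_rate:
                note_texts[rng.randrange(k)].append(rng.choice(bank["negated_sentences"]))
                phenomena.add("negated")
            if rng.random() < params.history_mention_rate:
                note_texts[rng.randrange(k)].append(rng.choice(bank["history_sentences"]))
                phenomena.add("history")
            if rng.random() < params.template_block_rate:
                block = rng.choice(bank["template_blocks"])
                ans = rng.choice(bank["template_answers"])
                note_texts[rng.randrange(k)].append(block.replace("{a}", ans))
                phenomena.add("template")
            if rng.random() < params.distractor_rate:
                note_texts[rng.randrange(k)].append(
                    rng.choice(bank["distractor_sentences"])
                )
                phenomena.add("distractor")

        # benign structured codes on some encounters either way
        if rng.random() < 0.5:
            pool = (
                bank["benign_codes_icd10"]
                if visit_date >= _ICD10_SWITCH
                else bank["benign_codes_icd9"]
            )
            codes.append(
                DiagnosisCode(
                    code=rng.choice(pool),
                    revision=10 if visit_date >= _ICD10_SWITCH else 9,
                )
            )

        notes = [
            Note(
                note_id=f"{eid}-n{j}",
                encounter_id=eid,
                author_role=rng.choice(
                    ("physician_app", "nursing", "social_work", "other")
                ),
                text="\n".join(text),
            )
            for j, text in enumerate(note_texts)
        ]
        encounters.append(
            Encounter(
                encounter_id=eid,
                patient_id=pid,
                visit_date=visit_date,
                diagnosis_codes=codes,
                notes=notes,
            )
        )
        truth.append(
            TruthRecord(encounter_id=eid, is_ipv=is_ipv, phenomena=frozenset(phenomena))
        )
    return encounters, truth
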