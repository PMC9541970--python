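"""Packaged rule resources: ICD code sets, term lexicons, scoping config.

Three tiers of evidence drive encounter classification:

* an IPV-related ICD-9/ICD-10 code set (structured diagnosis fields),
* 23 situational term phrases (literature / risk-assessment derived),
* 49 extended situational term phrases (mechanism-specific, mined from
  confirmed cases).

Everything ships as editable plain-text resources and is validated on load.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

from .preprocess import NormalizationConfig

__all__ = [
    "CodeSet",
    "TermLexicon",
    "ScopingConfig",
    "ResourceError",
    "normalize_code",
    "load_default_codes",
    "load_default_lexicon",
    "combined_lexicon",
    "load_scoping_config",
    "load_normalization_config",
    "load_template_patterns",
    "protected_function_words",
    "FUNCTION_WORDS",
]

TIERS = ("situational", "extended")

# closed-class words that may occur inside lexicon phrases and must therefore
# survive stop-class removal
FUNCTION_WORDS = frozenset(
    "a an and at by for from in of on or the to with against as".split()
)


class ResourceError(RuntimeError):
    """A packaged resource is missing or corrupt; message names the path."""


def _resource_path(name: str) -> Path:
    path = importlib.resources.files("ipvdetect.resources").joinpath(name)
    return Path(str(path))


def _read_resource_lines(name: str) -> list[str]:
    path = _resource_path(name)
    try:
        raw = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ResourceError(f"cannot read packaged resource {path}") from exc
    lines = []
    for line in raw.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            lines.append(line)
    return lines


def normalize_code(code: str) -> str:
    """Canonical diagnosis-code form: uppercase, dot separators stripped."""
    return code.replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class CodeSet:
    """IPV-related ICD-9 and ICD-10 diagnosis codes.

    Codes are stored dot-stripped and uppercased so membership is invariant
    to case and dot usage ("995.81" and "99581" both match).
    """

    icd9_codes: frozenset
    icd10_codes: frozenset

    def __post_init__(self) -> None:
        if any(not c for c in self.icd9_codes | self.icd10_codes):
            raise ValueError("empty code string in CodeSet")
        shared = self.icd9_codes & self.icd10_codes
        if shared:
            raise ValueError(f"codes present in both revisions: {sorted(shared)}")

    def __contains__(self, code: str) -> bool:
        norm = normalize_code(code)
        return norm in self.icd9_codes or norm in self.icd10_codes

    def contains(self, code: str, revision: int | None = None) -> bool:
        """Membership test; restricted to one revision when given."""
        norm = normalize_code(code)
        if revision == 9:
            return norm in self.icd9_codes
        if revision == 10:
            return norm in self.icd10_codes
        return norm in self.icd9_codes or norm in self.icd10_codes


@dataclass(frozen=True)
class TermLexicon:
    """One tier of term phrases, each a tuple of lowercase word tokens."""

    tier: str
    terms: tuple  # tuple[tuple[str, ...], ...], ordered
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; expected one of {TIERS}")
        seen = set()
        for phrase in self.terms:
            if len(phrase) < 1:
                raise ValueError("empty phrase in lexicon")
            for tok in phrase:
                if tok != tok.lower():
                    raise ValueError(f"non-lowercase token {tok!r} in lexicon")
            if phrase in seen:
                raise ValueError(f"duplicate phrase {' '.join(phrase)!r} in tier")
            seen.add(phrase)

    def __len__(self) -> int:
        return len(self.terms)

    def phrase_texts(self) -> list[str]:
        return [" ".join(p) for p in self.terms]

    def dump(self, path: str | Path) -> None:
        """Serialize one phrase per line (round-trips through ``from_file``)."""
        Path(path).write_text(
            "\n".join(self.phrase_texts()) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_phrases(
        cls, tier: str, phrases: Iterable[str], source_label: str = ""
    ) -> "TermLexicon":
        terms = tuple(tuple(p.lower().split()) for p in phrases)
        return cls(tier=tier, terms=terms, source_label=source_label)

    @classmethod
    def from_file(cls, path: str | Path, tier: str, source_label: str = "") -> "TermLexicon":
        lines = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                lines.append(line)
        return cls.from_phrases(tier, lines, source_label or str(path))


@dataclass(frozen=True)
class ScopingConfig:
    """Cue vocabularies for negation and history scoping.

    ``history_cues`` are token tuples ordered longest-first so multi-token
    cues ("h/o of") are never shadowed by their prefixes ("h/o").
    """

    negation_cues: frozenset
    termination_tokens: frozenset
    history_cues: tuple  # tuple[tuple[str, ...], ...], longest first
    faithful_table3: bool = False

    def __post_init__(self) -> None:
        overlap = self.negation_cues & self.termination_tokens
        if overlap:
            raise ValueError(
                f"negation cues and termination tokens overlap: {sorted(overlap)}"
            )
        for tok in self.termination_tokens:
            word = tok.isalpha() and tok == tok.lower()
            punct = len(tok) == 1 and not tok.isalnum()
            if not (word or punct):
                raise ValueError(f"bad termination token {tok!r}")
        lengths = [len(c) for c in self.history_cues]
        if lengths != sorted(lengths, reverse=True):
            raise ValueError("history cues must be ordered longest-first")

    def without_cues(self, cues: Iterable[str]) -> "ScopingConfig":
        """Disable individual cues (e.g. the ambiguous standalone "ho")."""
        drop = set(cues)
        return ScopingConfig(
            negation_cues=self.negation_cues - drop,
            termination_tokens=self.termination_tokens - drop,
            history_cues=tuple(
                c for c in self.history_cues if " ".join(c) not in drop
            ),
            faithful_table3=self.faithful_table3,
        )

    def cue_words(self) -> frozenset:
        """Every word token used by scoping (protected from stop removal)."""
        words = {w for w in self.negation_cues if w.isalpha()}
        words |= {w for w in self.termination_tokens if w.isalpha()}
        for cue in self.history_cues:
            words.update(cue)
        return frozenset(words)


def load_default_codes() -> CodeSet:
    """Load the packaged ICD code sets (7 unique ICD-9, 9 ICD-10 codes)."""
    icd9, icd10 = set(), set()
    for line in _read_resource_lines("icd_codes.tsv"):
        parts = line.split("\t")
        if len(parts) != 2 or parts[1] not in ("9", "10"):
            raise ResourceError(
                f"corrupt line {line!r} in {_resource_path('icd_codes.tsv')}"
            )
        (icd9 if parts[1] == "9" else icd10).add(normalize_code(parts[0]))
    return CodeSet(icd9_codes=frozenset(icd9), icd10_codes=frozenset(icd10))


_TIER_FILES = {
    "situational": "situational_terms.txt",
    "extended": "extended_terms.txt",
}


def load_default_lexicon(tier: str) -> TermLexicon:
    """Load the packaged phrase list for one tier, tokenized and lowercased."""
    if tier not in _TIER_FILES:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    phrases = _read_resource_lines(_TIER_FILES[tier])
    return TermLexicon.from_phrases(tier, phrases, source_label=_TIER_FILES[tier])


def combined_lexicon(a: TermLexicon, b: TermLexicon) -> TermLexicon:
    """Union of two lexicons, order-preserving, duplicates removed.

    Mixed tiers are recorded as "extended" (the union drives the widest
    detection approach).
    """
    terms = list(a.terms)
    seen = set(terms)
    for phrase in b.terms:
        if phrase not in seen:
            terms.append(phrase)
            seen.add(phrase)
    tier = a.tier if a.tier == b.tier else "extended"
    label = " + ".join(s for s in (a.source_label, b.source_label) if s)
    return TermLexicon(tier=tier, terms=tuple(terms), source_label=label)


def protected_function_words(lexicon: TermLexicon) -> frozenset:
    """Function words occurring inside lexicon phrases.

    Stop-class removal must never delete these, or multi-word phrases like
    "assault by husband" could never match.
    """
    tokens = {tok for phrase in lexicon.terms for tok in phrase}
    return frozenset(tokens & FUNCTION_WORDS)


def _load_config_mapping(config_path: str | Path | None) -> dict:
    if config_path is None:
        path = _resource_path("default_config.yaml")
    else:
        path = Path(config_path)
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except OSError as exc:
        raise ResourceError(f"cannot read config {path}") from exc
    if not isinstance(data, dict):
        raise ResourceError(f"config {path} is not a mapping")
    return data


def load_scoping_config(
    faithful_table3: bool = False, config_path: str | Path | None = None
) -> ScopingConfig:
    """Load negation/termination/history cue sets.

    The default mode excludes "and" from the termination tokens so negation
    scopes extend through conjunctions, reproducing the canonical annotated
    example; ``faithful_table3=True`` keeps the published set verbatim.
    """
    raw = _load_config_mapping(config_path)["scoping"]
    termination = set(raw["termination_tokens"])
    if not faithful_table3:
        termination.discard("and")
    cues = tuple(tuple(c.lower().split()) for c in raw["history_cues"])
    cues = tuple(sorted(cues, key=len, reverse=True))
    return ScopingConfig(
        negation_cues=frozenset(w.lower() for w in raw["negation_cues"]),
        termination_tokens=frozenset(termination),
        history_cues=cues,
        faithful_table3=faithful_table3,
    )


def load_normalization_config(
    config_path: str | Path | None = None,
    protected_words: Iterable[str] = (),
) -> NormalizationConfig:
    """Load stop classes / stemming settings; inject protected words."""
    raw = _load_config_mapping(config_path)
    norm = raw["normalization"]
    return NormalizationConfig(
        temporal_stopwords=frozenset(norm["temporal_stopwords"]),
        preposition_stopwords=frozenset(norm["preposition_stopwords"]),
        pronoun_stopwords=frozenset(norm["pronoun_stopwords"]),
        protected_words=frozenset(protected_words),
        min_word_length=int(norm["min_word_length"]),
        stemming_suffixes=tuple(norm["stemming_suffixes"]),
        template_patterns=tuple(raw.get("template_patterns", ())),
    )


def load_template_patterns(config_path: str | Path | None = None) -> tuple:
    return tuple(_load_config_mapping(config_path).get("template_patterns", ()))
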