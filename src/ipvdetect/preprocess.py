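"""Note-text pre-processing: tokenization and normalization.

Clinical notes reach the matcher in a canonical form: lowercased, light-stemmed
word tokens with numbers, sub-minimum-length words and temporal / preposition /
pronoun stop classes marked as removed. Punctuation tokens are retained through
the scoping stage (they serve as scope terminators) and only stripped at the
end of the pipeline.

The fixed stage order is::

    strip_template_blocks -> tokenize -> normalize
        -> mark_negation -> mark_history -> strip_punctuation -> match

Punctuation removal deliberately happens after history detection.
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Token",
    "TokenSequence",
    "NormalizationConfig",
    "TemplatePatternError",
    "normalize_word",
    "tokenize",
    "strip_template_blocks",
    "normalize",
    "strip_punctuation",
]

# words: letter runs, optionally slash-joined ("h/o", "h/x"); numbers: digit
# runs with optional internal separators; anything else: single-char punct
_TOKEN_RE = re.compile(r"[A-Za-z]+(?:/[A-Za-z]+)*|\d+(?:[\d.,:/-]*\d)?|\S")


@dataclass
class Token:
    """One annotated unit of note text.

    ``norm`` is the canonical matching form (lowercased, light-stemmed for
    word tokens). ``removed`` tokens never participate in matching or
    scoping; ``negated`` / ``in_history`` suppress term matches.
    """

    surface: str
    norm: str
    kind: str  # "word" | "punct" | "number"
    index: int
    removed: bool = False
    negated: bool = False
    in_history: bool = False


@dataclass
class TokenSequence:
    """Ordered tokens of one note; indices are positions in original order."""

    tokens: list[Token] = field(default_factory=list)
    source_note_id: str = ""

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def surviving(self) -> list[Token]:
        """Tokens still participating (not marked removed)."""
        return [t for t in self.tokens if not t.removed]

    def surviving_norms(self) -> list[str]:
        return [t.norm for t in self.surviving()]

    def copy(self) -> "TokenSequence":
        return TokenSequence([replace(t) for t in self.tokens], self.source_note_id)


@dataclass
class NormalizationConfig:
    """Stop classes, length threshold and stemming suffixes.

    ``protected_words`` (tokens occurring inside active lexicon phrases or
    scoping cues) are never removed regardless of the other rules.
    """

    temporal_stopwords: frozenset = frozenset()
    preposition_stopwords: frozenset = frozenset()
    pronoun_stopwords: frozenset = frozenset()
    protected_words: frozenset = frozenset()
    min_word_length: int = 2
    stemming_suffixes: tuple = ("ed", "ing", "s")
    template_patterns: tuple = ()

    def __post_init__(self) -> None:
        if self.min_word_length < 1:
            raise ValueError("min_word_length must be >= 1")
        # stop sets are compared against stemmed norms, so stem them too
        self.temporal_stopwords = frozenset(
            normalize_word(w, self.stemming_suffixes) for w in self.temporal_stopwords
        )
        self.preposition_stopwords = frozenset(
            normalize_word(w, self.stemming_suffixes) for w in self.preposition_stopwords
        )
        self.pronoun_stopwords = frozenset(
            normalize_word(w, self.stemming_suffixes) for w in self.pronoun_stopwords
        )
        self.protected_words = frozenset(
            normalize_word(w, self.stemming_suffixes) for w in self.protected_words
        )

    def with_protected(self, words: Iterable[str]) -> "NormalizationConfig":
        """New config with ``words`` added to the protected set."""
        return NormalizationConfig(
            temporal_stopwords=self.temporal_stopwords,
            preposition_stopwords=self.preposition_stopwords,
            pronoun_stopwords=self.pronoun_stopwords,
            protected_words=self.protected_words | frozenset(words),
            min_word_length=self.min_word_length,
            stemming_suffixes=self.stemming_suffixes,
            template_patterns=self.template_patterns,
        )


class TemplatePatternError(ValueError):
    """A configured template pattern is unusable; names the pattern."""


def _strip_once(word: str, suffixes: Sequence[str]) -> str:
    for suf in suffixes:
        if word.endswith(suf) and len(word) - len(suf) >= 3:
            # keep plural-looking but non-plural endings intact
            if suf == "s" and word[-2:] in ("ss", "us", "is"):
                continue
            return word[: -len(suf)]
    if len(word) >= 4 and word.endswith("e") and not word.endswith("ee"):
        return word[:-1]
    return word


def normalize_word(word: str, suffixes: Sequence[str] = ("ed", "ing", "s")) -> str:
    """Canonical matching form of a word: lowercase + light suffix stemming.

    Strips ``ed``/``ing``/``s`` when a stem of >= 3 characters remains, then a
    final ``e`` (length >= 4, not ``ee``), iterated to a fixpoint so inflected
    surface forms and their lexicon heads meet in one normalized space
    ("assaulted" -> "assault", and both "strangled" and "strangle" ->
    "strangl"). Fixpoint iteration makes the function idempotent.
    """
    w = word.lower()
    while True:
        nxt = _strip_once(w, suffixes)
        if nxt == w:
            return w
        w = nxt


def tokenize(text: str, source_note_id: str = "") -> TokenSequence:
    """Segment text into word / number / punctuation tokens.

    Whitespace is collapsed and discarded; original order is preserved.
    Slash-joined letter groups ("h/o") stay single word tokens.
    """
    tokens: list[Token] = []
    for i, m in enumerate(_TOKEN_RE.finditer(text)):
        surface = m.group(0)
        if surface[0].isdigit():
            kind = "number"
        elif surface[0].isalpha():
            kind = "word"
        else:
            kind = "punct"
        tokens.append(Token(surface=surface, norm=surface.lower(), kind=kind, index=i))
    return TokenSequence(tokens, source_note_id)


def _compile_patterns(patterns: Sequence[str]):
    compiled = []
    for pat in patterns:
        if not isinstance(pat, str) or not pat.strip():
            raise TemplatePatternError(f"invalid template pattern: {pat!r}")
        try:
            compiled.append(re.compile(fnmatch.translate(pat.lower())))
        except re.error as exc:  # pragma: no cover - fnmatch output is regular
            raise TemplatePatternError(f"invalid template pattern: {pat!r}") from exc
    return compiled


def strip_template_blocks(text: str, patterns: Sequence[str]) -> str:
    """Drop every line matching a configured pattern before tokenization.

    Patterns are shell-style wildcards matched case-insensitively against the
    stripped line, so auto-populated screening-question lines are removed
    whether completed or blank.
    """
    compiled = _compile_patterns(patterns)
    if not compiled:
        return text
    kept = [
        line
        for line in text.splitlines()
        if not any(rx.match(line.strip().lower()) for rx in compiled)
    ]
    return "\n".join(kept)


def normalize(seq: TokenSequence, cfg: NormalizationConfig) -> TokenSequence:
    """Apply general and task-specific normalization in place of matching form.

    Lowercases and stems word tokens; marks as removed: number tokens, word
    tokens shorter than ``min_word_length`` characters, and stop-class words —
    unless the normalized form is protected. Punctuation is retained (it
    terminates negation/history scopes downstream).
    """
    stop = cfg.temporal_stopwords | cfg.preposition_stopwords | cfg.pronoun_stopwords
    out = seq.copy()
    for tok in out.tokens:
        if tok.kind == "punct":
            tok.norm = tok.surface
            continue
        if tok.kind == "number":
            tok.norm = tok.surface
            tok.removed = True
            continue
        tok.norm = normalize_word(tok.surface, cfg.stemming_suffixes)
        if tok.norm in cfg.protected_words:
            tok.removed = False
            continue
        if len(tok.surface) < cfg.min_word_length or tok.norm in stop:
            tok.removed = True
    return out


def strip_punctuation(seq: TokenSequence) -> TokenSequence:
    """Mark punctuation tokens removed; word annotations are untouched.

    Runs after negation and history marking (ordering contract: punctuation
    must still be present while scopes are resolved).
    """
    out = seq.copy()
    for tok in out.tokens:
        if tok.kind == "punct":
            tok.removed = True
    return out
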