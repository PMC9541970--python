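"""Shared fixtures and the independent brute-force scoping oracle.

The oracle deliberately avoids the implementation's linear scan: it checks,
for every (cue, token) pair, whether any termination token lies strictly
between them, which is the defining property of a forward scope.
"""

from __future__ import annotations

import pytest

from ipvdetect import load_default_resources
from ipvdetect.preprocess import Token, TokenSequence


@pytest.fixture(scope="session")
def resources():
    return load_default_resources()


@pytest.fixture(scope="session")
def faithful_resources():
    return load_default_resources(faithful_table3=True)


def make_sequence(items) -> TokenSequence:
    """Build a surviving token sequence from (surface, kind) pairs or words."""
    tokens = []
    for i, item in enumerate(items):
        if isinstance(item, tuple):
            surface, kind = item
        else:
            surface = item
            kind = "word" if surface[0].isalpha() else "punct"
        tokens.append(Token(surface=surface, norm=surface, kind=kind, index=i))
    return TokenSequence(tokens, source_note_id="test")


def brute_force_negation(tokens, cues, terminators) -> set:
    """Indices a negation cue should flag: pairwise no-terminator-between."""
    flagged = set()
    for i, tok in enumerate(tokens):
        if tok.kind != "word" or tok.norm in terminators:
            continue
        for j in range(i):
            cue = tokens[j]
            if cue.kind == "word" and cue.norm in cues:
                between = any(
                    tokens[k].norm in terminators for k in range(j + 1, i)
                )
                if not between:
                    flagged.add(i)
                    break
    return flagged


def find_cue_spans(tokens, phrase_cues) -> list:
    """Greedy longest-first occurrences of multi-token cue phrases."""
    cues = sorted(phrase_cues, key=len, reverse=True)
    spans = []
    i = 0
    while i < len(tokens):
        hit = None
        for cue in cues:
            if i + len(cue) <= len(tokens) and all(
                tokens[i + k].kind == "word" and tokens[i + k].norm == cue[k]
                for k in range(len(cue))
            ):
                hit = cue
                break
        if hit is None:
            i += 1
        else:
            spans.append((i, i + len(hit) - 1))
            i += len(hit)
    return spans


def brute_force_history(tokens, phrase_cues, terminators) -> set:
    """Indices a history cue should flag, via the same pairwise property."""
    spans = find_cue_spans(tokens, phrase_cues)
    flagged = set()
    for i, tok in enumerate(tokens):
        if tok.kind != "word" or tok.norm in terminators:
            continue
        for _, b in spans:
            if b < i and not any(
                tokens[k].norm in terminators for k in range(b + 1, i)
            ):
                flagged.add(i)
                break
    return flagged
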