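"""Negation and history scoping over normalized token sequences.

A simplified NegEx-style scoper: when a cue token is found, every surviving
word token strictly after the cue and before the next termination token (or
the end of the sequence) is flagged. Negation cues set ``negated``; history
cue phrases (matched longest-first) set ``in_history``. The two flags are
independent — a negation cue inside a history scope still negates.

Only forward scopes are implemented; there are no backward scopes and no
pseudo-negation phrases from full NegEx.
"""

from __future__ import annotations

from .lexicons import ScopingConfig
from .preprocess import Token, TokenSequence, normalize_word

__all__ = ["mark_negation", "mark_history", "render_annotated"]


def _norm_set(words, suffixes) -> frozenset:
    return frozenset(normalize_word(w, suffixes) for w in words)


def _terminators(cfg: ScopingConfig, suffixes) -> frozenset:
    # word terminators are compared in stemmed space ("reports" meets
    # "reported"); punctuation terminators compare as-is
    out = set()
    for tok in cfg.termination_tokens:
        out.add(normalize_word(tok, suffixes) if tok.isalpha() else tok)
    return frozenset(out)


def mark_negation(
    seq: TokenSequence,
    cfg: ScopingConfig,
    suffixes=("ed", "ing", "s"),
) -> TokenSequence:
    """Flag every surviving word token inside a negation scope.

    Scopes from multiple cues union; the cue token itself is never flagged;
    a token that is itself a termination token is not flagged.
    """
    cues = _norm_set(cfg.negation_cues, suffixes)
    term = _terminators(cfg, suffixes)
    out = seq.copy()
    surv = out.surviving()
    for i, tok in enumerate(surv):
        if tok.kind != "word" or tok.norm not in cues:
            continue
        for nxt in surv[i + 1 :]:
            if nxt.norm in term:
                break
            if nxt.kind == "word":
                nxt.negated = True
    return out


def _match_cue_at(surv: list[Token], i: int, cue: tuple) -> bool:
    if i + len(cue) > len(surv):
        return False
    return all(
        surv[i + k].kind == "word" and surv[i + k].norm == cue[k]
        for k in range(len(cue))
    )


def mark_history(
    seq: TokenSequence,
    cfg: ScopingConfig,
    suffixes=("ed", "ing", "s"),
) -> TokenSequence:
    """Flag tokens referring to past (not current-visit) violence.

    History cue phrases are matched longest-first over surviving tokens; the
    scope runs from the end of the cue to the next termination token, using
    the same termination set as negation.
    """
    cues = tuple(
        tuple(normalize_word(w, suffixes) for w in cue) for cue in cfg.history_cues
    )
    term = _terminators(cfg, suffixes)
    out = seq.copy()
    surv = out.surviving()
    i = 0
    while i < len(surv):
        matched = next((c for c in cues if _match_cue_at(surv, i, c)), None)
        if matched is None:
            i += 1
            continue
        for nxt in surv[i + len(matched) :]:
            if nxt.norm in term:
                break
            if nxt.kind == "word":
                nxt.in_history = True
        i += len(matched)
    return out


def render_annotated(seq: TokenSequence) -> str:
    """Debug rendering: "_neg" / "_hx" suffixes, punctuation re-attached.

    Removed tokens are omitted; words render as their lowercased surface with
    the "_neg" suffix before "_hx" when both flags are set. The rendering is
    bit-stable and lowercased (regression comparisons should be
    case-insensitive against published capitalized examples).
    """
    parts: list[str] = []
    for tok in seq.surviving():
        if tok.kind == "punct":
            if parts:
                parts[-1] += tok.surface
            else:
                parts.append(tok.surface)
            continue
        text = tok.surface.lower()
        if tok.negated:
            text += "_neg"
        if tok.in_history:
            text += "_hx"
        parts.append(text)
    return " ".join(parts)
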