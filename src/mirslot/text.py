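"""Sentence splitting, tokenization and slot labeling.

The tokenizer is the convention every downstream count depends on: split on
whitespace, then split off each of ``- , / ( )`` as its own single-character
token.  ``miR-16-2`` therefore tokenizes as ``miR / - / 16 / - / 2``, which
is what makes hyphens and commas visible to the alignment scorer as
insertion symbols.

Offsets are 0-based, half-open, into the source string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .scheme import SlotScheme

_TOKEN_RE = re.compile(r"[-,/()]|[^\s\-,/()]+")
_SENT_RE = re.compile(r"[^.!?]*[.!?]+(?:\s+|$)|[^.!?]+$")


@dataclass(frozen=True)
class Token:
    """A token with character offsets into its source sentence."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad token offsets ({self.start}, {self.end})")


@dataclass
class LabeledSequence:
    """Tokens plus, per token, the set of slot labels that match it."""

    tokens: list[Token]
    labels: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.labels and len(self.labels) != len(self.tokens):
            raise ValueError("labels/tokens length mismatch")
        if not self.labels:
            self.labels = [frozenset()] * len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def slice(self, i: int, j: int) -> "LabeledSequence":
        return LabeledSequence(self.tokens[i:j], self.labels[i:j])


def split_sentences(text: str) -> list[tuple[str, int]]:
    """Split text into (sentence, start_offset) pairs.

    A sentence ends at ``. ! ?`` runs followed by whitespace or end of
    text; text without terminal punctuation is one sentence.  The spans
    cover the input, so offsets map straight back into it.
    """
    out = []
    for m in _SENT_RE.finditer(text):
        sent = m.group(0)
        stripped = sent.strip()
        if not stripped:
            continue
        lead = len(sent) - len(sent.lstrip())
        out.append((stripped, m.start() + lead))
    return out


def tokenize(sentence: str, offset: int = 0) -> list[Token]:
    """Tokenize one sentence; ``offset`` shifts reported positions."""
    return [
        Token(m.group(0), m.start() + offset, m.end() + offset)
        for m in _TOKEN_RE.finditer(sentence)
    ]


def label_slots(tokens: list[Token], scheme: SlotScheme) -> LabeledSequence:
    """Attach every matching slot label (with ancestors) to each token.

    Multi-token closed-class terms (e.g. ``micro rna``) are matched
    greedily, longest first; every covered token receives the slot label.
    A token may carry several labels (open-class pattern plus closed-class
    term); disambiguation is deferred to alignment scoring.
    """
    labels: list[set[str]] = [set(scheme.lookup_term(t.text)) for t in tokens]
    multi = scheme.multi_token_terms()
    if multi:
        folded = [t.text.casefold() for t in tokens]
        for words, slot in multi:
            n = len(words)
            for i in range(len(tokens) - n + 1):
                if tuple(folded[i : i + n]) == words:
                    extra = {slot, *scheme.ancestors(slot)}
                    for k in range(i, i + n):
                        labels[k].update(extra)
    return LabeledSequence(tokens, [frozenset(l) for l in labels])


def label_sentence(sentence: str, scheme: SlotScheme, offset: int = 0) -> LabeledSequence:
    """Convenience: tokenize then label one sentence."""
    return label_slots(tokenize(sentence, offset), scheme)


def label_text(text: str, scheme: SlotScheme) -> list[LabeledSequence]:
    """Split, tokenize and label a whole document; offsets are document-wide."""
    return [label_sentence(s, scheme, offset=off) for s, off in split_sentences(text)]
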