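"""Shared test helpers."""

from __future__ import annotations

import random

from mirslot.scoring import SlotStatistics
from mirslot.text import LabeledSequence, Token


def random_alignment_case(rng: random.Random):
    """A random window/principle/statistics triple for oracle comparison."""
    slot_pool = ["A1", "B1", "C1", "D1"]
    n = rng.randint(1, 8)
    tokens, labels = [], []
    pos = 0
    for _ in range(n):
        word = rng.choice(["w", "-", ",", "q", "z"])
        tokens.append(Token(word, pos, pos + len(word)))
        pos += len(word) + 1
        k = rng.randint(0, 2)
        labels.append(frozenset(rng.sample(slot_pool, k)))
    window = LabeledSequence(tokens, labels)
    principle = tuple(rng.choice(slot_pool) for _ in range(rng.randint(0, 5)))
    syms = {}
    for s in slot_pool:
        syms[s] = [float(rng.randint(0, 5)), float(rng.randint(0, 5))]
        if syms[s] == [0.0, 0.0]:
            syms[s] = [1.0, 0.0]
    words = {w: [float(rng.randint(0, 3)), float(rng.randint(0, 3))] for w in ["w", "-", ","]}
    words = {w: c for w, c in words.items() if c != [0.0, 0.0]}
    stats = SlotStatistics(slot_counts=syms, nonslot_counts=words)
    return window, principle, stats
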