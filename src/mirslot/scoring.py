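"""Corpus statistics and the principle-matching score functions.

Every symbol that can take part in an alignment — a slot, or a bare word
seen inside gold mentions (a *non-slot* symbol such as ``-`` or ``,``) —
carries two corpus frequencies: occurrences inside annotated miRNA
mentions and occurrences outside them.  From these the scorer derives

* the matched-slot score  ``λ · f_mi / (f_mi + f_non)``  (bounded in [0, λ],
  λ = 100 by default),
* the insertion penalty  ``1 / H``  where ``H`` is the binary entropy of
  (P_miRNA, P_nonMiRNA) — 0 when the symbol never occurs outside mentions,
  +inf when it never occurs inside one (such an insertion rejects the
  candidate),
* the deletion penalty  ``-log2 P_miRNA``  — 0 for mention-exclusive slots.

Penalties are non-negative and are *subtracted* from the candidate score;
the final score of a candidate C is

    Score(C) = Σ_{S ∈ M} score_m(S) − Σ_{S ∈ I} score_i(S) − Σ_{S ∈ D} score_d(S)

over the matched (M), inserted (I) and deleted (D) sets of its alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from .text import label_text

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import AnnotatedDocument
    from .induction import PrincipleCluster
    from .scheme import SlotScheme

INF = float("inf")


@dataclass
class SlotStatistics:
    """Inside/outside-mention frequencies for slots and non-slot words.

    ``slot_counts`` and ``nonslot_counts`` map a symbol to
    ``[freq_miRNA, freq_nonMiRNA]``.  ``lambda_scale`` is the matched-slot
    scale λ; ``unseen_insertion`` is the penalty ceiling applied to symbols
    never seen in training; ``pseudo_count`` optionally smooths the
    probabilities (off by default).
    """

    slot_counts: dict[str, list[float]] = field(default_factory=dict)
    nonslot_counts: dict[str, list[float]] = field(default_factory=dict)
    lambda_scale: float = 100.0
    unseen_insertion: float = 30.0
    pseudo_count: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_scale <= 0:
            raise ValueError("lambda_scale must be positive")

    def counts(self, symbol: str) -> list[float] | None:
        c = self.slot_counts.get(symbol)
        if c is None:
            c = self.nonslot_counts.get(symbol)
        return c

    def p_mirna(self, symbol: str) -> float | None:
        """P(symbol belongs to a miRNA mention); None if unseen."""
        c = self.counts(symbol)
        if c is None:
            return None
        fm, fn = c
        tot = fm + fn + 2 * self.pseudo_count
        if tot == 0:
            return None
        return (fm + self.pseudo_count) / tot

    def is_nonslot_symbol(self, word: str) -> bool:
        return word.casefold() in self.nonslot_counts

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "slot_counts": {k: list(v) for k, v in sorted(self.slot_counts.items())},
            "nonslot_counts": {k: list(v) for k, v in sorted(self.nonslot_counts.items())},
            "lambda_scale": self.lambda_scale,
            "unseen_insertion": self.unseen_insertion,
            "pseudo_count": self.pseudo_count,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlotStatistics":
        return cls(
            slot_counts={k: list(v) for k, v in d["slot_counts"].items()},
            nonslot_counts={k: list(v) for k, v in d["nonslot_counts"].items()},
            lambda_scale=d.get("lambda_scale", 100.0),
            unseen_insertion=d.get("unseen_insertion", 30.0),
            pseudo_count=d.get("pseudo_count", 0.0),
        )


def estimate_statistics(
    docs: Sequence["AnnotatedDocument"],
    scheme: "SlotScheme",
    lambda_scale: float = 100.0,
    unseen_insertion: float = 30.0,
    pseudo_count: float = 0.0,
) -> SlotStatistics:
    """Count slot and non-slot occurrences inside vs outside gold spans.

    A labeled token increments every slot in its label set (children count
    toward their ancestors, so generalized slots are scored too).  An
    unlabeled token inside a mention becomes a non-slot symbol; outside
    occurrences are kept only for symbols seen inside at least one mention.
    """
    if not docs:
        raise ValueError("cannot estimate statistics from an empty corpus")
    slot_counts: dict[str, list[float]] = {}
    inside_words: dict[str, float] = {}
    outside_words: dict[str, float] = {}
    for doc in docs:
        spans = [(a.start, a.end) for a in doc.annotations]
        for seq in label_text(doc.text, scheme):
            for tok, labels in zip(seq.tokens, seq.labels):
                inside = any(s <= tok.start and tok.end <= e for s, e in spans)
                if labels:
                    for slot in labels:
                        c = slot_counts.setdefault(slot, [0.0, 0.0])
                        c[0 if inside else 1] += 1
                else:
                    w = tok.text.casefold()
                    if inside:
                        inside_words[w] = inside_words.get(w, 0.0) + 1
                    else:
                        outside_words[w] = outside_words.get(w, 0.0) + 1
    nonslot_counts = {
        w: [fm, outside_words.get(w, 0.0)] for w, fm in inside_words.items()
    }
    return SlotStatistics(
        slot_counts=slot_counts,
        nonslot_counts=nonslot_counts,
        lambda_scale=lambda_scale,
        unseen_insertion=unseen_insertion,
        pseudo_count=pseudo_count,
    )


# -- elementary scores ---------------------------------------------------


def match_score(slot: str, stats: SlotStatistics) -> float:
    """λ · P(slot ∈ miRNA mention); λ/2 for slots unseen in training."""
    p = stats.p_mirna(slot)
    if p is None:
        return stats.lambda_scale / 2.0
    return stats.lambda_scale * p


def insertion_penalty(symbol: str, stats: SlotStatistics) -> float:
    """Inverse-entropy insertion penalty (non-negative; +inf rejects)."""
    p = stats.p_mirna(symbol)
    if p is None:
        return stats.unseen_insertion
    if p == 0.0:
        return INF
    q = 1.0 - p
    if q == 0.0:
        return 0.0
    h = -(p * math.log2(p) + q * math.log2(q))
    return 1.0 / h


def deletion_penalty(slot: str, stats: SlotStatistics) -> float:
    """-log2 of the normalized matched-slot score (0 if mention-exclusive)."""
    m = match_score(slot, stats) / stats.lambda_scale
    if m == 0.0:
        return INF
    return -math.log2(m)


def insertion_symbol_for_token(
    labels: Iterable[str], word: str, stats: SlotStatistics
) -> tuple[str, float]:
    """Resolve which symbol an inserted token is charged as.

    A labeled token is charged as its cheapest slot (an extra list item
    counts as an insertion of the Order slot, not of its surface string);
    an unlabeled token is charged as its own case-folded word.  Ties break
    alphabetically for determinism.
    """
    labels = sorted(labels)
    if labels:
        return min(((s, insertion_penalty(s, stats)) for s in labels), key=lambda p: (p[1], p[0]))
    w = word.casefold()
    return w, insertion_penalty(w, stats)


def score_components(
    matched_slots: Iterable[str],
    inserted_symbols: Iterable[str],
    deleted_slots: Iterable[str],
    stats: SlotStatistics,
) -> float:
    """The candidate score over explicit M / I / D symbol lists."""
    total = 0.0
    for s in matched_slots:
        total += match_score(s, stats)
    for s in inserted_symbols:
        pen = insertion_penalty(s, stats)
        if math.isinf(pen):
            return -INF
        total -= pen
    for s in deleted_slots:
        pen = deletion_penalty(s, stats)
        if math.isinf(pen):
            return -INF
        total -= pen
    return total


def sequence_score(alignment, stats: SlotStatistics) -> float:
    """Recompute the score of an alignment from its own M/I/D sets."""
    return score_components(
        alignment.matched_slots, alignment.inserted_symbols, alignment.deleted_slots, stats
    )


def cluster_threshold(
    cluster: "PrincipleCluster",
    stats: SlotStatistics,
    insertion_mode: str = "subtract",
) -> float:
    """Acceptance threshold of a principle cluster.

    Core slots (present in every member principle) contribute their full
    matched score; slots of the dominant outside the core contribute a
    deletion penalty; optional slots and non-slot words contribute their
    insertion penalty weighted by the probability of appearing in a member
    mention.  With ``insertion_mode="subtract"`` (default) the expected
    insertion cost lowers the threshold, mirroring how insertions lower
    every candidate's score; ``"add"`` flips the sign of those two terms.
    """
    if insertion_mode not in ("subtract", "add"):
        raise ValueError(f"unknown insertion_mode {insertion_mode!r}")
    sign = -1.0 if insertion_mode == "subtract" else 1.0
    t = 0.0
    for s in sorted(cluster.core_slots):
        t += match_score(s, stats)
    for s in sorted(set(cluster.dominant.slot_sequence) - set(cluster.core_slots)):
        t -= deletion_penalty(s, stats)
    for s in sorted(cluster.optional_probs):
        t += sign * cluster.optional_probs[s] * insertion_penalty(s, stats)
    for w in sorted(cluster.nonslot_probs):
        t += sign * cluster.nonslot_probs[w] * insertion_penalty(w, stats)
    return t
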