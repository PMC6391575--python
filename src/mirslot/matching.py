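"""Alignment-based recognition of miRNA mentions.

A candidate token window is aligned against a principle by dynamic
programming over (token index, slot index) with three moves:

* **match** — the token's label set contains the slot; gains the
  matched-slot score,
* **insert** — the token is consumed without a slot; costs the insertion
  penalty of its cheapest label (or of the bare word for unlabeled
  symbols such as ``-`` and ``,``),
* **delete** — the slot is skipped; costs the deletion penalty.

The DP maximizes the candidate score exactly; ties prefer fewer
insertions, then fewer deletions, then leftmost matches.  Recognition
anchors windows on miRNA-indicator tokens, aligns each window against
every cluster dominant, and accepts the best alignment iff its score
reaches the cluster's threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .induction import Principle, PrincipleCluster
from .scoring import (
    SlotStatistics,
    deletion_penalty,
    insertion_symbol_for_token,
    match_score,
)
from .text import LabeledSequence

NEG_INF = float("-inf")

# comparison slack for score >= threshold: both sides can be analytically
# equal and differ only by float summation order
THRESHOLD_TOL = 1e-9


def _slots_of(principle) -> tuple[str, ...]:
    """Slot sequence of a Principle or a bare slot-name sequence."""
    if isinstance(principle, Principle):
        return principle.slot_sequence
    return tuple(principle)


@dataclass
class AlignmentResult:
    """The matched/insertion/deletion decomposition of one alignment."""

    principle: Principle | tuple[str, ...]
    window: LabeledSequence
    M: list[tuple[int, int]]  # (token index, slot index), strictly increasing
    I: list[int]  # inserted token indices
    D: list[int]  # deleted slot indices
    score: float

    @property
    def slot_sequence(self) -> tuple[str, ...]:
        return _slots_of(self.principle)

    @property
    def matched_slots(self) -> list[str]:
        return [self.slot_sequence[j] for _, j in self.M]

    @property
    def inserted_symbols(self) -> list[str]:
        out = []
        for i in self.I:
            sym, _ = insertion_symbol_for_token(
                self.window.labels[i], self.window.tokens[i].text, self._stats
            )
            out.append(sym)
        return out

    @property
    def deleted_slots(self) -> list[str]:
        return [self.slot_sequence[j] for j in self.D]

    _stats: SlotStatistics = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class Mention:
    """A recognized mention span within one sentence/document."""

    start: int
    end: int
    text: str
    alignment: AlignmentResult
    accepted: bool
    score: float
    threshold: float
    cluster_index: int


def align(
    window: LabeledSequence,
    principle: Principle | Sequence[str],
    stats: SlotStatistics,
) -> AlignmentResult:
    """Maximum-score monotone alignment of a token window to a principle.

    ``principle`` may also be a bare slot-name sequence (possibly empty,
    in which case every token is an insertion).
    """
    toks = window.tokens
    labs = window.labels
    slots = _slots_of(principle)
    n, m = len(toks), len(slots)

    ins_pen = [insertion_symbol_for_token(labs[i], toks[i].text, stats)[1] for i in range(n)]
    del_pen = [deletion_penalty(s, stats) for s in slots]
    gain = [
        [match_score(slots[j], stats) if slots[j] in labs[i] else None for j in range(m)]
        for i in range(n)
    ]

    # value = (score, -#insertions, -#deletions, -Σ matched token indices);
    # maximize lexicographically — the last term realizes leftmost-match
    # preference among otherwise equal alignments
    worst = (NEG_INF, 0, 0, 0)
    val = [[worst] * (m + 1) for _ in range(n + 1)]
    back: list[list[str | None]] = [[None] * (m + 1) for _ in range(n + 1)]
    val[0][0] = (0.0, 0, 0, 0)
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = worst
            move = None
            # preference order on exact ties: match > delete > insert
            if i > 0 and j > 0 and gain[i - 1][j - 1] is not None:
                s, ni, nd, mi = val[i - 1][j - 1]
                cand = (s + gain[i - 1][j - 1], ni, nd, mi - (i - 1))
                if s > NEG_INF and cand > best:
                    best, move = cand, "M"
            if j > 0:
                s, ni, nd, mi = val[i][j - 1]
                cand = (s - del_pen[j - 1], ni, nd - 1, mi)
                if s > NEG_INF and not math.isinf(del_pen[j - 1]) and cand > best:
                    best, move = cand, "D"
            if i > 0:
                s, ni, nd, mi = val[i - 1][j]
                cand = (s - ins_pen[i - 1], ni - 1, nd, mi)
                if s > NEG_INF and not math.isinf(ins_pen[i - 1]) and cand > best:
                    best, move = cand, "I"
            val[i][j] = best
            back[i][j] = move

    M: list[tuple[int, int]] = []
    I: list[int] = []
    D: list[int] = []
    score = val[n][m][0]
    if score > NEG_INF:
        i, j = n, m
        while i > 0 or j > 0:
            mv = back[i][j]
            if mv == "M":
                M.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif mv == "D":
                D.append(j - 1)
                j -= 1
            else:
                I.append(i - 1)
                i -= 1
        M.reverse()
        I.reverse()
        D.reverse()
    else:
        # fully rejected window: report everything inserted/deleted
        I = list(range(n))
        D = list(range(m))
    res = AlignmentResult(principle, window, M, I, D, score, _stats=stats)
    return res


def enumerate_alignments(
    window: LabeledSequence, principle: Principle | Sequence[str], stats: SlotStatistics
) -> float:
    """Best score over *all* monotone alignments, by exhaustive recursion.

    Independent oracle for :func:`align` on small inputs; O(3^(n+m)).
    """
    toks, labs = window.tokens, window.labels
    slots = _slots_of(principle)

    def rec(i: int, j: int) -> float:
        if i == len(toks) and j == len(slots):
            return 0.0
        best = NEG_INF
        if i < len(toks) and j < len(slots) and slots[j] in labs[i]:
            r = rec(i + 1, j + 1)
            if r > NEG_INF:
                best = max(best, r + match_score(slots[j], stats))
        if j < len(slots):
            pen = deletion_penalty(slots[j], stats)
            if not math.isinf(pen):
                r = rec(i, j + 1)
                if r > NEG_INF:
                    best = max(best, r - pen)
        if i < len(toks):
            pen = insertion_symbol_for_token(labs[i], toks[i].text, stats)[1]
            if not math.isinf(pen):
                r = rec(i + 1, j)
                if r > NEG_INF:
                    best = max(best, r - pen)
        return best

    return rec(0, 0)


# -- recognition ---------------------------------------------------------

ANCHOR_SLOTS = ("miRNA", "Let")
PUNCT_SYMBOLS = {"-", ",", "/", "(", ")"}


def _window_bounds(
    seq: LabeledSequence, anchor: int, stats: SlotStatistics, limit: int
) -> tuple[int, int]:
    """Extend the anchor left/right over labeled or known-symbol tokens."""

    def eligible(i: int) -> bool:
        if seq.labels[i]:
            return True
        w = seq.tokens[i].text.casefold()
        return w in PUNCT_SYMBOLS or stats.is_nonslot_symbol(w)

    lo = anchor
    while lo > 0 and anchor - lo < limit and eligible(lo - 1):
        lo -= 1
    hi = anchor
    while hi + 1 < len(seq) and hi - anchor < limit and eligible(hi + 1):
        hi += 1
    return lo, hi + 1


def recognize(
    sentence: LabeledSequence,
    clusters: Sequence[PrincipleCluster],
    stats: SlotStatistics,
    window_limit: int = 30,
) -> list[Mention]:
    """Recognize mention spans in one labeled sentence.

    Candidate windows are anchored per indicator token, aligned against
    every cluster dominant, and the best-scoring alignment per anchor is
    kept; the mention is emitted iff its score reaches that cluster's
    threshold.  Reported spans run from the first to the last aligned
    slot-bearing token (edge-trimming bare symbols); overlapping accepted
    mentions keep the higher score.
    """
    mentions: list[Mention] = []
    for idx in range(len(sentence)):
        if not any(s in sentence.labels[idx] for s in ANCHOR_SLOTS):
            continue
        lo, hi = _window_bounds(sentence, idx, stats, window_limit)
        window = sentence.slice(lo, hi)
        best: tuple[float, float, int, AlignmentResult] | None = None
        for ci, cluster in enumerate(clusters):
            r = align(window, cluster.dominant, stats)
            margin = r.score - cluster.threshold
            key = (r.score, margin, -ci)
            if best is None or key > (best[0], best[1], -best[2]):
                best = (r.score, margin, ci, r)
        if best is None:
            continue
        score, margin, ci, r = best
        if not r.M:
            continue
        keep = [i for i, _ in r.M] + [i for i in r.I if window.labels[i]]
        first, last = min(keep), max(keep)
        start = window.tokens[first].start
        end = window.tokens[last].end
        accepted = margin >= -THRESHOLD_TOL
        if accepted:
            mentions.append(
                Mention(
                    start=start,
                    end=end,
                    text="",
                    alignment=r,
                    accepted=True,
                    score=score,
                    threshold=clusters[ci].threshold,
                    cluster_index=ci,
                )
            )
    # merge overlaps: keep higher score
    mentions.sort(key=lambda m: (-m.score, m.start, m.end))
    kept: list[Mention] = []
    for m in mentions:
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def reject_candidates(
    sentence: LabeledSequence,
    clusters: Sequence[PrincipleCluster],
    stats: SlotStatistics,
    window_limit: int = 30,
) -> list[Mention]:
    """Like :func:`recognize` but also returns sub-threshold candidates.

    Useful for diagnostics (e.g. inspecting why a bare indicator word such
    as an anaphoric ``miR`` was filtered out).
    """
    out: list[Mention] = []
    for idx in range(len(sentence)):
        if not any(s in sentence.labels[idx] for s in ANCHOR_SLOTS):
            continue
        lo, hi = _window_bounds(sentence, idx, stats, window_limit)
        window = sentence.slice(lo, hi)
        for ci, cluster in enumerate(clusters):
            r = align(window, cluster.dominant, stats)
            if not r.M:
                continue
            out.append(
                Mention(
                    start=window.tokens[min(i for i, _ in r.M)].start,
                    end=window.tokens[max(i for i, _ in r.M)].end,
                    text="",
                    alignment=r,
                    accepted=r.score - cluster.threshold >= -THRESHOLD_TOL,
                    score=r.score,
                    threshold=cluster.threshold,
                    cluster_index=ci,
                )
            )
    return out
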