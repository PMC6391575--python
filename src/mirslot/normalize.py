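"""Grounding recognized mentions to Rfam family accessions.

The lexicon is compiled from an Rfam ``family`` table dump (tab-separated;
column 1 = accession ``RF#####``, column 2 = family id, column 4 =
description, column 11 = previous names, 1-based as in the database
documentation).  Description names with slash alternatives expand to one
name per alternative (``mir-103/107`` → ``mir-103``, ``mir-107``); a
previous-names cell holding the literal ``\\N`` contributes nothing.
Every name also gains a variant with ``-``/``_`` replaced by space, and
everything is case-folded.

Names are slot-labeled and aligned against the trained principle clusters
to build an inverted index (slot, token value) → accessions, so that a
recognized mention retrieves candidates through its own matched slot
values and ranks them by the same alignment score used for recognition.
Conjunction or slash mentions carrying several numbering (Order) groups
split into sub-mentions normalized independently.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .induction import PrincipleCluster
from .matching import Mention, align
from .scheme import SlotScheme
from .scoring import (
    SlotStatistics,
    deletion_penalty,
    insertion_symbol_for_token,
    match_score,
)
from .text import LabeledSequence, Token, label_slots, tokenize

_ACCESSION_RE = re.compile(r"RF\d{5}")
# description-embedded names: indicator stem + numbering, with optional
# slash alternatives ("mir-103/107", "mir-29a/b-1")
_DESC_NAME_RE = re.compile(
    r"\b(?:mir|mirn|mirna|microrna|let|lin|lsy)[-_ ]?\d+[a-z]*\d*"
    r"(?:/[a-z0-9][a-z0-9_-]*)*\b",
    re.IGNORECASE,
)
_TRAILING_NUM_RE = re.compile(r"\d+[a-z]*\d*$")
_TRAILING_LETTER_RE = re.compile(r"[a-z]+\d*$")


@dataclass
class NormalizationEntry:
    """One Rfam family: accession, name variants, slot decompositions."""

    accession: str
    names: set[str] = field(default_factory=set)
    # per name: its labeled token sequence under the scheme (filled lazily)
    slot_decompositions: dict[str, LabeledSequence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _ACCESSION_RE.fullmatch(self.accession):
            raise ValueError(f"bad Rfam accession {self.accession!r}")
        if not self.names:
            raise ValueError(f"{self.accession}: entry has no names")


def expand_slash_name(name: str) -> list[str]:
    """Expand slash alternatives into full names.

    ``mir-103/107`` → [mir-103, mir-107]; an alternative starting with a
    letter replaces the trailing letter block instead (``mir-29a/b-1`` →
    [mir-29a, mir-29b-1]).
    """
    if "/" not in name:
        return [name]
    head, *alts = name.split("/")
    out = [head]
    for alt in alts:
        if alt[:1].isdigit():
            new = _TRAILING_NUM_RE.sub(alt, head) if _TRAILING_NUM_RE.search(head) else f"{head}-{alt}"
        else:
            new = _TRAILING_LETTER_RE.sub(alt, head) if _TRAILING_LETTER_RE.search(head) else f"{head}{alt}"
        out.append(new)
        head = new
    return out


def _name_variants(name: str) -> set[str]:
    name = name.casefold().strip()
    if not name:
        return set()
    variants = {name}
    spaced = re.sub(r"[-_]", " ", name).strip()
    if spaced:
        variants.add(spaced)
    return variants


def parse_family_file(
    path: str | Path,
    accession_col: int = 1,
    id_col: int = 2,
    description_col: int = 4,
    previous_col: int = 11,
) -> list[NormalizationEntry]:
    """Compile normalization entries from an Rfam family table dump.

    Column indices are 1-based, matching the database documentation; a
    config map allows re-pointing them for other dumps.  Malformed lines
    are skipped with a warning.
    """
    path = Path(path)
    entries: list[NormalizationEntry] = []
    min_cols = max(accession_col, id_col, description_col, previous_col)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < min_cols:
            warnings.warn(f"{path}:{lineno}: expected ≥{min_cols} columns; skipped")
            continue
        acc = cols[accession_col - 1].strip()
        if not _ACCESSION_RE.fullmatch(acc):
            warnings.warn(f"{path}:{lineno}: bad accession {acc!r}; skipped")
            continue
        names: set[str] = set()
        names |= _name_variants(cols[id_col - 1])
        desc = cols[description_col - 1]
        for m in _DESC_NAME_RE.finditer(desc):
            for n in expand_slash_name(m.group(0)):
                names |= _name_variants(n)
        prev = cols[previous_col - 1].strip()
        if prev and prev != r"\N":
            for n in re.split(r"[,\s;]+", prev):
                names |= _name_variants(n)
        if not names:
            warnings.warn(f"{path}:{lineno}: no usable names; skipped")
            continue
        entries.append(NormalizationEntry(accession=acc, names=names))
    return entries


# -- slot index ----------------------------------------------------------


@dataclass
class SlotIndex:
    """Inverted index (slot, token value) → accessions.

    The ``None`` slot key holds the raw-token fallback for names that
    matched no principle.
    """

    index: dict[tuple[str | None, str], set[str]] = field(default_factory=dict)

    def add(self, slot: str | None, value: str, accession: str) -> None:
        self.index.setdefault((slot, value.casefold()), set()).add(accession)

    def lookup(self, slot: str | None, value: str) -> set[str]:
        return set(self.index.get((slot, value.casefold()), ()))

    def accessions(self) -> set[str]:
        out: set[str] = set()
        for accs in self.index.values():
            out |= accs
        return out


def _labeled_name(name: str, scheme: SlotScheme) -> LabeledSequence:
    return label_slots(tokenize(name), scheme)


def build_slot_index(
    entries: Sequence[NormalizationEntry],
    scheme: SlotScheme,
    clusters: Sequence[PrincipleCluster],
    stats: SlotStatistics,
) -> SlotIndex:
    """Label and align every name variant; index matched slot values.

    Each name is aligned against every cluster dominant; the best
    alignment's matched (slot, token value) pairs map to the entry's
    accession.  A name with no slot match at all falls back to raw-token
    indexing so it stays retrievable.
    """
    idx = SlotIndex()
    for entry in entries:
        for name in sorted(entry.names):
            seq = _labeled_name(name, scheme)
            entry.slot_decompositions[name] = seq
            if not seq.tokens:
                continue
            best = None
            for cluster in clusters:
                r = align(seq, cluster.dominant, stats)
                if best is None or r.score > best.score:
                    best = r
            pairs = []
            if best is not None:
                for ti, sj in best.M:
                    pairs.append((best.slot_sequence[sj], seq.tokens[ti].text))
            if pairs:
                for slot, value in pairs:
                    idx.add(slot, value, entry.accession)
            else:
                for tok in seq.tokens:
                    idx.add(None, tok.text, entry.accession)
    return idx


# -- mention normalization ----------------------------------------------


def _score_against_name(
    tokens: list[tuple[Token, frozenset]],
    name_seq: LabeledSequence,
    scheme: SlotScheme,
    stats: SlotStatistics,
) -> float:
    """Alignment score of mention tokens against one name decomposition.

    A mention token matches a name token when they share a slot label and
    their case-folded texts are equal; unmatched mention tokens are
    insertions, unmatched labeled name tokens are deletions of their slot.
    """
    name_items = [
        (t.text.casefold(), scheme.most_specific(l))
        for t, l in zip(name_seq.tokens, name_seq.labels)
        if l
    ]
    m_items = [(t.text.casefold(), labels) for t, labels in tokens]
    NEG = float("-inf")

    memo: dict[tuple[int, int], float] = {}

    def rec(i: int, j: int) -> float:
        if (i, j) in memo:
            return memo[(i, j)]
        if i == len(m_items) and j == len(name_items):
            return 0.0
        best = NEG
        if i < len(m_items) and j < len(name_items):
            text, labels = m_items[i]
            ntext, nslot = name_items[j]
            if text == ntext and nslot in labels:
                r = rec(i + 1, j + 1)
                if r > NEG:
                    best = max(best, r + match_score(nslot, stats))
        if j < len(name_items):
            pen = deletion_penalty(name_items[j][1], stats)
            r = rec(i, j + 1)
            if pen != float("inf") and r > NEG:
                best = max(best, r - pen)
        if i < len(m_items):
            text, labels = m_items[i]
            _, pen = insertion_symbol_for_token(labels, text, stats)
            r = rec(i + 1, j)
            if pen != float("inf") and r > NEG:
                best = max(best, r - pen)
        memo[(i, j)] = best
        return best

    return rec(0, 0)


def score_entry(
    tokens: list[tuple[Token, frozenset]],
    entry: NormalizationEntry,
    scheme: SlotScheme,
    stats: SlotStatistics,
) -> float:
    """Best alignment score of mention tokens over all entry names."""
    best = float("-inf")
    for name in sorted(entry.names):
        seq = entry.slot_decompositions.get(name)
        if seq is None:
            seq = _labeled_name(name, scheme)
            entry.slot_decompositions[name] = seq
        s = _score_against_name(tokens, seq, scheme, stats)
        best = max(best, s)
    return best


def _sub_mentions(
    mention: Mention, scheme: SlotScheme
) -> list[list[tuple[Token, frozenset]]]:
    """Split a mention into one token group per numbering (Order) value.

    Each group pairs the shared indicator (and species/precursor) tokens
    with one Order token and any immediately following suffix token, so a
    conjunction or slash mention like ``miR-1/133a`` normalizes each
    alternative independently.
    """
    r = mention.alignment
    window = r.window
    aligned = sorted({i for i, _ in r.M} | set(r.I))
    items = [(window.tokens[i], window.labels[i]) for i in aligned]
    shared = [
        (t, l) for t, l in items if l and not ({"Order", "Suffix"} & set(l))
    ]
    groups: list[list[tuple[Token, frozenset]]] = []
    order_positions = [k for k, (_, l) in enumerate(items) if "Order" in l]
    for k in order_positions:
        group = list(shared)
        group.append(items[k])
        if k + 1 < len(items) and "Suffix" in items[k + 1][1]:
            group.append(items[k + 1])
        groups.append(group)
    if not groups:
        groups = [[(t, l) for t, l in items if l]]
    return groups


def normalize_mention(
    mention: Mention,
    index: SlotIndex,
    entries: Sequence[NormalizationEntry],
    scheme: SlotScheme,
    stats: SlotStatistics,
) -> list[tuple[str, float]]:
    """Ground an accepted mention to ranked Rfam accessions.

    Candidates are retrieved through the mention's slot values in the
    index; each candidate entry is scored by aligning the mention (or each
    of its Order sub-mentions) against the entry's best name
    decomposition.  Returns (accession, score) pairs sorted by descending
    score, ties by ascending accession; empty when nothing is retrievable.
    """
    groups = normalize_mention_groups(mention, index, entries, scheme, stats)
    results: dict[str, float] = {}
    for ranked in groups:
        for acc, s in ranked:
            if acc not in results or s > results[acc]:
                results[acc] = s
    return sorted(results.items(), key=lambda kv: (-kv[1], kv[0]))


def normalize_mention_groups(
    mention: Mention,
    index: SlotIndex,
    entries: Sequence[NormalizationEntry],
    scheme: SlotScheme,
    stats: SlotStatistics,
) -> list[list[tuple[str, float]]]:
    """Ranked candidates per sub-mention group (one group per Order value)."""
    by_acc = {e.accession: e for e in entries}
    out: list[list[tuple[str, float]]] = []
    for group in _sub_mentions(mention, scheme):
        candidates: set[str] = set()
        for tok, labels in group:
            for slot in labels:
                candidates |= index.lookup(slot, tok.text)
            candidates |= index.lookup(None, tok.text)
        ranked: dict[str, float] = {}
        for acc in sorted(candidates):
            entry = by_acc.get(acc)
            if entry is None:
                continue
            ranked[acc] = score_entry(group, entry, scheme, stats)
        out.append(sorted(ranked.items(), key=lambda kv: (-kv[1], kv[0])))
    return out


def normalize_mention_bruteforce(
    mention: Mention,
    entries: Sequence[NormalizationEntry],
    scheme: SlotScheme,
    stats: SlotStatistics,
) -> list[tuple[str, float]]:
    """Index-free oracle: score the mention against *every* entry."""
    results: dict[str, float] = {}
    for group in _sub_mentions(mention, scheme):
        for entry in entries:
            s = score_entry(group, entry, scheme, stats)
            if s == float("-inf"):
                continue
            if entry.accession not in results or s > results[entry.accession]:
                results[entry.accession] = s
    return sorted(results.items(), key=lambda kv: (-kv[1], kv[0]))


# -- lexicon ambiguity ---------------------------------------------------


def ambiguity_report(
    entries: Sequence[NormalizationEntry],
    english_words: set[str] | None = None,
) -> tuple[float, float, float]:
    """(mean IDs per name, mean names per ID, fraction of English-word names).

    Computed over the compiled name variants (case-folded, with the
    ``-``/``_`` → space expansion already applied at parse time).
    """
    name_to_ids: dict[str, set[str]] = {}
    for e in entries:
        for n in e.names:
            name_to_ids.setdefault(n, set()).add(e.accession)
    if not name_to_ids:
        return (0.0, 0.0, 0.0)
    pairs = sum(len(ids) for ids in name_to_ids.values())
    n_names = len(name_to_ids)
    n_ids = len({acc for ids in name_to_ids.values() for acc in ids})
    ids_per_name = pairs / n_names
    names_per_id = pairs / n_ids if n_ids else 0.0
    if english_words:
        english = {w.casefold() for w in english_words}
        frac = sum(1 for n in name_to_ids if n in english) / n_names
    else:
        frac = 0.0
    return (ids_per_name, names_per_id, frac)
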