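"""Principle extraction and dominating-set summarization.

A *principle* is the ordered sequence of slot labels inside one gold
mention (unlabeled words are treated as insertions and dropped), e.g.
``hsa-miR-181b`` yields ``[Species][miRNA][Order]``.  Identical sequences
from different mentions merge with summed support.

Principles are then summarized: principle *p* dominates *q* when *q* is
derivable from *p* within configured insertion/deletion/substitution (IDS)
limits — by default a dominant may only *omit* slots (deletions ≤ 3), so a
long pattern such as ``[Precursor][Species][miRNA][Order][Conj][Order][Suffix]``
covers its shorter variants.  Because minimum dominating set is NP-hard,
the cover is built greedily: repeatedly pick the vertex dominating the
most not-yet-covered vertices.  Each pick becomes a cluster carrying the
statistics the acceptance threshold needs: core slots (in every member),
optional slots (in some), and the non-slot words its mentions contain.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import TYPE_CHECKING, Sequence

import networkx as nx

from .text import label_text

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import AnnotatedDocument
    from .scheme import SlotScheme

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Principle:
    """An ordered slot sequence with its training support."""

    slot_sequence: tuple[str, ...]
    support: int = 1

    def __post_init__(self) -> None:
        if not self.slot_sequence:
            raise ValueError("principle slot_sequence must be non-empty")

    def key(self) -> tuple[str, ...]:
        return self.slot_sequence

    def __str__(self) -> str:  # e.g. [Species][miRNA][Order]
        return "".join(f"[{s}]" for s in self.slot_sequence)


@dataclass(frozen=True)
class IDSCriteria:
    """Edit limits under which one principle may dominate another.

    The defaults let a dominant only *omit* slots, never add or replace
    them; the deletion budget of 4 is the smallest that derives every
    published dominated principle (e.g. ``[miRNA][Order][Suffix]`` drops
    Precursor, Species, Conj and one Order from the 7-slot dominant).
    """

    max_deletions: int = 4
    max_insertions: int = 0
    max_substitutions: int = 0


@dataclass
class CandidatePrinciple:
    """A principle plus the per-mention bookkeeping clustering needs."""

    principle: Principle
    # number of source mentions containing each non-slot word (presence, not count)
    nonslot_presence: Counter = field(default_factory=Counter)
    examples: list[str] = field(default_factory=list)


@dataclass
class PrincipleCluster:
    """One dominant principle with its dominated members and threshold data."""

    dominant: Principle
    dominated: list[Principle] = field(default_factory=list)
    core_slots: frozenset[str] = frozenset()
    optional_probs: dict[str, float] = field(default_factory=dict)
    nonslot_probs: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.0

    @property
    def members(self) -> list[Principle]:
        return [self.dominant, *self.dominated]

    def to_dict(self) -> dict:
        return {
            "dominant": list(self.dominant.slot_sequence),
            "dominant_support": self.dominant.support,
            "dominated": [
                {"slots": list(p.slot_sequence), "support": p.support}
                for p in self.dominated
            ],
            "core_slots": sorted(self.core_slots),
            "optional_probs": dict(sorted(self.optional_probs.items())),
            "nonslot_probs": dict(sorted(self.nonslot_probs.items())),
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrincipleCluster":
        return cls(
            dominant=Principle(tuple(d["dominant"]), d.get("dominant_support", 1)),
            dominated=[
                Principle(tuple(q["slots"]), q.get("support", 1))
                for q in d["dominated"]
            ],
            core_slots=frozenset(d["core_slots"]),
            optional_probs=dict(d["optional_probs"]),
            nonslot_probs=dict(d["nonslot_probs"]),
            threshold=d["threshold"],
        )


# -- extraction ----------------------------------------------------------


def extract_candidate_principles(
    docs: Sequence["AnnotatedDocument"], scheme: "SlotScheme"
) -> list[CandidatePrinciple]:
    """Turn every gold mention into its slot-sequence principle.

    Each annotation must align to token boundaries; misaligned or fully
    unlabeled annotations are skipped with a warning.  Multi-label tokens
    resolve to their most specific label (ancestors shadowed by
    descendants, then scheme declaration order).
    """
    found: dict[tuple[str, ...], CandidatePrinciple] = {}
    for doc in docs:
        seqs = label_text(doc.text, scheme)
        for ann in doc.annotations:
            covered: list[tuple] = []
            aligned = True
            for seq in seqs:
                for tok, labels in zip(seq.tokens, seq.labels):
                    if tok.end <= ann.start or tok.start >= ann.end:
                        continue
                    if tok.start < ann.start or tok.end > ann.end:
                        aligned = False
                    covered.append((tok, labels))
            if not aligned or not covered:
                warnings.warn(
                    f"annotation {doc.doc_id}:{ann.start}-{ann.end} ({ann.text!r}) "
                    "does not align to token boundaries; skipped"
                )
                continue
            slots = []
            nonslot_words = set()
            for tok, labels in covered:
                chosen = scheme.most_specific(labels)
                if chosen is not None:
                    slots.append(chosen)
                else:
                    nonslot_words.add(tok.text.casefold())
            if not slots:
                warnings.warn(
                    f"annotation {doc.doc_id}:{ann.start}-{ann.end} ({ann.text!r}) "
                    "contains no labeled token; skipped"
                )
                continue
            key = tuple(slots)
            cand = found.get(key)
            if cand is None:
                cand = found[key] = CandidatePrinciple(Principle(key, 0))
            cand.principle = Principle(key, cand.principle.support + 1)
            cand.nonslot_presence.update(nonslot_words)
            if len(cand.examples) < 5:
                cand.examples.append(ann.text)
    return sorted(found.values(), key=lambda c: (-c.principle.support, c.principle.key()))


# -- domination ----------------------------------------------------------


def dominates(p: Principle | Sequence[str], q: Principle | Sequence[str],
              criteria: IDSCriteria = IDSCriteria()) -> bool:
    """True iff q derives from p within the IDS edit limits (order kept).

    Deletions remove slots of p, insertions add slots of q, substitutions
    replace one slot with another; counted by a slot-level edit search.
    """
    ps = tuple(p.slot_sequence if isinstance(p, Principle) else p)
    qs = tuple(q.slot_sequence if isinstance(q, Principle) else q)

    @lru_cache(maxsize=None)
    def feasible(i: int, j: int, d: int, ins: int, sub: int) -> bool:
        if i == len(ps):
            need = len(qs) - j
            return need <= ins
        if j == len(qs):
            return len(ps) - i <= d
        if ps[i] == qs[j] and feasible(i + 1, j + 1, d, ins, sub):
            return True
        if sub > 0 and feasible(i + 1, j + 1, d, ins, sub - 1):
            return True
        if d > 0 and feasible(i + 1, j, d - 1, ins, sub):
            return True
        if ins > 0 and feasible(i, j + 1, d, ins - 1, sub):
            return True
        return False

    return feasible(0, 0, criteria.max_deletions, criteria.max_insertions,
                    criteria.max_substitutions)


def build_domination_graph(
    principles: Sequence[Principle], criteria: IDSCriteria = IDSCriteria()
) -> nx.DiGraph:
    """Directed graph with an edge p→q whenever p dominates q (p ≠ q)."""
    g = nx.DiGraph()
    for p in principles:
        g.add_node(p.key(), principle=p)
    for p in principles:
        for q in principles:
            if p.key() != q.key() and dominates(p, q, criteria):
                g.add_edge(p.key(), q.key())
    return g


def greedy_dominating_set(
    graph: nx.DiGraph,
    candidates: Sequence[CandidatePrinciple] | None = None,
) -> list[PrincipleCluster]:
    """Greedy dominating-set cover of the domination graph.

    Repeatedly selects the vertex covering the most not-yet-covered
    vertices (itself plus out-neighbors); ties break by higher support,
    longer slot sequence, then lexicographic order.  Every selected vertex
    becomes a cluster dominant together with *all* its out-neighbors, so a
    principle dominated by two dominants belongs to both clusters.  Cluster
    core/optional slot sets and non-slot word probabilities are computed
    from the members' source-mention bookkeeping when ``candidates`` is
    given.
    """
    by_key: dict[tuple[str, ...], CandidatePrinciple] = {}
    if candidates is not None:
        by_key = {c.principle.key(): c for c in candidates}

    uncovered = set(graph.nodes)
    clusters: list[PrincipleCluster] = []
    while uncovered:
        def gain(v):
            return len(({v} | set(graph.successors(v))) & uncovered)

        best = max(
            graph.nodes,
            key=lambda v: (gain(v), graph.nodes[v]["principle"].support, len(v)),
        )
        # deterministic final tie-break: among equal (gain, support, len),
        # take lexicographically smallest key
        contenders = [
            v
            for v in graph.nodes
            if (gain(v), graph.nodes[v]["principle"].support, len(v))
            == (gain(best), graph.nodes[best]["principle"].support, len(best))
        ]
        best = min(contenders)
        if gain(best) == 0:  # pragma: no cover - cannot happen while uncovered
            best = min(uncovered)
        members_keys = [best, *sorted(graph.successors(best))]
        uncovered -= {best, *graph.successors(best)}
        dominant = graph.nodes[best]["principle"]
        dominated = [graph.nodes[k]["principle"] for k in members_keys[1:]]
        cluster = PrincipleCluster(dominant=dominant, dominated=dominated)
        _fill_cluster_sets(cluster, [by_key.get(k) for k in members_keys])
        clusters.append(cluster)
    return clusters


def _fill_cluster_sets(
    cluster: PrincipleCluster, cands: list[CandidatePrinciple | None]
) -> None:
    """Compute core/optional slots and member-mention probabilities."""
    members = cluster.members
    slot_sets = [set(p.slot_sequence) for p in members]
    core = set.intersection(*slot_sets)
    all_slots = set.union(*slot_sets)
    cluster.core_slots = frozenset(core)
    total = sum(p.support for p in members)
    optional: dict[str, float] = {}
    for s in sorted(all_slots - core):
        present = sum(
            p.support for p, ss in zip(members, slot_sets) if s in ss
        )
        optional[s] = present / total if total else 0.0
    cluster.optional_probs = optional
    nonslot: Counter = Counter()
    for c in cands:
        if c is not None:
            nonslot.update(c.nonslot_presence)
    cluster.nonslot_probs = (
        {w: min(1.0, n / total) for w, n in sorted(nonslot.items())} if total else {}
    )


def exact_minimum_dominating_set_size(graph: nx.DiGraph) -> int:
    """Brute-force minimum dominating set size (test oracle; small graphs)."""
    from itertools import combinations

    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        return 0
    for k in range(1, n + 1):
        for sub in combinations(nodes, k):
            covered = set(sub)
            for v in sub:
                covered.update(graph.successors(v))
            if len(covered) == n:
                return k
    return n  # pragma: no cover
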