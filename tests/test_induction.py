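"""Principle extraction, domination and the greedy dominating-set cover."""

import math
import random

import networkx as nx
import pytest

from mirslot.corpus import AnnotatedDocument, Annotation
from mirslot.induction import (
    IDSCriteria,
    Principle,
    build_domination_graph,
    dominates,
    exact_minimum_dominating_set_size,
    extract_candidate_principles,
    greedy_dominating_set,
)

TABLE_DOMINANT = ("Precursor", "Species", "miRNA", "Order", "Conj", "Order", "Suffix")
TABLE_DOMINATED = [
    ("Species", "miRNA", "Order", "Order"),
    ("Precursor", "miRNA", "Order", "Order"),
    ("miRNA", "Order", "Suffix"),
]


def _doc(text, spans):
    return AnnotatedDocument("d0", text, [Annotation(s, e, text[s:e]) for s, e in spans])


class TestExtraction:
    @pytest.mark.parametrize(
        "mention,expected",
        [
            ("hsa-miR-181b", ("Species", "miRNA", "Order")),
            ("pre-miR-149", ("Precursor", "miRNA", "Order")),
            ("miR-485-5p", ("miRNA", "Order", "Hairpin")),
        ],
    )
    def test_mention_to_principle(self, scheme, mention, expected):
        text = f"levels of {mention} were low."
        start = text.index(mention)
        cands = extract_candidate_principles(
            [_doc(text, [(start, start + len(mention))])], scheme
        )
        assert [c.principle.slot_sequence for c in cands] == [expected]
        assert cands[0].principle.support == 1

    def test_identical_sequences_merge_with_summed_support(self, scheme):
        text = "hsa-miR-21 rose while hsa-miR-16 fell."
        spans = [(0, 10), (22, 32)]
        cands = extract_candidate_principles([_doc(text, spans)], scheme)
        assert len(cands) == 1
        assert cands[0].principle.support == 2
        # both mentions contribute the hyphen as a non-slot word
        assert cands[0].nonslot_presence["-"] == 2

    def test_unlabeled_mention_warns_and_is_skipped(self, scheme):
        with pytest.warns(UserWarning, match="no labeled token"):
            cands = extract_candidate_principles([_doc("abcde fghij.", [(0, 5)])], scheme)
        assert cands == []

    def test_misaligned_span_warns_and_is_skipped(self, scheme):
        text = "hsa-miR-181b fell."
        with pytest.warns(UserWarning, match="token boundaries"):
            cands = extract_candidate_principles([_doc(text, [(0, 10)])], scheme)
        assert cands == []


class TestDominates:
    def test_table_dominance_relations_under_default_criteria(self):
        for q in TABLE_DOMINATED:
            assert dominates(TABLE_DOMINANT, q, IDSCriteria())

    def test_three_deletion_derivation(self):
        # [Species][miRNA][Order][Order] drops exactly Precursor, Conj, Suffix
        crit = IDSCriteria(max_deletions=3, max_insertions=0, max_substitutions=0)
        assert dominates(TABLE_DOMINANT, TABLE_DOMINATED[0], crit)

    def test_reflexive(self):
        p = Principle(("miRNA", "Order"))
        assert dominates(p, p, IDSCriteria(0, 0, 0))

    def test_insufficient_deletions(self):
        # slot edit distance 3 (three insertions needed) > limits
        assert not dominates(
            ("miRNA",), ("Species", "miRNA", "Order", "Order"), IDSCriteria(1, 0, 0)
        )

    def test_edit_operation_budgets(self):
        assert dominates(("A", "B"), ("A", "C"), IDSCriteria(0, 0, 1))
        # a substitution is also achievable as one deletion plus one insertion
        assert dominates(("A", "B"), ("A", "C"), IDSCriteria(1, 1, 0))
        assert not dominates(("A", "B"), ("A", "C"), IDSCriteria(1, 0, 0))
        assert dominates(("A",), ("A", "B"), IDSCriteria(0, 1, 0))
        assert not dominates(("A",), ("A", "B"), IDSCriteria(3, 0, 0))

    def test_agrees_with_bruteforce_edit_distance(self):
        # oracle: slot edit distance by DP; feasible iff each op count fits
        def edit_ops(p, q):
            # returns set of (d,i,s) pareto-minimal triples via exhaustive DP
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def rec(i, j):
                if i == len(p) and j == len(q):
                    return {(0, 0, 0)}
                out = set()
                if i < len(p) and j < len(q):
                    for d, ins, s in rec(i + 1, j + 1):
                        out.add((d, ins, s) if p[i] == q[j] else (d, ins, s + 1))
                if i < len(p):
                    for d, ins, s in rec(i + 1, j):
                        out.add((d + 1, ins, s))
                if j < len(q):
                    for d, ins, s in rec(i, j + 1):
                        out.add((d, ins + 1, s))
                return out

            return rec(0, 0)

        rng = random.Random(0)
        alphabet = ["A", "B", "C"]
        for _ in range(60):
            p = tuple(rng.choice(alphabet) for _ in range(rng.randint(1, 4)))
            q = tuple(rng.choice(alphabet) for _ in range(rng.randint(1, 4)))
            crit = IDSCriteria(rng.randint(0, 2), rng.randint(0, 2), rng.randint(0, 2))
            expected = any(
                d <= crit.max_deletions and i <= crit.max_insertions and s <= crit.max_substitutions
                for d, i, s in edit_ops(p, q)
            )
            assert dominates(p, q, crit) == expected, (p, q, crit)


class TestGreedyCover:
    def _graph(self, principles, crit=IDSCriteria()):
        return build_domination_graph(principles, crit)

    def test_table_principles_form_one_cluster(self):
        principles = [Principle(TABLE_DOMINANT)] + [Principle(q) for q in TABLE_DOMINATED]
        clusters = greedy_dominating_set(self._graph(principles))
        assert len(clusters) == 1
        assert clusters[0].dominant.slot_sequence == TABLE_DOMINANT
        assert {p.slot_sequence for p in clusters[0].dominated} == set(TABLE_DOMINATED)

    def test_edgeless_graph_every_principle_its_own_cluster(self):
        principles = [Principle(("A",)), Principle(("B",)), Principle(("C",))]
        g = nx.DiGraph()
        for p in principles:
            g.add_node(p.key(), principle=p)
        clusters = greedy_dominating_set(g)
        assert len(clusters) == 3
        assert all(not c.dominated for c in clusters)

    def test_star_graph_single_cluster(self):
        # one dominator of n others -> exactly 1 cluster; exhaustive check
        # confirms 1 is also the minimum for every n <= 6
        for n in range(1, 7):
            hub = Principle(tuple("ABCDEFG"[: n + 1]))
            leaves = [Principle(tuple("ABCDEFG"[: n + 1][:k])) for k in range(1, n + 1)]
            g = nx.DiGraph()
            for p in [hub, *leaves]:
                g.add_node(p.key(), principle=p)
            for leaf in leaves:
                g.add_edge(hub.key(), leaf.key())
            clusters = greedy_dominating_set(g)
            assert len(clusters) == 1
            assert exact_minimum_dominating_set_size(g) == 1

    def test_coverage_no_principle_lost(self, noiseless_corpus, scheme):
        cands = extract_candidate_principles(noiseless_corpus.documents, scheme)
        graph = build_domination_graph([c.principle for c in cands])
        clusters = greedy_dominating_set(graph, cands)
        covered = set()
        for c in clusters:
            covered.add(c.dominant.key())
            covered.update(p.key() for p in c.dominated)
        assert covered == {c.principle.key() for c in cands}

    def test_cluster_sets_core_optional_nonslot(self):
        principles = [Principle(TABLE_DOMINANT, 5)] + [
            Principle(q, 2) for q in TABLE_DOMINATED
        ]
        clusters = greedy_dominating_set(self._graph(principles))
        c = clusters[0]
        # miRNA and Order appear in every member; others in some only
        assert c.core_slots == frozenset({"miRNA", "Order"})
        assert set(c.optional_probs) == {"Precursor", "Species", "Conj", "Suffix"}
        total = 5 + 2 + 2 + 2
        assert c.optional_probs["Species"] == pytest.approx((5 + 2) / total)
        assert all(0.0 <= p <= 1.0 for p in c.optional_probs.values())

    def test_determinism(self, noiseless_corpus, scheme):
        def run():
            cands = extract_candidate_principles(noiseless_corpus.documents, scheme)
            graph = build_domination_graph([c.principle for c in cands])
            return [c.to_dict() for c in greedy_dominating_set(graph, cands)]

        assert run() == run()

    def test_greedy_within_log_bound_of_exact_minimum(self):
        # random digraphs, n <= 12: greedy cover >= minimum and
        # <= (1 + ln n) * minimum
        rng = random.Random(42)
        for trial in range(30):
            n = rng.randint(2, 12)
            g = nx.DiGraph()
            principles = [Principle((f"S{i}",)) for i in range(n)]
            for p in principles:
                g.add_node(p.key(), principle=p)
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.25:
                        g.add_edge(principles[i].key(), principles[j].key())
            greedy_size = len(greedy_dominating_set(g))
            exact = exact_minimum_dominating_set_size(g)
            assert exact <= greedy_size <= math.ceil((1 + math.log(n)) * exact)
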