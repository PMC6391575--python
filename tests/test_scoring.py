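"""Statistics estimation and the match/insertion/deletion/threshold scores."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirslot.corpus import AnnotatedDocument, Annotation
from mirslot.induction import Principle, PrincipleCluster
from mirslot.scoring import (
    SlotStatistics,
    cluster_threshold,
    deletion_penalty,
    estimate_statistics,
    insertion_penalty,
    match_score,
    score_components,
)

INF = float("inf")


def _stats(**symbols) -> SlotStatistics:
    """Build statistics from symbol=(freq_in, freq_out) pairs.

    Lower-case single-character keys become non-slot words.
    """
    slot_counts = {}
    nonslot = {}
    for k, (fm, fn) in symbols.items():
        (nonslot if len(k) == 1 else slot_counts)[k] = [float(fm), float(fn)]
    return SlotStatistics(slot_counts=slot_counts, nonslot_counts=nonslot)


class TestEstimateStatistics:
    def test_inside_outside_bookkeeping(self, scheme):
        # 'hsa' appears once inside a mention and once outside
        text = "hsa cells express hsa-miR-21 today."
        doc = AnnotatedDocument("d", text, [Annotation(18, 28, text[18:28])])
        stats = estimate_statistics([doc], scheme)
        assert stats.slot_counts["Species"] == [1.0, 1.0]
        assert stats.p_mirna("Species") == 0.5
        # the hyphen only occurs inside the mention
        assert stats.nonslot_counts["-"] == [2.0, 0.0]

    def test_ratio_three_inside_one_outside(self, scheme):
        text = "pre cursor words pre-miR-1 and pre-miR-2 and pre-miR-3 end."
        spans = [(17, 26), (31, 40), (45, 54)]
        doc = AnnotatedDocument("d", text, [Annotation(s, e, text[s:e]) for s, e in spans])
        stats = estimate_statistics([doc], scheme)
        assert stats.slot_counts["Precursor"] == [3.0, 1.0]
        assert stats.p_mirna("Precursor") == 0.75

    def test_symbol_absent_from_corpus_not_in_statistics(self, scheme):
        doc = AnnotatedDocument("d", "hsa-miR-21 rose.", [Annotation(0, 10, "hsa-miR-21")])
        stats = estimate_statistics([doc], scheme)
        assert "Conj" not in stats.slot_counts
        assert stats.p_mirna("Conj") is None

    def test_outside_only_words_are_not_nonslot_symbols(self, scheme):
        doc = AnnotatedDocument("d", "filler words hsa-miR-21.", [Annotation(13, 23, "hsa-miR-21")])
        stats = estimate_statistics([doc], scheme)
        assert "filler" not in stats.nonslot_counts

    def test_empty_corpus_raises(self, scheme):
        with pytest.raises(ValueError, match="empty corpus"):
            estimate_statistics([], scheme)

    def test_noiseless_corpus_suffix_is_mention_exclusive(self, noiseless_corpus, scheme):
        stats = estimate_statistics(noiseless_corpus.documents, scheme)
        assert stats.slot_counts["Suffix"][1] == 0.0


class TestMatchScore:
    def test_mention_exclusive_slot_scores_lambda(self):
        s = _stats(Suffix=(37, 0))
        assert match_score("Suffix", s) == 100.0

    def test_never_inside_scores_zero(self):
        s = _stats(Conj=(0, 12))
        assert match_score("Conj", s) == 0.0

    def test_symmetric_case_scores_half_lambda(self):
        s = _stats(Species=(30, 30))
        assert match_score("Species", s) == 50.0

    def test_unseen_slot_falls_back_to_half_lambda(self):
        assert match_score("Ghost", _stats(Species=(1, 0))) == 50.0

    def test_bounds_and_monotonicity(self):
        prev = -1.0
        for fm in range(0, 11):
            s = _stats(X1=(fm, 10 - fm))
            v = match_score("X1", s)
            assert 0.0 <= v <= 100.0
            assert v > prev
            prev = v


class TestInsertionPenalty:
    def test_zero_when_never_outside(self):
        assert insertion_penalty("Suffix", _stats(Suffix=(5, 0))) == 0.0

    def test_infinite_when_never_inside(self):
        assert insertion_penalty("Conj", _stats(Conj=(0, 5))) == INF

    def test_maximum_entropy_gives_penalty_one(self):
        assert insertion_penalty("Species", _stats(Species=(5, 5))) == pytest.approx(1.0)

    def test_unseen_symbol_uses_config_ceiling(self):
        s = SlotStatistics(slot_counts={}, nonslot_counts={}, unseen_insertion=30.0)
        assert insertion_penalty("whatever", s) == 30.0

    @given(st.integers(1, 200), st.integers(1, 200))
    def test_symmetry_in_the_two_probabilities(self, fm, fn):
        a = insertion_penalty("X1", _stats(X1=(fm, fn)))
        b = insertion_penalty("X1", _stats(X1=(fn, fm)))
        assert a == pytest.approx(b)
        assert a >= 1.0  # 1/H with H <= 1


class TestDeletionPenalty:
    @pytest.mark.parametrize(
        "fm,fn,expected",
        [(5, 0, 0.0), (5, 5, 1.0), (1, 3, 2.0)],
    )
    def test_log_probability_values(self, fm, fn, expected):
        assert deletion_penalty("X1", _stats(X1=(fm, fn))) == pytest.approx(expected)

    def test_impossible_slot_deletion_is_infinite(self):
        assert deletion_penalty("X1", _stats(X1=(0, 5))) == INF


class TestSequenceScore:
    def test_additivity_two_exclusive_slots(self):
        s = _stats(A1=(5, 0), B1=(7, 0))
        assert score_components(["A1", "B1"], [], [], s) == 200.0

    def test_empty_alignment_scores_zero(self):
        assert score_components([], [], [], _stats(A1=(1, 0))) == 0.0

    def test_hand_evaluated_mixed_case(self):
        # M gains 100, insertion penalty 1 (max entropy), deletion penalty 2
        s = _stats(A1=(5, 0), B1=(3, 3), C1=(1, 3))
        assert score_components(["A1"], ["B1"], ["C1"], s) == pytest.approx(97.0)

    def test_infinite_penalty_rejects(self):
        s = _stats(A1=(5, 0), Z1=(0, 4))
        assert score_components(["A1"], ["Z1"], [], s) == float("-inf")
        assert score_components(["A1"], [], ["Z1"], s) == float("-inf")

    def test_moving_match_to_deletion_never_raises_score(self):
        import random

        rng = random.Random(3)
        for _ in range(50):
            syms = {f"S{i}": (rng.randint(1, 9), rng.randint(0, 9)) for i in range(4)}
            s = _stats(**syms)
            names = list(syms)
            matched = names[:2]
            base = score_components(matched, [], [], s)
            moved = score_components(matched[:1], [], matched[1:], s)
            grown = score_components(matched, [names[2]], [], s)
            assert moved <= base
            assert grown <= base


class TestClusterThreshold:
    def _cluster(self, dominant, core, optional=None, nonslot=None):
        return PrincipleCluster(
            dominant=Principle(tuple(dominant)),
            dominated=[],
            core_slots=frozenset(core),
            optional_probs=optional or {},
            nonslot_probs=nonslot or {},
        )

    def test_single_exclusive_core_slot(self):
        s = _stats(A1=(5, 0))
        c = self._cluster(["A1"], ["A1"])
        assert cluster_threshold(c, s) == 100.0

    def test_noncore_slot_lowers_threshold_by_its_deletion_penalty(self):
        s = _stats(A1=(5, 0), C1=(1, 3))  # deletion penalty 2
        base = cluster_threshold(self._cluster(["A1"], ["A1"]), s)
        with_extra = cluster_threshold(self._cluster(["A1", "C1"], ["A1"]), s)
        assert base - with_extra == pytest.approx(2.0)

    def test_insertion_mode_flips_sign_of_expected_insertions(self):
        s = _stats(A1=(5, 0), B1=(3, 3))
        c = self._cluster(["A1"], ["A1"], optional={"B1": 0.5})
        sub = cluster_threshold(c, s, "subtract")
        add = cluster_threshold(c, s, "add")
        assert sub == pytest.approx(100.0 - 0.5)
        assert add == pytest.approx(100.0 + 0.5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cluster_threshold(self._cluster(["A1"], ["A1"]), _stats(A1=(1, 0)), "bogus")

    def test_brute_force_recomputation_on_trained_clusters(self, noisy_model):
        # independent spreadsheet-style evaluation of the threshold formula
        stats = noisy_model.stats
        lam = stats.lambda_scale

        def p(sym):
            fm, fn = (stats.slot_counts.get(sym) or stats.nonslot_counts[sym])
            return fm / (fm + fn)

        def pen_i(sym):
            pm = p(sym)
            if pm == 1.0:
                return 0.0
            h = -(pm * math.log2(pm) + (1 - pm) * math.log2(1 - pm))
            return 1.0 / h

        for c in noisy_model.clusters:
            expected = sum(lam * p(s) for s in sorted(c.core_slots))
            expected -= sum(
                -math.log2(p(s))
                for s in sorted(set(c.dominant.slot_sequence) - set(c.core_slots))
            )
            expected -= sum(q * pen_i(s) for s, q in sorted(c.optional_probs.items()))
            expected -= sum(q * pen_i(w) for w, q in sorted(c.nonslot_probs.items()))
            assert c.threshold == pytest.approx(expected, abs=1e-6)
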