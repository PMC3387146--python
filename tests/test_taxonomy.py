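"""Naive-Bayes taxonomy: training statistics, classification, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from ampliclass.taxonomy import (DEFAULT_RANKS, ReferenceDB, assign_all,
                                 classify, distinct_words, train)


def lineage(genus: str, family: str = "F", phylum: str = "P") -> tuple:
    return ("Bacteria", phylum, "C", "O", family, genus)


def brute_force_genus(reference: ReferenceDB, seq: str, k: int) -> str:
    """Independent oracle: argmax over exhaustively computed joint probabilities.

    Recomputes all word counts with plain loops and multiplies raw (unlogged)
    conditional probabilities; ties go to the lexicographically smallest
    genus.
    """
    records = reference.records
    N = len(records)
    genera = sorted({lin[-1] for _, _, lin in records})
    M = {g: sum(1 for _, _, lin in records if lin[-1] == g) for g in genera}
    read_words = distinct_words(seq, k)
    best_g, best_p = None, -1.0
    for g in genera:
        joint = 1.0
        for w in read_words:
            n_w = sum(1 for _, s, _ in records if w in distinct_words(s, k))
            m_wg = sum(1 for _, s, lin in records
                       if lin[-1] == g and w in distinct_words(s, k))
            p_w = (n_w + 0.5) / (N + 1)
            joint *= (m_wg + p_w) / (M[g] + 1)
        if joint > best_p:
            best_g, best_p = g, joint
    return best_g


class TestTrain:
    def test_word_statistics_match_hand_computation(self):
        # two sequences, one genus each; word "AAAACCCC" only in the first
        ref = ReferenceDB([
            ("a", "AAAACCCC", lineage("GenusA")),
            ("b", "GGGGTTTT", lineage("GenusB")),
        ])
        model = train(ref, word_size=8)
        N = 2
        p_w = (1 + 0.5) / (N + 1)                   # word in 1 of 2 sequences
        i = model.word_index["AAAACCCC"]
        ga = model.genera.index("GenusA")
        gb = model.genera.index("GenusB")
        assert model.log_cond[i, ga] == pytest.approx(math.log((1 + p_w) / (1 + 1)))
        assert model.log_cond[i, gb] == pytest.approx(math.log((0 + p_w) / (1 + 1)))

    def test_unseen_word_floor_is_positive(self):
        ref = ReferenceDB([("a", "A" * 20, lineage("GenusA"))])
        model = train(ref)
        # P(w) for an absent word is 0.5/(N+1) > 0
        assert np.all(np.isfinite(model.log_unseen))
        assert model.log_unseen[0] == pytest.approx(math.log((0.5 / 2) / 2))

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            train(ReferenceDB([]))

    def test_duplicate_record_collapsed_with_warning(self):
        rec = ("a", "ACGTACGTACGT", lineage("GenusA"))
        with pytest.warns(UserWarning, match="duplicate"):
            model = train(ReferenceDB([rec, rec]))
        assert model.genera == ["GenusA"]


class TestClassify:
    def test_single_genus_reference_confidence_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 200))
        model = train(ReferenceDB([("a", seq, lineage("OnlyGenus"))]))
        a = classify(model, ("q", seq[10:150]), seed=0)
        assert a.labels["genus"] == "OnlyGenus"
        assert all(c == 1.0 for c in a.confidences.values())

    def test_disjoint_word_sets_full_confidence(self):
        # genus A all-A-rich words, genus B all-G-rich; no shared 8-mer
        ref = ReferenceDB([
            ("a", "ACACACACACACACACACAC", lineage("GenusA")),
            ("b", "GTGTGTGTGTGTGTGTGTGT", lineage("GenusB")),
        ])
        model = train(ref)
        a = classify(model, ("q", "ACACACACACACAC"), seed=0)
        assert a.best_genus == "GenusA"
        assert a.confidences["genus"] == 1.0

    def test_too_short_read_unclassified(self, five_genus_reference):
        model = train(five_genus_reference)
        a = classify(model, ("q", "ACGTACG"), seed=0)  # 7 nt < word size 8
        assert a.unclassified_reason == "too_short"
        assert all(lbl is None for lbl in a.labels.values())

    def test_tie_broken_lexicographically_and_flagged(self):
        seq = "ACGTACGTACGTACGT"
        ref = ReferenceDB([
            ("a", seq, lineage("GenusB")),
            ("b", seq, lineage("GenusA")),
        ])
        model = train(ref)
        a = classify(model, ("q", seq), seed=0)
        assert a.best_genus == "GenusA"
        assert a.tie

    def test_self_classification_on_synthetic_reference(self, five_genus_reference):
        model = train(five_genus_reference)
        for rid, seq, lin in five_genus_reference.records[::3]:
            a = classify(model, (rid, seq), seed=1)
            assert a.best_genus == lin[-1]
            assert a.confidences["genus"] >= 0.99

    def test_confidences_in_unit_interval(self, five_genus_reference):
        model = train(five_genus_reference)
        rng = np.random.default_rng(3)
        read = "".join(rng.choice(list("ACGT"), 80))
        a = classify(model, ("q", read), seed=2)
        for rank in DEFAULT_RANKS:
            assert 0.0 <= a.confidences[rank] <= 1.0
            if a.labels[rank] is None:
                assert rank != "domain" or a.confidences[rank] < 0.8

    def test_duplicate_reads_get_identical_assignments(self, five_genus_reference):
        model = train(five_genus_reference)
        seq = five_genus_reference.records[0][1][100:300]
        a1 = classify(model, ("q", seq), seed=9)
        a2 = classify(model, ("q", seq), seed=9)
        assert a1.labels == a2.labels and a1.confidences == a2.confidences

    @pytest.mark.parametrize("seed", range(6))
    def test_winner_matches_brute_force_oracle(self, seed):
        """<=3 genera, short reads: argmax equals exhaustive joint probability."""
        rng = np.random.default_rng(seed)
        n_genera = int(rng.integers(2, 4))
        records = []
        for g in range(n_genera):
            for s in range(int(rng.integers(1, 3))):
                seq = "".join(rng.choice(list("ACGT"), 30))
                records.append((f"g{g}s{s}", seq, lineage(f"Genus{g}")))
        ref = ReferenceDB(records)
        model = train(ref)
        # query with <=12 distinct words, partly borrowed from a reference
        src = records[int(rng.integers(0, len(records)))][1]
        query = src[:15] + "".join(rng.choice(list("ACGT"), 4))
        assert len(distinct_words(query, 8)) <= 12
        a = classify(model, ("q", query), seed=0)
        assert a.best_genus == brute_force_genus(ref, query, 8)


class TestAssignAll:
    def test_empty_batch(self, five_genus_reference):
        model = train(five_genus_reference)
        table = assign_all(model, [])
        assert len(table) == 0

    def test_batch_accuracy_and_determinism(self, five_genus_reference):
        from ampliclass import CohortSpec, ReadSimSpec, simulate_reads

        model = train(five_genus_reference)
        spec = ReadSimSpec(
            cohort=CohortSpec(n_per_class={"a": 2, "b": 2}, n_taxa=5,
                              depth_mean=150, seed=4),
            reference=five_genus_reference, seed=4)
        result = simulate_reads(spec)
        t1 = assign_all(model, result.reads, seed=5)
        t2 = assign_all(model, result.reads, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert list(t1["read_id"]) == [r.id for r in result.reads]  # order kept
        truth = result.read_truth.set_index("read_id")["genus"]
        acc = (t1.set_index("read_id")["best_genus"] == truth).mean()
        assert acc >= 0.95
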