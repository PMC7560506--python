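"""Bigram tokenization, incidence, phi, and network construction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oneironet.cooccurrence import (
    NetworkThresholds,
    PairCount,
    UndefinedStatisticError,
    build_incidence,
    build_network,
    pair_counts,
    phi,
    tokenize_bigrams,
)

from conftest import make_report


class TestTokenizeBigrams:
    def test_worked_example(self):
        tokens = ["tuberculosis", "doctor", "anger", "symptom"]
        assert tokenize_bigrams(tokens) == [
            ("tuberculosis", "doctor"), ("doctor", "anger"), ("anger", "symptom")]

    @pytest.mark.parametrize("tokens,expected", [
        (["corona"], []),
        ([], []),
        (["crowd", "party", "crowd"], [("crowd", "party"), ("party", "crowd")]),
    ])
    def test_short_and_repeating_inputs(self, tokens, expected):
        assert tokenize_bigrams(tokens) == expected


class TestIncidence:
    def test_doc_freq_hand_count(self, four_report_corpus):
        inc = build_incidence(four_report_corpus)
        assert inc.doc_freq == {"corona": 3, "death": 2, "work": 2}

    def test_within_report_duplicates_count_once(self):
        inc = build_incidence([make_report("r1", ["a", "a", "b"])])
        assert inc.doc_freq == {"a": 1, "b": 1}

    def test_disjoint_vocabularies(self):
        reports = [make_report("r1", ["a"]), make_report("r2", ["b"])]
        assert build_incidence(reports).doc_freq == {"a": 1, "b": 1}

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError):
            build_incidence([])


class TestPairCounts:
    def test_hand_counted_table(self, four_report_corpus):
        inc = build_incidence(four_report_corpus)
        pc = pair_counts(inc, "corona", "death")
        assert (pc.n11, pc.n10, pc.n01, pc.n00) == (1, 2, 1, 0)
        assert pc.n_reports == 4

    def test_self_pair_rejected(self, four_report_corpus):
        inc = build_incidence(four_report_corpus)
        with pytest.raises(ValueError):
            pair_counts(inc, "corona", "corona")

    def test_never_cooccurring_words(self):
        reports = [make_report("r1", ["a"]), make_report("r2", ["a"]),
                   make_report("r3", ["b"]), make_report("r4", ["b"])]
        pc = pair_counts(build_incidence(reports), "a", "b")
        assert (pc.n11, pc.n10, pc.n01, pc.n00) == (0, 2, 2, 0)

    def test_symmetric_up_to_margin_swap(self, four_report_corpus):
        inc = build_incidence(four_report_corpus)
        assert pair_counts(inc, "death", "corona") == pair_counts(inc, "corona", "death")

    def test_unknown_word_rejected(self, four_report_corpus):
        inc = build_incidence(four_report_corpus)
        with pytest.raises(KeyError):
            pair_counts(inc, "corona", "ghost")


class TestPhi:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 0, 0, 5), 1.0),
        ((25, 25, 25, 25), 0.0),
        ((3, 2, 1, 4), 0.408248290463863),  # Pearson of the binary vectors
    ])
    def test_known_values(self, counts, expected):
        pc = PairCount("a", "b", *counts)
        assert phi(pc) == pytest.approx(expected, abs=1e-12)

    def test_zero_margin_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            phi(PairCount("a", "b", 3, 0, 2, 0))  # b present everywhere

    def test_equals_binary_pearson_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(4, 30))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            pc = PairCount("a", "b",
                           int(((a == 1) & (b == 1)).sum()),
                           int(((a == 1) & (b == 0)).sum()),
                           int(((a == 0) & (b == 1)).sum()),
                           int(((a == 0) & (b == 0)).sum()))
            assert phi(pc) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)


class TestBuildNetwork:
    def test_all_words_rare_gives_empty_network(self):
        reports = [make_report(f"r{i}", [f"w{i}", f"v{i}"]) for i in range(10)]
        net = build_network(reports)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_perfectly_cooccurring_pair_retained_with_phi_one(self):
        reports = [make_report(f"r{i}", ["x", "y"]) for i in range(6)]
        reports += [make_report(f"s{i}", [f"rare{i}", f"other{i}"]) for i in range(6)]
        net = build_network(reports)
        assert set(net.edges) == {("x", "y")}
        assert net.edges[("x", "y")][0] == pytest.approx(1.0)
        assert net.nodes == {"x": 6, "y": 6}

    def test_permissive_thresholds_give_complete_graph_minus_undefined(
            self, four_report_corpus):
        # every word pair has defined phi here; with |phi| thresholding at -1
        # the network is the complete graph on the three words
        net = build_network(four_report_corpus,
                            NetworkThresholds(min_doc_freq=1, min_phi=-1.0),
                            keep_negative=True)
        assert set(net.nodes) == {"corona", "death", "work"}
        assert set(net.edges) == {("corona", "death"), ("corona", "work"),
                                  ("death", "work")}

    def test_edges_carry_bigram_counts(self, four_report_corpus):
        net = build_network(four_report_corpus,
                            NetworkThresholds(min_doc_freq=1, min_phi=-1.0),
                            keep_negative=True)
        # corona-death adjacent once (r1); corona-work adjacent in r2 and r4
        assert net.edges[("corona", "death")][1] == 1
        assert net.edges[("corona", "work")][1] == 2

    def test_default_threshold_is_strict(self):
        # craft a pair with phi exactly at threshold: phi=0.2 must be dropped
        pc = PairCount("x", "y", 3, 2, 2, 3)
        assert phi(pc) == pytest.approx(0.2)
        reports = []
        idx = 0
        for n11 in range(3):
            idx += 1
            reports.append(make_report(f"r{idx}", ["x", "y"]))
        for _ in range(2):
            idx += 1
            reports.append(make_report(f"r{idx}", ["x", "pad"]))
        for _ in range(2):
            idx += 1
            reports.append(make_report(f"r{idx}", ["y", "pad"]))
        for _ in range(3):
            idx += 1
            reports.append(make_report(f"r{idx}", ["pad", "pad2"]))
        net = build_network(reports, NetworkThresholds(min_doc_freq=1, min_phi=0.2))
        assert ("x", "y") not in net.edges

    def test_report_order_invariance(self):
        rng = np.random.default_rng(3)
        reports, _ = _random_corpus(rng)
        net_a = build_network(reports, NetworkThresholds(2, 0.1))
        shuffled = [reports[i] for i in rng.permutation(len(reports))]
        net_b = build_network(shuffled, NetworkThresholds(2, 0.1))
        assert net_a.nodes == net_b.nodes and net_a.edges == net_b.edges


def _random_corpus(rng, n_reports=40, vocab=12):
    words = [f"w{i}" for i in range(vocab)]
    reports = []
    for i in range(n_reports):
        length = int(rng.integers(1, 6))
        tokens = [words[int(k)] for k in rng.integers(0, vocab, length)]
        reports.append(make_report(f"r{i}", tokens))
    return reports, words


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seed=st.integers(0, 10_000),
       min_doc_freq=st.integers(1, 6),
       min_phi=st.floats(-1.0, 0.9))
def test_network_invariants_hold_for_random_corpora(seed, min_doc_freq, min_phi):
    """Every construction satisfies the declared structural invariants."""
    rng = np.random.default_rng(seed)
    reports, _ = _random_corpus(rng)
    thresholds = NetworkThresholds(min_doc_freq=min_doc_freq, min_phi=min_phi)
    net = build_network(reports, thresholds)
    net.validate()
    inc = build_incidence(reports)
    for (a, b), (phi_val, _) in net.edges.items():
        assert phi_val > min_phi
        assert phi_val == pytest.approx(phi(pair_counts(inc, a, b)), abs=1e-9)
    # no retained-but-isolated words
    assert set(net.nodes) == {w for pair in net.edges for w in pair}
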