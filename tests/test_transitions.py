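"""Transition counting, frequency-preserving randomization, and the
Monte-Carlo significance test, checked against an exhaustive-enumeration
oracle on tiny corpora."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalcomb.errors import LabelError, ParameterError, VocalcombError
from vocalcomb.transitions import (
    SequenceCorpus,
    TransitionMatrix,
    TransitionTestResult,
    count_transitions,
    export_transition_graph,
    permutation_test,
    randomize_corpus,
)

# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of token-to-slot assignments
# ---------------------------------------------------------------------------


def exhaustive_null(corpus: SequenceCorpus) -> list[np.ndarray]:
    """All distinct transition-probability matrices under uniform random
    assignment of the token multiset to the fixed sequence slots, one entry
    per distinct flat arrangement (each equally likely)."""
    tokens = [t for s in corpus.sequences for t in s]
    lengths = [len(s) for s in corpus.sequences]
    alphabet = corpus.alphabet
    idx = {a: i for i, a in enumerate(alphabet)}
    mats = []
    for arrangement in set(itertools.permutations(tokens)):
        counts = np.zeros((len(alphabet), len(alphabet)))
        off = 0
        for ln in lengths:
            seq = arrangement[off:off + ln]
            for a, b in zip(seq, seq[1:]):
                counts[idx[a], idx[b]] += 1
            off += ln
        sums = counts.sum(axis=1, keepdims=True)
        probs = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
        mats.append(probs)
    return mats


def exact_two_tailed_p(null_mats, observed, i, j):
    vals = np.array([m[i, j] for m in null_mats])
    obs = observed[i, j]
    eps = 1e-12
    lo = np.mean(vals <= obs + eps)
    hi = np.mean(vals >= obs - eps)
    return min(1.0, 2 * min(lo, hi))


class TestCounting:
    def test_hand_enumerated_counts(self):
        corpus = SequenceCorpus([["A", "B", "A"], ["B", "A"]], ("A", "B"))
        tm = count_transitions(corpus)
        assert tm.counts.tolist() == [[0, 1], [2, 0]]
        assert tm.prob("A", "B") == 1.0
        assert tm.prob("B", "A") == 1.0

    def test_length_one_sequences_have_no_transitions(self):
        tm = count_transitions(SequenceCorpus([["A"], ["B"], ["A"]], ("A", "B")))
        assert tm.counts.sum() == 0
        assert np.all(tm.probs == 0)

    def test_no_cross_sequence_pairs(self):
        # B at the end of seq 1 and A at the start of seq 2 must not pair
        tm = count_transitions(SequenceCorpus([["A", "B"], ["A", "B"]], ("A", "B")))
        assert tm.counts[1, 0] == 0  # B->A never within a sequence
        assert tm.counts[0, 1] == 2

    def test_token_outside_alphabet_rejected(self):
        with pytest.raises(LabelError):
            SequenceCorpus([["A", "Z"]], ("A", "B"))


class TestRandomization:
    @given(st.lists(
        st.lists(st.sampled_from("ABC"), min_size=1, max_size=5),
        min_size=1, max_size=8,
    ), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_token_and_length_multisets_preserved(self, seqs, seed):
        corpus = SequenceCorpus(seqs, ("A", "B", "C"))
        rnd = randomize_corpus(corpus, seed)
        assert Counter(t for s in rnd.sequences for t in s) == Counter(
            t for s in seqs for t in s
        )
        assert sorted(map(len, rnd.sequences)) == sorted(map(len, seqs))

    def test_identical_tokens_fixed_point(self):
        corpus = SequenceCorpus([["A", "A"], ["A"]], ("A",))
        assert randomize_corpus(corpus, 7).sequences == corpus.sequences


class TestPermutationTest:
    def test_matches_exhaustive_oracle_on_tiny_corpus(self):
        """{A,A,B,B} over two length-2 sequences: Monte-Carlo p-values must
        converge to the exhaustively enumerated null."""
        corpus = SequenceCorpus([["A", "B"], ["A", "B"]], ("A", "B"))
        null_mats = exhaustive_null(corpus)
        observed = count_transitions(corpus).probs
        res = permutation_test(corpus, n_iter=10_000, seed=5)
        tol = 2 / np.sqrt(10_000)
        for i in range(2):
            for j in range(2):
                exact = exact_two_tailed_p(null_mats, observed, i, j)
                assert res.p_two_tailed[i, j] == pytest.approx(exact, abs=tol)

    def test_observed_at_null_median_not_significant(self):
        # a featureless corpus: observed equals a typical null draw
        rng = np.random.default_rng(0)
        seqs = [[rng.choice(["A", "B"]) for _ in range(3)] for _ in range(40)]
        corpus = SequenceCorpus(seqs, ("A", "B"))
        res = permutation_test(corpus, n_iter=2000, seed=1)
        # at least the modal cell sits inside the central mass
        assert not res.significant.all()
        assert np.nanmax(res.p_two_tailed) > 0.2

    def test_p_floor(self):
        corpus = SequenceCorpus([["A", "B"]] * 30, ("A", "B"))
        res = permutation_test(corpus, n_iter=100, seed=0)
        assert np.nanmin(res.p_two_tailed) >= 1 / 101

    def test_invalid_n_iter(self):
        corpus = SequenceCorpus([["A", "B"]], ("A", "B"))
        with pytest.raises(ParameterError):
            permutation_test(corpus, n_iter=0)

    def test_absent_state_reported_na(self):
        corpus = SequenceCorpus([["A", "B"], ["B", "A"]], ("A", "B", "C"))
        res = permutation_test(corpus, n_iter=200, seed=0)
        assert np.isnan(res.p_two_tailed[2]).all()  # row C undefined
        assert not res.significant[2].any()

    def test_deterministic_given_seed(self):
        corpus = SequenceCorpus([["A", "B", "A"], ["B", "A"]], ("A", "B"))
        r1 = permutation_test(corpus, n_iter=500, seed=9)
        r2 = permutation_test(corpus, n_iter=500, seed=9)
        assert np.array_equal(r1.p_two_tailed, r2.p_two_tailed)
        assert np.array_equal(r1.null_samples, r2.null_samples)

    def test_row_stochasticity_of_observed_and_null(self):
        rng = np.random.default_rng(3)
        seqs = [list(rng.choice(["A", "B", "C"], size=rng.integers(1, 6)))
                for _ in range(25)]
        corpus = SequenceCorpus(seqs, ("A", "B", "C"))
        res = permutation_test(corpus, n_iter=300, seed=2)
        obs_sums = res.observed.probs.sum(axis=1)
        active = res.observed.counts.sum(axis=1) > 0
        assert np.allclose(obs_sums[active], 1.0, atol=1e-12)
        assert np.all(obs_sums[~active] == 0)
        null_sums = res.null_samples.sum(axis=1)  # (states, n_iter)
        assert np.all(
            np.isclose(null_sums, 1.0, atol=1e-12) | (null_sums == 0)
        )


class TestExport:
    def test_edge_table_includes_zeros(self, tmp_path):
        corpus = SequenceCorpus(
            [["DS", "SH"], ["SH", "DS"], ["DS", "LH"], ["NL", "DS"]],
            ("DS", "LH", "NL", "SH"),
        )
        res = permutation_test(corpus, n_iter=100, seed=0)
        path = export_transition_graph(res, tmp_path / "edges.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 16

    def test_graph_image_rendered(self, tmp_path):
        corpus = SequenceCorpus([["A", "B"], ["B", "A"]], ("A", "B"))
        res = permutation_test(corpus, n_iter=50, seed=0)
        export_transition_graph(res, tmp_path / "e.csv", tmp_path / "e.png")
        assert (tmp_path / "e.png").stat().st_size > 0

    def test_two_state_edges_match_matrix(self, tmp_path):
        corpus = SequenceCorpus([["A", "B"], ["B", "A"]], ("A", "B"))
        res = permutation_test(corpus, n_iter=50, seed=0)
        path = export_transition_graph(res, tmp_path / "e.csv")
        rows = [ln.split(",") for ln in path.read_text().strip().splitlines()[1:]]
        for a, b, count, prob, _, _ in rows:
            assert float(prob) == pytest.approx(res.observed.prob(a, b), abs=1e-6)
            i, j = res.alphabet.index(a), res.alphabet.index(b)
            assert int(count) == res.observed.counts[i, j]

    def test_empty_alphabet_rejected(self, tmp_path):
        res = TransitionTestResult(
            observed=TransitionMatrix.from_counts(np.zeros((0, 0)), ()),
            null_samples=np.zeros((0, 0, 1)),
            p_two_tailed=np.zeros((0, 0)),
            significant=np.zeros((0, 0), dtype=bool),
            n_iter=1, seed=0, alphabet=(),
        )
        with pytest.raises(VocalcombError):
            export_transition_graph(res, tmp_path / "x.csv")
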