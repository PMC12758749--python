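"""Collapsed-Gibbs LDA: corpus building, the count-based conditional against
an exhaustive-enumeration oracle, fitting, and the derived topic tables."""
import numpy as np
import pytest

from heatlens import lda
from heatlens.lda import (
    LdaModel,
    build_corpus,
    decrement,
    dominant_topic,
    fit_lda,
    gibbs_conditional,
    increment,
    log_joint,
    match_topics,
    reference_topic_matrix,
    regional_topic_distribution,
    top_words,
    topic_shares,
    topic_word_distributions,
)
from heatlens.synthetic import simulate_corpus_docs
from oracles import enumerate_conditional


def _disjoint_phi(v_per_topic=10):
    phi = np.zeros((2, 2 * v_per_topic))
    phi[0, :v_per_topic] = 1.0 / v_per_topic
    phi[1, v_per_topic:] = 1.0 / v_per_topic
    return phi


class TestBuildCorpus:
    def test_vocab_size(self):
        c = build_corpus([["a", "b"], ["b", "c"]])
        assert len(c.vocabulary) == 3

    def test_min_count_filters_vocab_and_docs(self):
        c = build_corpus([["a", "b"], ["b", "c"]], min_count=2)
        assert set(c.vocabulary) == {"b"}
        assert c.docs == [[0], [0]]

    def test_first_appearance_id_order(self):
        c = build_corpus([["q", "a"], ["z", "a", "m"]])
        assert c.vocabulary == {"q": 0, "a": 1, "z": 2, "m": 3}

    def test_empty_docs_dropped_and_counted(self):
        c = build_corpus([["a", "a"], ["b"], ["a"]], min_count=2)
        assert c.n_dropped_empty == 1
        assert len(c.docs) == 2

    def test_all_empty_is_error(self):
        with pytest.raises(ValueError, match="no documents"):
            build_corpus([["a"], ["b"]], min_count=5)


class TestGibbsConditional:
    def test_single_topic_is_certain(self):
        m = LdaModel.from_assignments([[0, 1]], [[0, 0]], K=1, V=2)
        decrement(m, 0, 0)
        assert gibbs_conditional(m, 0, 0) == pytest.approx([1.0])

    def test_symmetric_counts_give_uniform(self):
        m = LdaModel.from_assignments([[0]], [[0]], K=3, V=2)
        decrement(m, 0, 0)  # all counts now zero
        np.testing.assert_allclose(gibbs_conditional(m, 0, 0), np.full(3, 1 / 3))

    def test_sums_to_one(self):
        m = LdaModel.from_assignments(
            [[0, 1, 0], [2, 1]], [[0, 1, 0], [1, 0]], K=2, V=3
        )
        decrement(m, 1, 1)
        assert gibbs_conditional(m, 1, 1).sum() == pytest.approx(1.0, abs=1e-12)

    def test_position_out_of_range(self):
        m = LdaModel.from_assignments([[0]], [[0]], K=2, V=1)
        with pytest.raises(IndexError):
            gibbs_conditional(m, 0, 5)

    def test_matches_exhaustive_enumeration(self, small_gibbs_corpora):
        """On every ≤12-token corpus the count-ratio conditional equals the
        conditional from enumerating all complete assignments."""
        rng = np.random.default_rng(99)
        for docs, v in small_gibbs_corpora:
            z = [[int(k) for k in rng.integers(0, 2, len(d))] for d in docs]
            m = LdaModel.from_assignments(docs, z, K=2, V=v)
            for d in range(len(docs)):
                for pos in range(len(docs[d])):
                    expected = enumerate_conditional(
                        docs, z, d, pos, K=2, V=v, alpha=0.1, beta=0.01
                    )
                    old = decrement(m, d, pos)
                    got = gibbs_conditional(m, d, pos)
                    increment(m, d, pos, old)
                    np.testing.assert_allclose(got, expected, atol=1e-10)


class TestFitLda:
    def test_k1_forces_all_assignments(self):
        c = build_corpus([["a", "b"], ["b"]])
        m = fit_lda(c, K=1, iters=3, seed=0)
        assert all(k == 0 for zd in m.z for k in zd)

    def test_seeded_determinism(self):
        c = build_corpus([["a", "b", "c"], ["c", "d"], ["a", "d", "d"]])
        m1 = fit_lda(c, K=2, iters=50, seed=4)
        m2 = fit_lda(c, K=2, iters=50, seed=4)
        assert m1.z == m2.z

    def test_count_invariants_after_fit(self):
        c = build_corpus([["a", "b", "c"], ["c", "d"], ["a", "d", "d"]])
        m = fit_lda(c, K=3, iters=20, seed=1)
        m.check_counts()

    def test_k_exceeding_tokens_is_error(self):
        c = build_corpus([["a", "b"]])
        with pytest.raises(ValueError, match="exceeds"):
            fit_lda(c, K=5, iters=1, seed=0)

    def test_bad_iters_and_restarts(self):
        c = build_corpus([["a", "b"]])
        with pytest.raises(ValueError):
            fit_lda(c, K=1, iters=0, seed=0)
        with pytest.raises(ValueError):
            fit_lda(c, K=1, iters=1, seed=0, restarts=0)

    def test_disjoint_vocabulary_recovery(self):
        """Two topics over disjoint word blocks are recovered within TV 0.1
        up to label permutation."""
        phi = _disjoint_phi()
        docs, _ = simulate_corpus_docs(phi, n_docs=150, doc_length_mean=15.0, seed=8)
        tokens = [[f"w{w:02d}" for w in d] for d in docs]
        c = build_corpus(tokens)
        m = fit_lda(c, K=2, iters=80, seed=3)
        ref = reference_topic_matrix(phi, [f"w{w:02d}" for w in range(20)], c)
        _, tv = match_topics(topic_word_distributions(m), ref)
        assert (tv < 0.1).all()

    def test_log_joint_finite_and_improves(self):
        """The collapsed log joint is finite at every sweep, and over 20
        seeded runs the final value beats initialization in ≥ 95%."""
        phi = _disjoint_phi()
        docs, _ = simulate_corpus_docs(phi, n_docs=120, doc_length_mean=12.0, seed=21)
        tokens = [[f"w{w:02d}" for w in d] for d in docs]
        c = build_corpus(tokens)
        improved = 0
        for seed in range(20):
            m = fit_lda(c, K=2, iters=25, seed=seed, track_log_joint=True)
            hist = np.array(m.log_joint_history)
            assert np.isfinite(hist).all()
            improved += hist[-1] >= hist[0]
        assert improved >= 19


class TestTopicTables:
    def _model_with_dominants(self, dominants, K=3, regions=None):
        docs = [[0, 1] for _ in dominants]
        z = [[k, k] for k in dominants]
        m = LdaModel.from_assignments(docs, z, K=K, V=2)
        c = lda.Corpus(
            vocabulary={"a": 0, "b": 1},
            docs=docs,
            doc_region=list(regions) if regions else ["R"] * len(docs),
        )
        return m, c

    def test_dominant_topic_simple_and_tie(self):
        m, _ = self._model_with_dominants([2])
        assert dominant_topic(m, 0) == 2
        tie = LdaModel.from_assignments([[0, 1]], [[1, 3]], K=4, V=2)
        assert dominant_topic(tie, 0) == 1  # tie between 1 and 3 → lowest

    def test_dominant_topic_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(1, 8))
            doc = [int(w) for w in rng.integers(0, 3, n)]
            z = [int(k) for k in rng.integers(0, 4, n)]
            m = LdaModel.from_assignments([doc], [z], K=4, V=3)
            counts = [z.count(k) for k in range(4)]
            best = max(range(4), key=lambda k: (counts[k], -k))
            assert dominant_topic(m, 0) == best

    def test_topic_shares_direct_count(self):
        m, _ = self._model_with_dominants([0, 0, 1, 2], K=4)
        shares = topic_shares(m)
        assert list(shares["percent"]) == [50.0, 25.0, 25.0, 0.0]
        assert shares["percent"].sum() == pytest.approx(100.0)

    def test_topic_shares_single_topic(self):
        m, _ = self._model_with_dominants([1, 1, 1], K=2)
        assert list(topic_shares(m)["percent"]) == [0.0, 100.0]

    def test_regional_distribution_single_region(self):
        m, c = self._model_with_dominants([0, 1, 2], K=3)
        table = regional_topic_distribution(m, c)
        assert (table["percent_within_topic"] == 100.0).all()

    def test_regional_distribution_hand_tally(self):
        m, c = self._model_with_dominants(
            [0, 0, 1, 0], K=2, regions=["RA", "RB", "RA", "RA"]
        )
        table = regional_topic_distribution(m, c)
        t0 = table[table.topic == 0].set_index("region")
        assert t0.loc["RA", "n_docs"] == 2 and t0.loc["RB", "n_docs"] == 1
        assert t0.loc["RA", "percent_within_topic"] == pytest.approx(200 / 3)

    def test_regional_distribution_order_invariant(self):
        doms = [0, 1, 0, 1, 1]
        regs = ["RA", "RB", "RB", "RA", "RA"]
        m1, c1 = self._model_with_dominants(doms, K=2, regions=regs)
        m2, c2 = self._model_with_dominants(doms[::-1], K=2, regions=regs[::-1])
        t1 = regional_topic_distribution(m1, c1)
        t2 = regional_topic_distribution(m2, c2)
        assert t1.equals(t2)

    def test_regional_distribution_unknown_region(self):
        m, c = self._model_with_dominants([0], regions=["RX"])
        with pytest.raises(ValueError, match="RX"):
            regional_topic_distribution(m, c, regions=["RA"])

    def test_top_words_all_zero_counts_lexicographic(self):
        docs = [[0]]
        m = LdaModel.from_assignments(docs, [[0]], K=2, V=3)
        c = lda.Corpus(vocabulary={"c": 0, "a": 1, "b": 2}, docs=docs, doc_region=["R"])
        assert top_words(m, 1, 3, c) == ["a", "b", "c"]  # topic 1 never used

    def test_top_words_dominant_first_and_brute_force(self):
        rng = np.random.default_rng(5)
        doc = [int(w) for w in rng.integers(0, 6, 40)]
        z = [0] * 40
        m = LdaModel.from_assignments([doc], [z], K=1, V=6)
        c = lda.Corpus(
            vocabulary={f"w{i}": i for i in range(6)}, docs=[doc], doc_region=["R"]
        )
        weights = [(-(doc.count(w) + m.beta), f"w{w}") for w in range(6)]
        expected = [t for _, t in sorted(weights)]
        assert top_words(m, 0, 6, c) == expected
        assert top_words(m, 0, 1, c)[0] == f"w{np.bincount(doc).argmax()}"

    def test_top_words_unknown_topic(self):
        m, c = self._model_with_dominants([0])
        with pytest.raises(ValueError, match="topic"):
            top_words(m, 7, 1, c)
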