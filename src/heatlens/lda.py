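"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model: each document d draws a topic mixture θ_d ~ Dirichlet(α), each
topic k a word distribution φ_k ~ Dirichlet(β); every token gets a topic
z ~ θ_d and a word w ~ φ_z. Collapsed Gibbs sampling integrates θ and φ out
analytically and resamples each token's topic from the count-based
conditional

    p(z = k | z₋, w) ∝ (n_dk + α) · (n_kw + β) / (n_k + V·β)

where the counts exclude the token being resampled. Defaults α = 0.1 and
β = 0.01 favour sparse, interpretable topics — appropriate for short,
noisy social-media text.

Point estimates of θ and φ are taken from the final sweep's counts with
additive smoothing; no sample averaging is done, which keeps every output a
deterministic function of (corpus, K, α, β, iters, seed). Topic labels are
arbitrary: cross-run comparisons use Hungarian matching on total-variation
distance between topic-word distributions (:func:`match_topics`).
"""
from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .records import PostRecord

log = logging.getLogger(__name__)


@dataclass
class Corpus:
    """Integer-coded documents with their region labels."""

    vocabulary: dict[str, int]
    docs: list[list[int]]
    doc_region: list[str]
    n_dropped_empty: int = 0

    @property
    def id_to_token(self) -> list[str]:
        out = [""] * len(self.vocabulary)
        for tok, i in self.vocabulary.items():
            out[i] = tok
        return out

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.docs)


def build_corpus(
    posts: Sequence[PostRecord] | Sequence[Sequence[str]],
    min_count: int = 1,
    regions: Sequence[str] | None = None,
) -> Corpus:
    """Index a tokenized corpus.

    Vocabulary covers tokens with corpus count ≥ ``min_count``; token ids are
    assigned in first-appearance order. Documents left empty (all tokens
    below the threshold) are dropped with a logged count.
    """
    token_docs: list[list[str]] = []
    doc_region: list[str] = []
    for i, p in enumerate(posts):
        if isinstance(p, PostRecord):
            token_docs.append(list(p.tokens))
            doc_region.append(p.region)
        else:
            token_docs.append(list(p))
            doc_region.append(regions[i] if regions is not None else "")

    counts: Counter[str] = Counter()
    for doc in token_docs:
        counts.update(doc)
    vocabulary: dict[str, int] = {}
    for doc in token_docs:
        for tok in doc:
            if counts[tok] >= min_count and tok not in vocabulary:
                vocabulary[tok] = len(vocabulary)

    docs: list[list[int]] = []
    kept_region: list[str] = []
    dropped = 0
    for doc, region in zip(token_docs, doc_region):
        ids = [vocabulary[t] for t in doc if t in vocabulary]
        if ids:
            docs.append(ids)
            kept_region.append(region)
        else:
            dropped += 1
    if dropped:
        log.info("build_corpus: dropped %d empty document(s)", dropped)
    if not docs:
        raise ValueError("no documents survive preprocessing (all empty)")
    return Corpus(
        vocabulary=vocabulary,
        docs=docs,
        doc_region=kept_region,
        n_dropped_empty=dropped,
    )


@dataclass
class LdaModel:
    """A fitted collapsed-Gibbs LDA state: assignments plus the three count
    tables they induce (document×topic, topic×word, topic totals)."""

    K: int
    alpha: float
    beta: float
    V: int
    docs: list[list[int]]
    z: list[list[int]]
    n_dk: np.ndarray
    n_kw: np.ndarray
    n_k: np.ndarray
    iters: int
    seed: int
    log_joint_history: list[float] = field(default_factory=list)

    @classmethod
    def from_assignments(
        cls,
        docs: list[list[int]],
        z: list[list[int]],
        K: int,
        V: int,
        alpha: float = 0.1,
        beta: float = 0.01,
        seed: int = 0,
    ) -> "LdaModel":
        n_dk = np.zeros((len(docs), K), dtype=np.int64)
        n_kw = np.zeros((K, V), dtype=np.int64)
        n_k = np.zeros(K, dtype=np.int64)
        for d, (doc, zd) in enumerate(zip(docs, z)):
            for w, k in zip(doc, zd):
                n_dk[d, k] += 1
                n_kw[k, w] += 1
                n_k[k] += 1
        return cls(
            K=K, alpha=alpha, beta=beta, V=V, docs=docs,
            z=[list(zd) for zd in z],
            n_dk=n_dk, n_kw=n_kw, n_k=n_k, iters=0, seed=seed,
        )

    def check_counts(self) -> None:
        """Assert the count-conservation invariants."""
        assert all(
            self.n_dk[d].sum() == len(doc) for d, doc in enumerate(self.docs)
        ), "document-topic counts do not sum to document lengths"
        assert (self.n_kw.sum(axis=1) == self.n_k).all(), "topic-word totals drift"
        assert self.n_k.sum() == sum(len(d) for d in self.docs), "token total drift"


def gibbs_conditional(model: LdaModel, doc: int, position: int) -> np.ndarray:
    """The collapsed conditional over topics for one token.

    Precondition: the model's counts already exclude the token at
    ``(doc, position)`` (as during a sweep, after decrementing). Returns a
    length-K probability vector summing to 1.
    """
    if not (0 <= doc < len(model.docs)):
        raise IndexError(f"document index {doc} out of range")
    if not (0 <= position < len(model.docs[doc])):
        raise IndexError(f"position {position} out of range for document {doc}")
    w = model.docs[doc][position]
    p = (
        (model.n_dk[doc] + model.alpha)
        * (model.n_kw[:, w] + model.beta)
        / (model.n_k + model.V * model.beta)
    )
    return p / p.sum()


def decrement(model: LdaModel, doc: int, position: int) -> int:
    """Remove one token's assignment from the counts; returns its old topic."""
    k = model.z[doc][position]
    w = model.docs[doc][position]
    model.n_dk[doc, k] -= 1
    model.n_kw[k, w] -= 1
    model.n_k[k] -= 1
    return k


def increment(model: LdaModel, doc: int, position: int, k: int) -> None:
    """Assign topic ``k`` to a token and restore it into the counts."""
    w = model.docs[doc][position]
    model.z[doc][position] = k
    model.n_dk[doc, k] += 1
    model.n_kw[k, w] += 1
    model.n_k[k] += 1


def log_joint(model: LdaModel) -> float:
    """Collapsed log p(w, z | α, β): Dirichlet-multinomial in both blocks."""
    K, V, a, b = model.K, model.V, model.alpha, model.beta
    doc_lens = np.array([len(d) for d in model.docs], dtype=float)
    lp = float(
        len(model.docs) * (gammaln(K * a) - K * gammaln(a))
        + gammaln(model.n_dk + a).sum()
        - gammaln(doc_lens + K * a).sum()
        + K * (gammaln(V * b) - V * gammaln(b))
        + gammaln(model.n_kw + b).sum()
        - gammaln(model.n_k + V * b).sum()
    )
    return lp


def fit_lda(
    corpus: Corpus,
    K: int = 4,
    alpha: float = 0.1,
    beta: float = 0.01,
    iters: int = 1000,
    seed: int = 0,
    track_log_joint: bool = False,
    restarts: int = 1,
) -> LdaModel:
    """Fit LDA by full sweeps of collapsed Gibbs sampling.

    Topic assignments are initialised uniformly at random from ``seed``;
    ``iters`` full sweeps follow. The returned model carries the final-sweep
    assignments and counts (the point-estimate state). With
    ``track_log_joint`` the collapsed log joint is recorded at initialisation
    and after every sweep.

    With ``restarts > 1`` the chain is run from that many deterministically
    derived seeds and the state with the highest collapsed log joint is
    returned: the collapsed posterior is multimodal (a heavy topic can split
    into two near-copies while two light ones merge), and the log joint
    separates such trapped modes from the dominant one sharply.
    """
    if restarts < 1:
        raise ValueError(f"restarts must be >= 1, got {restarts}")
    if restarts == 1:
        return _fit_lda_single(corpus, K, alpha, beta, iters, seed, track_log_joint)
    best: LdaModel | None = None
    best_lj = -np.inf
    for r in range(restarts):
        child = int(
            np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0]
            % (2**31)
        )
        model = _fit_lda_single(corpus, K, alpha, beta, iters, child, track_log_joint)
        lj = log_joint(model)
        if lj > best_lj:
            best, best_lj = model, lj
    assert best is not None
    return best


def _fit_lda_single(
    corpus: Corpus,
    K: int,
    alpha: float,
    beta: float,
    iters: int,
    seed: int,
    track_log_joint: bool = False,
) -> LdaModel:
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if iters < 1:
        raise ValueError(f"iters must be >= 1, got {iters}")
    total_tokens = corpus.n_tokens
    if K > total_tokens:
        raise ValueError(f"K={K} exceeds the corpus token count {total_tokens}")
    V = len(corpus.vocabulary)
    rng = np.random.default_rng(seed)

    docs = corpus.docs
    z_init = rng.integers(0, K, size=total_tokens)
    z: list[list[int]] = []
    pos = 0
    for doc in docs:
        z.append([int(k) for k in z_init[pos : pos + len(doc)]])
        pos += len(doc)

    model = LdaModel.from_assignments(docs, z, K, V, alpha, beta, seed)
    model.iters = iters
    if track_log_joint:
        model.log_joint_history.append(log_joint(model))

    # Hot loop in plain Python over list-based counts: for the small K used
    # here this outruns per-token numpy dispatch by a wide margin.
    n_dk = [[int(c) for c in row] for row in model.n_dk]
    n_kw = [[int(c) for c in row] for row in model.n_kw.T]  # indexed [w][k]
    n_k = [int(c) for c in model.n_k]
    zl = model.z
    Vb = V * beta
    K_range = range(K)
    probs = [0.0] * K

    for _ in range(iters):
        us = rng.random(total_tokens)
        ui = 0
        for d, doc in enumerate(docs):
            ndk_d = n_dk[d]
            zd = zl[d]
            for i, w in enumerate(doc):
                k = zd[i]
                ndk_d[k] -= 1
                nkw_w = n_kw[w]
                nkw_w[k] -= 1
                n_k[k] -= 1
                tot = 0.0
                for kk in K_range:
                    tot += (ndk_d[kk] + alpha) * (nkw_w[kk] + beta) / (n_k[kk] + Vb)
                    probs[kk] = tot
                u = us[ui] * tot
                ui += 1
                k = 0
                while probs[k] < u:
                    k += 1
                zd[i] = k
                ndk_d[k] += 1
                nkw_w[k] += 1
                n_k[k] += 1
        if track_log_joint:
            model.n_dk = np.array(n_dk, dtype=np.int64)
            model.n_kw = np.array(n_kw, dtype=np.int64).T
            model.n_k = np.array(n_k, dtype=np.int64)
            model.log_joint_history.append(log_joint(model))

    model.n_dk = np.array(n_dk, dtype=np.int64)
    model.n_kw = np.array(n_kw, dtype=np.int64).T
    model.n_k = np.array(n_k, dtype=np.int64)
    model.check_counts()
    return model


def topic_word_distributions(model: LdaModel) -> np.ndarray:
    """Smoothed point estimate of φ: (n_kw + β) / (n_k + V·β), shape (K, V)."""
    return (model.n_kw + model.beta) / (model.n_k + model.V * model.beta)[:, None]


def doc_topic_distributions(model: LdaModel) -> np.ndarray:
    """Smoothed point estimate of θ per document, shape (D, K)."""
    lens = np.array([len(d) for d in model.docs], dtype=float)
    return (model.n_dk + model.alpha) / (lens + model.K * model.alpha)[:, None]


def dominant_topic(model: LdaModel, doc: int) -> int:
    """Topic with the largest smoothed document-topic mass; ties go to the
    lowest topic id."""
    return int(np.argmax(model.n_dk[doc] + model.alpha))


def topic_shares(model: LdaModel) -> pd.DataFrame:
    """Percentage of documents per dominant topic (columns: topic, n_docs,
    percent); percentages sum to 100 within rounding."""
    dom = [dominant_topic(model, d) for d in range(len(model.docs))]
    counts = Counter(dom)
    n = len(model.docs)
    rows = [
        (k, counts.get(k, 0), 100.0 * counts.get(k, 0) / n) for k in range(model.K)
    ]
    return pd.DataFrame(rows, columns=["topic", "n_docs", "percent"])


def regional_topic_distribution(
    model: LdaModel,
    corpus: Corpus,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per topic, each region's share of that topic's documents.

    Columns: topic, region, n_docs, percent_within_topic (summing to 100 per
    topic with any documents). With ``regions`` given, document region codes
    outside it are an error listing the offenders.
    """
    if regions is not None:
        known = set(regions)
        offenders = sorted({r for r in corpus.doc_region if r not in known})
        if offenders:
            raise ValueError(f"unknown region code(s): {offenders}")
    dom = [dominant_topic(model, d) for d in range(len(model.docs))]
    pair_counts: Counter[tuple[int, str]] = Counter(zip(dom, corpus.doc_region))
    region_list = sorted(set(regions) if regions is not None else set(corpus.doc_region))
    rows = []
    for k in range(model.K):
        topic_total = sum(pair_counts.get((k, r), 0) for r in region_list)
        for r in region_list:
            c = pair_counts.get((k, r), 0)
            pct = 100.0 * c / topic_total if topic_total else 0.0
            rows.append((k, r, c, pct))
    return pd.DataFrame(
        rows, columns=["topic", "region", "n_docs", "percent_within_topic"]
    )


def top_words(model: LdaModel, topic: int, n: int, corpus: Corpus) -> list[str]:
    """The ``n`` highest-mass words of a topic (smoothed counts, ties
    lexicographic by token string)."""
    if not (0 <= topic < model.K):
        raise ValueError(f"unknown topic {topic} (K={model.K})")
    tokens = corpus.id_to_token
    weights = model.n_kw[topic] + model.beta
    order = sorted(range(model.V), key=lambda w: (-weights[w], tokens[w]))
    return [tokens[w] for w in order[:n]]


def reference_topic_matrix(
    phi: np.ndarray, vocab: Sequence[str], corpus: Corpus
) -> np.ndarray:
    """Re-order a generator's topic-word matrix (columns in ``vocab`` order)
    into the corpus's token-id order so it can be compared with a fitted
    model's distributions. Vocabulary entries absent from the corpus get
    zero columns."""
    phi = np.asarray(phi, dtype=float)
    ref = np.zeros((phi.shape[0], len(corpus.vocabulary)))
    for j, tok in enumerate(vocab):
        if tok in corpus.vocabulary:
            ref[:, corpus.vocabulary[tok]] = phi[:, j]
    return ref


def match_topics(phi_est: np.ndarray, phi_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of estimated topics to reference topics on
    total-variation distance.

    Returns ``(perm, tv)`` where ``perm[j]`` is the estimated topic matched
    to reference topic j and ``tv[j]`` the TV distance of that pair.
    """
    K = phi_ref.shape[0]
    cost = np.zeros((K, K))
    for j in range(K):
        for i in range(K):
            cost[j, i] = 0.5 * np.abs(phi_ref[j] - phi_est[i]).sum()
    ref_idx, est_idx = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    tv = np.empty(K)
    for j, i in zip(ref_idx, est_idx):
        perm[j] = i
        tv[j] = cost[j, i]
    return perm, tv
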