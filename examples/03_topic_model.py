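"""Fit LDA by collapsed Gibbs sampling on a synthetic corpus with known
topics and recover the dominant-topic shares.

Documents are generated with a skewed dominant-topic profile; the fitted
model's shares should land within a fraction of a percentage point of it
(topic labels are arbitrary, hence the Hungarian matching step).
"""
import numpy as np

from heatlens import build_corpus, fit_lda, match_topics, topic_shares, topic_word_distributions
from heatlens.lda import reference_topic_matrix, top_words
from heatlens.synthetic import default_topics, simulate_corpus_docs

phi, vocab = default_topics()          # 4 topics over an abstract vocabulary
profile = [0.26, 0.526, 0.114, 0.10]   # dominant-topic mass per document

docs, _ = simulate_corpus_docs(phi, n_docs=2000, doc_length_mean=12.0,
                               seed=3, dominant_profile=profile)
corpus = build_corpus([[vocab[w] for w in d] for d in docs])
model = fit_lda(corpus, K=4, alpha=0.1, beta=0.01, iters=120, seed=5, restarts=5)

perm, tv = match_topics(topic_word_distributions(model),
                        reference_topic_matrix(phi, vocab, corpus))
pct = dict(zip(topic_shares(model)["topic"], topic_shares(model)["percent"]))
for j, target in enumerate(profile):
    k = int(perm[j])
    words = ", ".join(top_words(model, k, 3, corpus))
    print(f"generator topic {j}: share {pct[k]:5.1f}% (target {100*target:.1f}%), "
          f"TV {tv[j]:.3f}, top words: {words}")
# Shares are percentages of documents whose dominant fitted topic matches;
# TV is the total-variation distance between fitted and generative
# topic-word distributions.
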