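"""Clean, keyword-filter and tokenize raw post text.

Shows PII scrubbing (phone-like digit runs, coordinates), platform-noise
removal, heat-keyword filtering, stopword merging with zero-occurrence
pruning, and the word-frequency ranking.
"""
from heatlens import (
    clean_text,
    filter_heat_related,
    merge_stopwords,
    tokenize,
    word_frequencies,
)
from heatlens.records import PostRecord
import datetime as dt

raw = "so hot today 13812345678 @friend check https://spam.example #heatwave# 23.13,113.26"
print("raw:    ", raw)
print("cleaned:", clean_text(raw))
# The phone-like run, mention, URL, hashtag marks and coordinate pair are
# gone; ordinary words survive.

posts = [
    PostRecord("p1", dt.date(2023, 7, 1), "RA", clean_text(raw)),
    PostRecord("p2", dt.date(2023, 7, 1), "RA", "a mild cloudy day"),
]
kept = [p for p in posts if filter_heat_related(p)]
print(f"keyword filter kept {len(kept)}/{len(posts)} posts")

stop = merge_stopwords([["today", "check"], ["a", "ancient-term"]],
                       corpus="so hot today check a mild cloudy day".split())
tokenized = [tokenize(p, stopwords=stop) for p in kept]
print("tokens:", tokenized[0].tokens)
print("top words:", word_frequencies(tokenized, 3))
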