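import datetime as dt

import numpy as np
import pytest

from heatlens.records import PostRecord, RegionDayTemp


@pytest.fixture
def tiny_posts():
    """Six tokenized posts over two regions and three days."""
    d = dt.date
    mk = lambda i, date, region, toks: PostRecord(
        post_id=f"p{i}", date=date, region=region, raw_text=" ".join(toks),
        tokens=list(toks),
    )
    return [
        mk(0, d(2023, 7, 1), "RA", ["hot", "sun"]),
        mk(1, d(2023, 7, 1), "RA", ["hot", "hot", "shade"]),
        mk(2, d(2023, 7, 2), "RA", ["sun", "shade"]),
        mk(3, d(2023, 7, 1), "RB", ["hot", "rain"]),
        mk(4, d(2023, 7, 3), "RB", ["rain", "rain", "sun"]),
        mk(5, d(2023, 7, 3), "RB", ["shade"]),
    ]


@pytest.fixture
def small_gibbs_corpora():
    """A suite of integer-coded corpora with at most 12 tokens each, for
    exhaustive-enumeration checks at K=2."""
    rng = np.random.default_rng(20230701)
    suite = [
        # the 3-doc, 5-token corpus
        ([[0, 1], [1, 2], [0]], 3),
        ([[0, 0, 1], [2, 1]], 3),
        ([[0]], 1),
        ([[0, 1, 2, 3], [3, 2], [1, 1, 0]], 4),
    ]
    for _ in range(3):
        v = int(rng.integers(2, 5))
        n_docs = int(rng.integers(1, 4))
        docs = [
            [int(w) for w in rng.integers(0, v, size=rng.integers(1, 5))]
            for _ in range(n_docs)
        ]
        while sum(len(d) for d in docs) > 12:
            docs[-1] = docs[-1][:-1]
            docs = [d for d in docs if d]
        suite.append((docs, v))
    return suite


def make_temps(region: str, start: dt.date, values: list[float]) -> list[RegionDayTemp]:
    return [
        RegionDayTemp(region=region, date=start + dt.timedelta(days=i),
                      tmax_c=v, n_stations=1)
        for i, v in enumerate(values)
    ]
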