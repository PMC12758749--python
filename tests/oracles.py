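"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (explicit loops,
``math.lgamma``) and deliberately shares no code path with the package
implementation it checks.
"""
from __future__ import annotations

import itertools
import math


def collapsed_log_joint(
    docs: list[list[int]],
    z_flat: tuple[int, ...],
    K: int,
    V: int,
    alpha: float,
    beta: float,
) -> float:
    """log p(w, z | α, β) of the LDA model with θ and φ integrated out,
    computed directly from the Dirichlet-multinomial closed form."""
    # re-count everything from scratch for this assignment
    n_dk = [[0] * K for _ in docs]
    n_kw = [[0] * V for _ in range(K)]
    n_k = [0] * K
    pos = 0
    for d, doc in enumerate(docs):
        for w in doc:
            k = z_flat[pos]
            n_dk[d][k] += 1
            n_kw[k][w] += 1
            n_k[k] += 1
            pos += 1

    lp = 0.0
    for d, doc in enumerate(docs):
        lp += math.lgamma(K * alpha) - math.lgamma(len(doc) + K * alpha)
        for k in range(K):
            lp += math.lgamma(n_dk[d][k] + alpha) - math.lgamma(alpha)
    for k in range(K):
        lp += math.lgamma(V * beta) - math.lgamma(n_k[k] + V * beta)
        for w in range(V):
            lp += math.lgamma(n_kw[k][w] + beta) - math.lgamma(beta)
    return lp


def enumerate_conditional(
    docs: list[list[int]],
    z_ref: list[list[int]],
    d: int,
    pos: int,
    K: int,
    V: int,
    alpha: float,
    beta: float,
) -> list[float]:
    """Conditional p(z_{d,pos} = k | z₋, w) by exhaustive enumeration.

    Enumerates every one of the K^N complete topic assignments, keeps those
    agreeing with ``z_ref`` everywhere except (d, pos), and normalises their
    joint probabilities.
    """
    flat_ref = [k for zd in z_ref for k in zd]
    # flat index of the free position
    offset = sum(len(doc) for doc in docs[:d]) + pos
    n = len(flat_ref)

    weights = [0.0] * K
    logs: dict[int, float] = {}
    for assignment in itertools.product(range(K), repeat=n):
        if any(
            assignment[i] != flat_ref[i] for i in range(n) if i != offset
        ):
            continue
        logs[assignment[offset]] = collapsed_log_joint(
            docs, assignment, K, V, alpha, beta
        )
    m = max(logs.values())
    total = sum(math.exp(v - m) for v in logs.values())
    for k, v in logs.items():
        weights[k] = math.exp(v - m) / total
    return weights


def spearman_rho_brute(x: list[float], y: list[float]) -> float:
    """Spearman correlation via average ranks and the Pearson formula,
    written out longhand."""

    def avg_ranks(v: list[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(x)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def bisect_right_root(
    a0: float, a1: float, a2: float, m: float, lo: float, hi: float,
    tol: float = 1e-12, max_iter: int = 200,
) -> float:
    """Right intersection of the quadratic with level ``m`` by bisection on
    [lo, hi]; requires f(lo) ≤ 0 ≤ f(hi) for f(ω) = a0 + a1ω + a2ω² − m."""

    def f(w: float) -> float:
        return a0 + a1 * w + a2 * w * w - m

    flo, fhi = f(lo), f(hi)
    assert flo <= 0.0 <= fhi, "bracket does not straddle the root"
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
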