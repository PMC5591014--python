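"""Independent brute-force oracles used by the test suite.

Each oracle is a direct transcription of a definition (naive scan,
exhaustive enumeration, suffix minimum) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def naive_motif_positions(seq: str, motif: str) -> List[int]:
    """Position-by-position substring scan on both strands."""
    seq = seq.upper()
    rc = motif.translate(_COMP)[::-1]
    hits = set()
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i:i + len(motif)]
        if window == motif or window == rc:
            hits.add(i)
    return sorted(hits)


def naive_digest(seq: str, primary: str) -> List[Tuple[int, int]]:
    """Fragment spans from cut positions at each motif start (no leading empty)."""
    cuts = [p for p in naive_motif_positions(seq, primary) if p > 0]
    edges = [0] + cuts + [len(seq)]
    return list(zip(edges[:-1], edges[1:]))


def brute_force_isotonic_decreasing(y: Sequence[float]) -> np.ndarray:
    """Least-squares non-increasing fit by enumerating contiguous level sets.

    Every monotone step function constant on a contiguous partition is a
    candidate; the optimum over partitions whose block means are
    non-increasing equals the isotonic regression (PAVA characterization is
    NOT used here: feasibility and SSE are checked directly).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    best, best_sse = None, np.inf
    for mask in range(1 << (n - 1)):
        cuts = [i + 1 for i in range(n - 1) if mask >> i & 1]
        bounds = [0] + cuts + [n]
        fit = np.empty(n)
        means = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            m = y[a:b].mean()
            means.append(m)
            fit[a:b] = m
        if any(means[i] < means[i + 1] - 1e-12 for i in range(len(means) - 1)):
            continue
        sse = float(((y - fit) ** 2).sum())
        if sse < best_sse - 1e-15:
            best_sse, best = sse, fit
    return best


def suffix_min_bh(p: Sequence[float]) -> np.ndarray:
    """BH step-up by its definition: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q_sorted[rank - 1] = min(
            m * p[order[j - 1]] / j for j in range(rank, m + 1))
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enumerate_mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all rank assignments.

    Requires no ties.  Returns (U of x, p) with
    p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n, k = len(pooled), len(x)

    def u_of(idx_set):
        xs = [pooled[i] for i in idx_set]
        ys = [pooled[i] for i in range(n) if i not in idx_set]
        return sum(1 for a in xs for b in ys if a > b)

    obs = sum(1 for a in x for b in y if a > b)
    us = [u_of(set(c)) for c in combinations(range(n), k)]
    us = np.array(us)
    p_lo = (us <= obs).mean()
    p_hi = (us >= obs).mean()
    return float(obs), float(min(1.0, 2 * min(p_lo, p_hi)))


def enumerate_conditional_count_p(ka: int, kb: int, lib_a: float, lib_b: float) -> float:
    """Two-sided conditional test by enumerating every split of the total."""
    from math import comb

    n = ka + kb
    if n == 0:
        return 1.0
    pr = lib_a / (lib_a + lib_b)
    probs = np.array([comb(n, k) * pr ** k * (1 - pr) ** (n - k) for k in range(n + 1)])
    return float(probs[probs <= probs[ka] * (1 + 1e-9)].sum())


def naive_nearest_distance(tss: int, intervals: Sequence[Tuple[int, int]]) -> float:
    """Minimum over intervals of the distance to the nearest occupied base."""
    best = np.inf
    for s, e in intervals:
        if s <= tss < e:
            return 0.0
        best = min(best, min(abs(tss - s), abs(tss - (e - 1))))
    return float(best) if intervals else float("nan")


def naive_window_counts(ends_per_frag: Sequence[int], w: int) -> List[int]:
    """Brute-force sliding-window sums of captured ends."""
    e = list(ends_per_frag)
    return [sum(e[i:i + w]) for i in range(len(e) - w + 1)]
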