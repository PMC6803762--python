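"""Independent brute-force oracles used by the test suite.

These deliberately use the slowest, most literal definition of each
quantity — per-base sets for interval arithmetic, full enumeration for the
exact tests — and share no code with the implementation they check.
"""

import itertools
import math
from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def base_set(intervals: Iterable[Interval]) -> set:
    out = set()
    for s, e in intervals:
        out.update(range(s, e))
    return out


def coverage_length_oracle(region: Interval, peaks: Iterable[Interval]) -> int:
    """Per-base count of region positions covered by >= 1 peak."""
    rs, re = region
    covered = base_set(peaks)
    return sum(1 for pos in range(rs, re) if pos in covered)


def merge_oracle(intervals: Iterable[Interval]) -> List[Interval]:
    """Merged runs recovered from the per-base set."""
    covered = sorted(base_set(intervals))
    runs: List[Interval] = []
    for pos in covered:
        if runs and pos == runs[-1][1]:
            runs[-1] = (runs[-1][0], pos + 1)
        else:
            runs.append((pos, pos + 1))
    return runs


def jaccard_oracle(a: Iterable[Interval], b: Iterable[Interval]) -> float:
    sa, sb = base_set(a), base_set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def distance_oracle(pos: int, region: Interval) -> int:
    """min |pos - b| over covered bases b."""
    s, e = region
    return min(abs(pos - b) for b in range(s, e))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities of margin-matched tables whose
    probability does not exceed the observed table's."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x: int) -> float:
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def wilcoxon_exact_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration of group labelings.

    Requires no ties. p = 2 * min(P(U <= u), P(U >= u)), capped at 1 — the
    standard exact convention for the symmetric null distribution of U.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(ranks[pooled[i]] for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    n_total = len(us)
    le = sum(1 for u in us if u <= u_obs) / n_total
    ge = sum(1 for u in us if u >= u_obs) / n_total
    return min(1.0, 2.0 * min(le, ge))


def wilcoxon_permutation_oracle(
    x: Sequence[float], y: Sequence[float], n_resample: int, seed: int
) -> float:
    """Monte-Carlo permutation p for |mean rank difference| (handles ties)."""
    import numpy as np
    from scipy.stats import rankdata

    x = list(x)
    y = list(y)
    pooled = np.asarray(x + y, dtype=float)
    n1 = len(x)
    ranks = rankdata(pooled)
    stat_obs = abs(ranks[:n1].sum() - n1 * (len(pooled) + 1) / 2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resample):
        perm = rng.permutation(len(pooled))
        stat = abs(ranks[perm[:n1]].sum() - n1 * (len(pooled) + 1) / 2)
        if stat >= stat_obs - 1e-9:
            count += 1
    return count / n_resample


def kendall_tau_b_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Tau-b by literal pairwise counting with tie terms."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif (dx > 0) == (dy > 0):
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    n1 = sum(
        c * (c - 1) / 2
        for c in [list(x).count(v) for v in set(x)]
    )
    n2 = sum(
        c * (c - 1) / 2
        for c in [list(y).count(v) for v in set(y)]
    )
    return (concordant - discordant) / math.sqrt((n0 - n1) * (n0 - n2))


def bh_oracle(p_values: Sequence[float]) -> List[float]:
    """Step-up q-values straight from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        q[i] = running_min
    return q
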