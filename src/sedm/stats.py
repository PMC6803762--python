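"""The four statistical primitives used by the pipeline.

* Fisher's exact test on 2x2 tables (tile-level differential methylation).
* Wilcoxon rank-sum / Mann-Whitney (per-SE differential methylation on the
  net-intersection-length metric).
* Kendall's tau-b with tie-adjusted normal p-value (methylation-expression
  correlation; tau-b because intersection-length data are tie-heavy, with
  many exact zeros).
* Benjamini-Hochberg step-up FDR.

Fisher and Wilcoxon are thin wrappers over scipy with explicit handling of
the degenerate cases a peak-based pipeline actually produces (empty margins,
all-identical values). The Kendall p-value is computed here: tau-b's null
variance with tie adjustments plus a continuity correction, which scipy's
asymptotic mode does not apply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Wilcoxon switches from exact enumeration to the normal approximation
#: above this combined sample size (or whenever ties are present).
WILCOXON_EXACT_MAX_N = 12


@dataclass
class TestResult:
    statistic: Optional[float]
    p_value: float
    method: str
    n_effective: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Two-sided p sums the probabilities of all tables with the same margins
    whose hypergeometric probability does not exceed the observed table's.
    A zero margin carries no information and yields p = 1.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    if a + b + c + d == 0:
        raise ValueError("empty 2x2 table")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return TestResult(None, 1.0, "fisher_exact", a + b + c + d)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(odds), min(float(p), 1.0), "fisher_exact", a + b + c + d)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact by enumeration when there are no ties and n1+n2 <= 12; otherwise
    the normal approximation with tie correction and continuity correction.
    All values identical across both groups gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(None, 1.0, "wilcoxon_degenerate", x.size + y.size)
    n = x.size + y.size
    has_ties = np.unique(pooled).size < n
    if not has_ties and n <= WILCOXON_EXACT_MAX_N:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "wilcoxon_exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "wilcoxon_normal"
    return TestResult(float(res.statistic), min(float(res.pvalue), 1.0), method, n)


def _kendall_counts(x: np.ndarray, y: np.ndarray):
    """Concordant/discordant S plus tie-group sizes, by direct pairwise count."""
    n = x.size
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = int(np.sum(dx[iu] * dy[iu]))
    _, tx = np.unique(x, return_counts=True)
    _, ty = np.unique(y, return_counts=True)
    return s, tx[tx > 1], ty[ty > 1]


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall's tau-b with a tie-adjusted normal-approximation p-value.

    Pairs with a missing value in either vector are dropped; >= 3 complete
    pairs are required. A zero-variance vector gives a missing statistic and
    p = 1. The p-value uses the null variance of S with the standard tie
    adjustment terms and a continuity correction of 1 on |S|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(None, 1.0, "kendall_degenerate", n)

    s, tx, ty = _kendall_counts(x, y)
    n0 = n * (n - 1) // 2
    n1 = int(np.sum(tx * (tx - 1) // 2))
    n2 = int(np.sum(ty * (ty - 1) // 2))
    tau_b = s / math.sqrt((n0 - n1) * (n0 - n2))

    # null variance of S with tie adjustments
    v0 = n * (n - 1) * (2 * n + 5)
    vt = int(np.sum(tx * (tx - 1) * (2 * tx + 5)))
    vu = int(np.sum(ty * (ty - 1) * (2 * ty + 5)))
    var_s = (v0 - vt - vu) / 18.0
    var_s += (
        np.sum(tx * (tx - 1) * (tx - 2)) * np.sum(ty * (ty - 1) * (ty - 2))
    ) / (9.0 * n * (n - 1) * (n - 2))
    var_s += (np.sum(tx * (tx - 1)) * np.sum(ty * (ty - 1))) / (2.0 * n * (n - 1))

    if var_s <= 0:
        return TestResult(float(tau_b), 1.0, "kendall_tau_b", n)
    z = (abs(s) - 1) / math.sqrt(var_s) if abs(s) > 0 else 0.0
    z = max(z, 0.0)
    p = min(2.0 * sps.norm.sf(z), 1.0)
    return TestResult(float(tau_b), float(p), "kendall_tau_b", n)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Missing p-values (NaN) propagate to missing q-values and do not count
    toward the number of tests. Values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum() > 0:
        _, q_ok, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = q_ok
    return q
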