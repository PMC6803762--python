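"""Genomic interval algebra on 0-based half-open coordinates.

Every quantity downstream of peak calling reduces to arithmetic on sets of
genomic intervals: the net number of base pairs of a super-enhancer covered
by a sample's methylation peaks, genome tiling into fixed-width windows,
Jaccard similarity of two region catalogs, TSS-to-region distances for
in-cis target assignment, and a midpoint-projection overlap statistic for
"are these regions enriched inside that catalog" questions.

Coordinates follow the BED convention throughout: ``start`` is 0-based
inclusive, ``end`` exclusive, so ``end - start`` is the length in bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from scipy import stats as _scipy_stats

STRAND_TOKENS = {"+", "-", "."}

#: Sentinel returned by :func:`distance_to_interval` for cross-chromosome pairs.
INF_DISTANCE = math.inf


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    Raises ``ValueError`` unless ``0 <= start < end``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                f"(id={self.id!r}): need 0 <= start < end"
            )
        if self.strand not in STRAND_TOKENS:
            raise ValueError(
                f"unknown strand {self.strand!r} for {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered, per-chromosome collection of :class:`GenomicInterval`.

    The set retains its member intervals as given (duplicates and overlaps
    included) until :meth:`normalize` is called, which returns a new set whose
    members are sorted, non-overlapping and non-touching per chromosome.
    Coverage-style queries (:func:`net_intersection_length`, :func:`jaccard`)
    operate on the normalized form.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._intervals: List[GenomicInterval] = list(intervals)
        self._merged: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self._intervals)} intervals)"

    @property
    def intervals(self) -> List[GenomicInterval]:
        return list(self._intervals)

    def chromosomes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def total_length(self) -> int:
        """Sum of member lengths (counts overlap twice unless normalized)."""
        return sum(iv.length() for iv in self._intervals)

    def coverage(self) -> int:
        """Number of distinct bp covered by at least one member."""
        return sum(
            int(np.sum(ends - starts)) for starts, ends in self._merged_arrays().values()
        )

    # -- normalized-form machinery ------------------------------------------------

    def _merged_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of the merged (union) form, cached."""
        if self._merged is None:
            by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for iv in self._intervals:
                by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
            merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                out_s: List[int] = []
                out_e: List[int] = []
                for s, e in pairs:
                    # touching intervals ([a,b) + [b,c)) merge as well
                    if out_e and s <= out_e[-1]:
                        if e > out_e[-1]:
                            out_e[-1] = e
                    else:
                        out_s.append(s)
                        out_e.append(e)
                merged[chrom] = (
                    np.asarray(out_s, dtype=np.int64),
                    np.asarray(out_e, dtype=np.int64),
                )
            self._merged = merged
        return self._merged

    def normalize(self) -> "IntervalSet":
        """Return a new set in normalized form (sorted, disjoint, non-touching)."""
        out: List[GenomicInterval] = []
        for chrom in sorted(self._merged_arrays()):
            starts, ends = self._merged_arrays()[chrom]
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        result = IntervalSet(out)
        result._merged = self._merged
        return result

    def is_normalized(self) -> bool:
        prev: Optional[GenomicInterval] = None
        seen_chroms: Dict[str, None] = {}
        for iv in self._intervals:
            if prev is not None and iv.chrom == prev.chrom:
                if iv.start <= prev.end:  # overlap or touch
                    return False
            elif iv.chrom in seen_chroms:
                return False  # chromosome blocks must be contiguous
            seen_chroms[iv.chrom] = None
            prev = iv
        return True


@dataclass
class ChromSizes:
    """Chromosome name -> length (bp). All lengths must be positive."""

    sizes: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def items(self):
        return self.sizes.items()

    def genome_length(self) -> int:
        return sum(self.sizes.values())


@dataclass
class OverlapStats:
    """Midpoint-projection overlap statistic for query vs reference regions.

    ``observed`` query intervals have their midpoint inside the reference;
    under uniform placement the expectation is ``n_query * coverage_fraction``
    and the p-value is the upper binomial tail at the observed count.
    ``ratio`` is None when ``expected`` is 0 (empty query or empty reference).
    """

    observed: int
    expected: float
    ratio: Optional[float]
    p_value: float
    n_query: int


def normalize(interval_set: IntervalSet) -> IntervalSet:
    """Merge overlapping and touching intervals per chromosome.

    Total covered bp is conserved; the result satisfies the normalized-form
    invariant and the operation is idempotent.
    """
    return interval_set.normalize()


def net_intersection_length(region: GenomicInterval, peaks: IntervalSet) -> int:
    """Net bp of ``region`` covered by at least one interval of ``peaks``.

    This is the per-sample methylation metric for a super-enhancer or
    promoter: the length of the intersection of the region with the sample's
    methylation peak calls, with overlapping peaks counted once. A chromosome
    absent from ``peaks`` yields 0.
    """
    merged = peaks._merged_arrays().get(region.chrom)
    if merged is None:
        return 0
    starts, ends = merged
    if starts.size == 0:
        return 0
    clip_s = np.maximum(starts, region.start)
    clip_e = np.minimum(ends, region.end)
    return int(np.sum(np.maximum(clip_e - clip_s, 0)))


def coverage_in_windows(
    peaks: IntervalSet, chrom: str, win_starts: np.ndarray, win_ends: np.ndarray
) -> np.ndarray:
    """Vectorized net-intersection length for many windows on one chromosome.

    Equivalent to calling :func:`net_intersection_length` per window but in
    O((P + W) log P) using prefix sums over the merged peaks.
    """
    win_starts = np.asarray(win_starts, dtype=np.int64)
    win_ends = np.asarray(win_ends, dtype=np.int64)
    merged = peaks._merged_arrays().get(chrom)
    if merged is None or merged[0].size == 0:
        return np.zeros(len(win_starts), dtype=np.int64)
    starts, ends = merged
    # cum[i] = covered bp in peaks[0..i)
    cum = np.concatenate([[0], np.cumsum(ends - starts)])

    def covered_upto(pos: np.ndarray) -> np.ndarray:
        """Covered bp in [0, pos) per position."""
        idx = np.searchsorted(starts, pos, side="right")
        full = cum[idx]
        # subtract the part of peak idx-1 that lies at/after pos
        prev_end = np.where(idx > 0, ends[np.maximum(idx - 1, 0)], 0)
        overshoot = np.maximum(prev_end - pos, 0)
        # overshoot capped at the peak's own length (pos before peak start never
        # happens here because searchsorted guarantees starts[idx-1] <= pos)
        return full - overshoot

    return covered_upto(win_ends) - covered_upto(win_starts)


def tile_genome(sizes: ChromSizes, width: int = 100) -> IntervalSet:
    """Partition the genome into fixed-width non-overlapping tiles.

    Per chromosome, tiles ``[0,w), [w,2w), ...``; the final tile is truncated
    at the chromosome end. The tiles cover every bp exactly once.
    """
    if width < 1:
        raise ValueError(f"tile width must be >= 1, got {width}")
    tiles: List[GenomicInterval] = []
    for chrom, length in sizes.items():
        n_full, rem = divmod(length, width)
        edges = np.arange(0, n_full + 1) * width
        for i in range(n_full):
            tiles.append(GenomicInterval(chrom, int(edges[i]), int(edges[i + 1])))
        if rem:
            tiles.append(GenomicInterval(chrom, n_full * width, length))
    return IntervalSet(tiles)


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    """bp-level Jaccard index |A∩B| / |A∪B| of two interval sets.

    Both sets are normalized internally. Two empty sets give 0 by convention.
    """
    ma = a._merged_arrays()
    mb = b._merged_arrays()
    inter = 0
    for chrom in set(ma) & set(mb):
        sa, ea = ma[chrom]
        sb, eb = mb[chrom]
        # two-pointer sweep over merged runs
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                inter += int(hi - lo)
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
    cov_a = a.coverage()
    cov_b = b.coverage()
    union = cov_a + cov_b - inter
    if union == 0:
        return 0.0
    return inter / union


def distance_to_interval(pos: int, region: GenomicInterval, chrom: Optional[str] = None) -> float:
    """Distance in bp from a position to a region; 0 if the position is inside.

    Outside the region the distance is to the nearest covered base
    (``min(|pos - start|, |pos - (end-1)|)``). If ``chrom`` is given and
    differs from the region's chromosome, returns ``INF_DISTANCE`` — the
    caller simply skips such gene-SE combinations.
    """
    if chrom is not None and chrom != region.chrom:
        return INF_DISTANCE
    if region.start <= pos < region.end:
        return 0
    return min(abs(pos - region.start), abs(pos - (region.end - 1)))


def midpoint_distance(pos: int, region: GenomicInterval, chrom: Optional[str] = None) -> float:
    """Distance from a position to the region midpoint (descriptive metric)."""
    if chrom is not None and chrom != region.chrom:
        return INF_DISTANCE
    return abs(pos - region.midpoint())


def projection_overlap_stats(
    query: IntervalSet, reference: IntervalSet, sizes: ChromSizes
) -> OverlapStats:
    """Midpoint-projection binomial overlap test of query intervals vs a reference.

    Each query interval is projected to its midpoint; ``observed`` counts
    midpoints falling inside the (normalized) reference. Under the null of
    uniform placement the hit probability is the reference's genome coverage
    fraction, so ``expected = n_query * fraction`` and the p-value is the
    upper binomial tail ``P(X >= observed)``.
    """
    genome = sizes.genome_length()
    if genome <= 0:
        raise ValueError("genome length must be positive")
    ref_merged = reference._merged_arrays()
    ref_cov = reference.coverage()
    frac = ref_cov / genome
    n_query = len(query)
    observed = 0
    for iv in query:
        merged = ref_merged.get(iv.chrom)
        if merged is None or merged[0].size == 0:
            continue
        starts, ends = merged
        mid = iv.midpoint()
        k = int(np.searchsorted(starts, mid, side="right"))
        if k > 0 and mid < ends[k - 1]:
            observed += 1
    expected = n_query * frac
    ratio = observed / expected if expected > 0 else None
    if n_query == 0:
        p_value = 1.0
    else:
        # P(X >= observed) under Binomial(n_query, frac)
        p_value = float(_scipy_stats.binom.sf(observed - 1, n_query, frac))
    return OverlapStats(
        observed=observed, expected=expected, ratio=ratio, p_value=p_value, n_query=n_query
    )
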