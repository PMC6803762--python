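"""Assign in-cis candidate target genes to DM-SEs and correlate methylation
with expression.

Every gene whose TSS lies within 1 Mbp of a differentially methylated SE is
a candidate target (chromatin loops can reach that far). Eligibility
distance is TSS to the nearest SE edge (0 inside the SE); the TSS-to-SE-
midpoint distance is reported alongside as a descriptive column. Each
duplicated catalog row (same coordinates from different source cell lines)
pairs independently.

Per candidate pair, Kendall's tau-b between the SE's net methylation bp and
the gene's expression across shared samples; BH FDR across all candidate
pairs jointly (default) or within each SE (``fdr_scope="per-se"``). A pair
passes when q < alpha AND tau < 0 — positive correlations contradict the
repression model and are filtered as artifacts. Promoter-methylation
correlations are computed with the same machinery and reported alongside,
with their own FDR; they play no role in pass/fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .differential import DifferentialRegion
from .intervals import GenomicInterval, distance_to_interval, midpoint_distance
from .io import GeneAnnotation
from .quantify import RegionMethylationMatrix
from .stats import bh_fdr, kendall_tau

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000


@dataclass
class SEGenePair:
    """One candidate SE-gene pair with its correlation statistics and flags."""

    se_id: str
    interval: GenomicInterval
    gene_id: str
    tss_distance_bp: int
    tss_midpoint_distance_bp: int
    se_direction: str
    tau_se: Optional[float] = None
    p_se: Optional[float] = None
    q_se: Optional[float] = None
    tau_promoter: Optional[float] = None
    p_promoter: Optional[float] = None
    q_promoter: Optional[float] = None
    expression_direction: str = "none"
    passed: bool = False
    validated: Optional[bool] = None
    validation_probe: Optional[str] = None
    tau_probe: Optional[float] = None
    p_probe: Optional[float] = None


def find_targets(
    dm_ses: List[DifferentialRegion],
    genes: GeneAnnotation,
    window: int = DEFAULT_WINDOW,
) -> List[SEGenePair]:
    """Candidate pairs: gene TSS within ``window`` bp of a DM-SE edge.

    Only SEs with a hyper/hypo call are paired; cross-chromosome distances
    are infinite and simply skipped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    pairs: List[SEGenePair] = []
    gene_tab = genes.table
    by_chrom = {chrom: sub for chrom, sub in gene_tab.groupby("chrom", sort=False)}
    for se in dm_ses:
        if se.direction == "none":
            continue
        sub = by_chrom.get(se.interval.chrom)
        if sub is None:
            continue
        for row in sub.itertuples(index=False):
            d = distance_to_interval(int(row.tss), se.interval)
            if d <= window:
                pairs.append(
                    SEGenePair(
                        se_id=se.region_id,
                        interval=se.interval,
                        gene_id=str(row.gene_id),
                        tss_distance_bp=int(d),
                        tss_midpoint_distance_bp=int(midpoint_distance(int(row.tss), se.interval)),
                        se_direction=se.direction,
                    )
                )
    logger.info("find_targets: %d DM-SEs x genes -> %d candidate pairs",
                sum(1 for s in dm_ses if s.direction != "none"), len(pairs))
    return pairs


def correlate_pairs(
    pairs: List[SEGenePair],
    se_meth: RegionMethylationMatrix,
    expr: pd.DataFrame,
    alpha: float = 0.05,
    fdr_scope: str = "joint",
) -> List[SEGenePair]:
    """Kendall tau-b of SE methylation vs expression; q and pass flags.

    FDR is one joint BH correction across all candidate pairs with complete
    data (``fdr_scope="joint"``, default) or within each SE
    (``fdr_scope="per-se"``). ``passed = (q < alpha) and (tau < 0)``. Pairs
    whose gene is absent from the expression matrix are dropped with a
    logged warning.
    """
    if fdr_scope not in ("joint", "per-se"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    shared = [s for s in se_meth.sample_ids if s in expr.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")

    kept: List[SEGenePair] = []
    dropped = 0
    for pair in pairs:
        if pair.gene_id not in expr.index:
            dropped += 1
            continue
        if pair.se_id not in se_meth.values.index:
            raise ValueError(f"SE {pair.se_id!r} missing from methylation matrix")
        res = kendall_tau(
            se_meth.values.loc[pair.se_id, shared].to_numpy(dtype=float),
            expr.loc[pair.gene_id, shared].to_numpy(dtype=float),
        )
        pair.tau_se = res.statistic
        pair.p_se = res.p_value
        kept.append(pair)
    if dropped:
        logger.warning("correlate_pairs: dropped %d pairs with genes absent from expression", dropped)
    logger.info("correlate_pairs: %d pairs entering FDR (scope=%s)", len(kept), fdr_scope)

    if fdr_scope == "joint":
        groups: Dict[str, List[SEGenePair]] = {"": kept}
    else:
        groups = {}
        for pair in kept:
            groups.setdefault(pair.se_id, []).append(pair)
    for members in groups.values():
        q = bh_fdr([p.p_se for p in members])
        for pair, qv in zip(members, q):
            pair.q_se = float(qv) if np.isfinite(qv) else None

    for pair in kept:
        tau = pair.tau_se
        pair.expression_direction = (
            "down" if (tau is not None and tau < 0) else ("up" if tau and tau > 0 else "none")
        )
        pair.passed = bool(
            pair.q_se is not None and pair.q_se < alpha and tau is not None and tau < 0
        )
    logger.info("correlate_pairs: %d passed pairs", sum(p.passed for p in kept))
    return kept


def correlate_promoters(
    pairs: List[SEGenePair],
    promoter_meth: RegionMethylationMatrix,
    expr: pd.DataFrame,
) -> List[SEGenePair]:
    """Promoter-methylation vs expression tau per pair, FDR'd separately.

    Promoter region ids are the gene ids. Results annotate the pairs and do
    not alter pass/fail. Most promoters carry little or no methylation; an
    all-zero promoter yields a missing tau with p = 1.
    """
    shared = [s for s in promoter_meth.sample_ids if s in expr.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    with_data: List[SEGenePair] = []
    for pair in pairs:
        if pair.gene_id in promoter_meth.values.index and pair.gene_id in expr.index:
            res = kendall_tau(
                promoter_meth.values.loc[pair.gene_id, shared].to_numpy(dtype=float),
                expr.loc[pair.gene_id, shared].to_numpy(dtype=float),
            )
            pair.tau_promoter = res.statistic
            pair.p_promoter = res.p_value
            with_data.append(pair)
    q = bh_fdr([p.p_promoter for p in with_data])
    for pair, qv in zip(with_data, q):
        pair.q_promoter = float(qv) if np.isfinite(qv) else None
    return pairs


def pair_table(pairs: List[SEGenePair]) -> pd.DataFrame:
    """Flatten pairs to a TSV-ready frame (one row per candidate pair)."""
    return pd.DataFrame(
        [
            {
                "se_id": p.se_id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "gene_id": p.gene_id,
                "tss_distance_bp": p.tss_distance_bp,
                "tss_midpoint_distance_bp": p.tss_midpoint_distance_bp,
                "se_direction": p.se_direction,
                "tau_se": np.nan if p.tau_se is None else p.tau_se,
                "p_se": np.nan if p.p_se is None else p.p_se,
                "q_se": np.nan if p.q_se is None else p.q_se,
                "tau_promoter": np.nan if p.tau_promoter is None else p.tau_promoter,
                "p_promoter": np.nan if p.p_promoter is None else p.p_promoter,
                "q_promoter": np.nan if p.q_promoter is None else p.q_promoter,
                "expression_direction": p.expression_direction,
                "passed": p.passed,
                "validated": "NA" if p.validated is None else p.validated,
                "validation_probe": p.validation_probe or "NA",
                "tau_probe": np.nan if p.tau_probe is None else p.tau_probe,
                "p_probe": np.nan if p.p_probe is None else p.p_probe,
            }
            for p in pairs
        ]
    )
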