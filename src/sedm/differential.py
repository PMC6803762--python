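"""Differential-methylation calling.

Two scans mirror the two scales of the discovery analysis:

* :func:`scan_tiles` — genome-wide 100-bp tiles, binary methylation status,
  Fisher exact test of status x group per tile, BH FDR across tiles.
  Uninformative tiles (methylated in no sample, or in every sample) are
  excluded before the correction so they do not dilute it.
* :func:`se_differential` — per-SE Wilcoxon rank-sum on the net
  peak-intersection length between cases and controls, BH FDR across SEs,
  with significant SEs classified hypermethylated (higher in cases) or
  hypomethylated (lower in cases) from group means.

FDR is computed within each scan separately — tiles and SEs are two
separate analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet, OverlapStats, projection_overlap_stats
from .io import SampleSheet
from .quantify import RegionMethylationMatrix
from .stats import bh_fdr, fisher_exact_2x2, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass
class DifferentialRegion:
    """Per-region differential-methylation result."""

    region_id: str
    interval: GenomicInterval
    p_value: float
    q_value: float
    mean_case: float
    mean_control: float
    direction: str  # "hyper" | "hypo" | "none"

    @property
    def significant(self) -> bool:
        return np.isfinite(self.q_value) and self.direction in ("hyper", "hypo")


def _split_groups(
    matrix: RegionMethylationMatrix, samples: SampleSheet
) -> Tuple[np.ndarray, np.ndarray]:
    missing = [s for s in samples.sample_ids if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"samples in sheet but not in matrix: {missing}")
    case_ids = samples.group_ids("case")
    control_ids = samples.group_ids("control")
    return (
        matrix.values[case_ids].to_numpy(dtype=float),
        matrix.values[control_ids].to_numpy(dtype=float),
    )


def _direction(mean_case, mean_control, med_case, med_control, significant) -> str:
    """Hyper/hypo from the mean difference; median breaks exact mean ties."""
    if not significant:
        return "none"
    if mean_case > mean_control:
        return "hyper"
    if mean_case < mean_control:
        return "hypo"
    if med_case > med_control:
        return "hyper"
    if med_case < med_control:
        return "hypo"
    return "none"


def scan_tiles(
    status: RegionMethylationMatrix, samples: SampleSheet, alpha: float = 0.05
) -> List[DifferentialRegion]:
    """Fisher-exact differential scan over binary tile status.

    Per tile the 2x2 table is (methylated, unmethylated) x (case, control).
    Tiles whose margin is uninformative — methylated in zero samples or in
    all samples of both groups — are skipped before FDR; the number skipped
    is logged. Returned regions carry q-values; direction is set for tiles
    with q < alpha.
    """
    if status.kind != "binary":
        raise ValueError("scan_tiles requires a binary status matrix")
    samples.require_groups(1)
    case, control = _split_groups(status, samples)
    n_case, n_control = case.shape[1], control.shape[1]
    k_case = case.sum(axis=1).astype(int)
    k_control = control.sum(axis=1).astype(int)

    informative = ~(((k_case + k_control) == 0) | ((k_case + k_control) == n_case + n_control))
    n_skipped = int((~informative).sum())
    logger.info("scan_tiles: %d tiles, %d skipped as uninformative", len(informative), n_skipped)

    # Fisher p depends only on the table; memoize over (k_case, k_control)
    cache: Dict[Tuple[int, int], float] = {}
    p_values = np.full(len(informative), np.nan)
    for i in np.nonzero(informative)[0]:
        key = (k_case[i], k_control[i])
        if key not in cache:
            cache[key] = fisher_exact_2x2(
                k_case[i], n_case - k_case[i], k_control[i], n_control - k_control[i]
            ).p_value
        p_values[i] = cache[key]
    q_values = bh_fdr(p_values)

    out: List[DifferentialRegion] = []
    frac_case = k_case / n_case
    frac_control = k_control / n_control
    for i, rid in enumerate(status.region_ids):
        sig = informative[i] and np.isfinite(q_values[i]) and q_values[i] < alpha
        direction = _direction(frac_case[i], frac_control[i], frac_case[i], frac_control[i], sig)
        out.append(
            DifferentialRegion(
                region_id=rid,
                interval=status.interval(rid),
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                mean_case=float(frac_case[i]),
                mean_control=float(frac_control[i]),
                direction=direction,
            )
        )
    return out


def se_differential(
    meth: RegionMethylationMatrix, samples: SampleSheet, alpha: float = 0.05
) -> List[DifferentialRegion]:
    """Wilcoxon rank-sum differential methylation per SE, FDR across SEs.

    Regions with q < alpha are differentially methylated and classified
    hyper (mean case > mean control) or hypo; an exact mean tie falls back
    to the median, and a full tie leaves direction "none" (logged).
    """
    if meth.kind != "bp":
        raise ValueError("se_differential requires a bp-valued matrix")
    samples.require_groups(2)
    case, control = _split_groups(meth, samples)

    p_values = np.empty(case.shape[0])
    for i in range(case.shape[0]):
        p_values[i] = wilcoxon_rank_sum(case[i], control[i]).p_value
    q_values = bh_fdr(p_values)

    out: List[DifferentialRegion] = []
    ambiguous = 0
    for i, rid in enumerate(meth.region_ids):
        sig = bool(np.isfinite(q_values[i]) and q_values[i] < alpha)
        direction = _direction(
            case[i].mean(), control[i].mean(),
            float(np.median(case[i])), float(np.median(control[i])),
            sig,
        )
        if sig and direction == "none":
            ambiguous += 1
        out.append(
            DifferentialRegion(
                region_id=rid,
                interval=meth.interval(rid),
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                mean_case=float(case[i].mean()),
                mean_control=float(control[i].mean()),
                direction=direction,
            )
        )
    n_hyper = sum(1 for r in out if r.direction == "hyper")
    n_hypo = sum(1 for r in out if r.direction == "hypo")
    logger.info(
        "se_differential: %d SEs -> %d hyper, %d hypo (%d significant-but-tied)",
        len(out), n_hyper, n_hypo, ambiguous,
    )
    return out


def dm_tiles_vs_se_overlap(
    dm_tiles: List[DifferentialRegion] | IntervalSet,
    se_catalog: IntervalSet,
    sizes: ChromSizes,
) -> OverlapStats:
    """Overrepresentation of DM tiles inside the SE catalog.

    Midpoint-projection binomial test: observed DM-tile midpoints inside the
    catalog vs the expectation from the catalog's genome coverage fraction.
    """
    if isinstance(dm_tiles, IntervalSet):
        query = dm_tiles
    else:
        query = IntervalSet([r.interval for r in dm_tiles if r.direction != "none"])
    return projection_overlap_stats(query, se_catalog, sizes)


def differential_table(regions: List[DifferentialRegion]) -> pd.DataFrame:
    """Flatten results to a TSV-ready frame (one row per region)."""
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "direction": r.direction,
            }
            for r in regions
        ]
    )
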