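"""Cross-platform validation of SE-gene pairs in an array-profiled cohort.

In a validation cohort measured on a 450k-style methylation array, per-probe
beta values (β = M/(M+U), the methylated fraction of signal intensity) stand
in for region-level methylation. For each discovered SE-gene pair, the
probes located inside the SE are each correlated (Kendall tau-b) with the
gene's expression in the validation cohort; the probe with the minimum
(most negative) tau represents the pair. The pair validates when that probe
exists, its unadjusted p < 0.05, and its tau is negative — the negative-sign
requirement reflects the repression model and can be switched off
(``require_negative=False``) to accept any probe with p below the cutoff.

Validation only annotates pairs; it never changes discovery pass/fail flags.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional

import numpy as np
import pandas as pd

from .pairing import SEGenePair
from .stats import kendall_tau

logger = logging.getLogger(__name__)


def compute_beta(m: float, u: float) -> float:
    """Array beta value β = M/(M+U) from methylated/unmethylated intensities.

    Returns NaN (missing) when both intensities are zero; negative
    intensities are an error.
    """
    if m < 0 or u < 0:
        raise ValueError(f"negative intensity (M={m}, U={u})")
    if m + u == 0:
        return math.nan
    return m / (m + u)


def validate_pairs(
    pairs: List[SEGenePair],
    probes: pd.DataFrame,
    betas: pd.DataFrame,
    expr: pd.DataFrame,
    p_cut: float = 0.05,
    require_negative: bool = True,
) -> List[SEGenePair]:
    """Annotate each pair with its best in-SE probe and a validated flag.

    ``probes`` is the probe map (probe_id, chrom, pos; half-open containment
    on pos), ``betas`` the probe x sample beta matrix and ``expr`` the
    validation cohort's gene x sample expression matrix. Pairs whose SE
    contains no mapped probe, or whose gene is absent from ``expr``, get
    ``validated = None`` (not assessable).
    """
    shared = [s for s in betas.columns if s in expr.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared validation samples, got {len(shared)}")
    by_chrom = {chrom: sub for chrom, sub in probes.groupby("chrom", sort=False)}

    n_validated = n_missing = 0
    for pair in pairs:
        pair.validated = None
        pair.validation_probe = None
        pair.tau_probe = None
        pair.p_probe = None
        if pair.gene_id not in expr.index:
            n_missing += 1
            continue
        sub = by_chrom.get(pair.interval.chrom)
        if sub is None:
            n_missing += 1
            continue
        inside = sub[(sub["pos"] >= pair.interval.start) & (sub["pos"] < pair.interval.end)]
        probe_ids = [p for p in inside["probe_id"] if p in betas.index]
        if not probe_ids:
            n_missing += 1
            continue
        expr_vec = expr.loc[pair.gene_id, shared].to_numpy(dtype=float)
        best: Optional[tuple] = None
        for probe_id in probe_ids:
            res = kendall_tau(betas.loc[probe_id, shared].to_numpy(dtype=float), expr_vec)
            tau = res.statistic if res.statistic is not None else np.inf
            if best is None or tau < best[1]:
                best = (probe_id, tau, res.p_value)
        probe_id, tau, p = best
        if not np.isfinite(tau):
            n_missing += 1
            continue
        pair.validation_probe = probe_id
        pair.tau_probe = float(tau)
        pair.p_probe = float(p)
        ok = p < p_cut and (tau < 0 or not require_negative)
        pair.validated = bool(ok)
        n_validated += int(ok)
    logger.info(
        "validate_pairs: %d/%d validated (%d not assessable)",
        n_validated, len(pairs), n_missing,
    )
    return pairs
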