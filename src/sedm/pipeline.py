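"""End-to-end pipeline staging: discovery, pairing, and validation.

`run_all` chains the stages on files and writes the documented TSV/BED
artifacts into an output directory, logging the funnel (candidate SEs ->
DM-SEs -> candidate pairs -> passed pairs -> validated pairs) at every
filter. All thresholds default to the discovery analysis' values and are
overridable. Outputs are deterministic: rerunning with identical inputs and
config reproduces the tables byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import differential, io, pairing, quantify, validation
from .intervals import tile_genome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    se_bed: str
    samples: str
    chrom_sizes: str
    genes: str
    expr: str
    out_dir: str
    probes: Optional[str] = None
    betas: Optional[str] = None
    val_expr: Optional[str] = None
    tile_width: int = 100
    window: int = 1_000_000
    promoter_up: int = 1500
    promoter_down: int = 500
    dm_alpha: float = 0.05
    pair_alpha: float = 0.05
    validation_p: float = 0.05
    fdr_scope: str = "joint"
    with_tiles: bool = False

    def __post_init__(self) -> None:
        for name in ("tile_width", "window", "promoter_up", "promoter_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dm_alpha", "pair_alpha", "validation_p"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class RunResult:
    dm_table: pd.DataFrame
    pair_table: pd.DataFrame
    funnel: Dict[str, int] = field(default_factory=dict)
    overlap_table: Optional[pd.DataFrame] = None


def run_all(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline from files and write result tables.

    Stages: read inputs -> SE methylation quantification -> per-SE Wilcoxon
    differential scan -> in-cis target assignment -> SE and promoter
    Kendall correlations -> (optional) array validation -> (optional)
    genome tile scan with DM-tile/SE-catalog overlap statistics.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    try:
        return _run_all_inner(cfg, out, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)  # no partial outputs on failure
        raise


def _run_all_inner(cfg: RunConfig, out: Path, written: List[Path]) -> RunResult:
    sizes = io.read_chrom_sizes(cfg.chrom_sizes)
    se_catalog = io.read_bed(cfg.se_bed)
    sheet = io.read_sample_sheet(cfg.samples)
    genes = io.read_gene_annotation(cfg.genes)
    expr = io.read_matrix(cfg.expr)
    funnel: Dict[str, int] = {"candidate_ses": len(se_catalog)}
    logger.info("run_all: %d candidate SEs, %d samples, %d genes",
                len(se_catalog), len(sheet), len(genes))

    se_meth = quantify.region_methylation_matrix(se_catalog, sheet)
    dm = differential.se_differential(se_meth, sheet, alpha=cfg.dm_alpha)
    dm_called = [r for r in dm if r.direction != "none"]
    funnel["dm_ses"] = len(dm_called)
    funnel["dm_hyper"] = sum(1 for r in dm_called if r.direction == "hyper")
    funnel["dm_hypo"] = sum(1 for r in dm_called if r.direction == "hypo")

    dm_table = differential.differential_table(dm)
    dm_path = out / "se_differential.tsv"
    io.write_results(dm_table, dm_path)
    written.append(dm_path)
    dm_bed = out / "dm_se.bed"
    io.write_bed([r.interval for r in dm_called], dm_bed)
    written.append(dm_bed)

    pairs = pairing.find_targets(dm_called, genes, window=cfg.window)
    funnel["candidate_pairs"] = len(pairs)
    funnel["candidate_genes"] = len({p.gene_id for p in pairs})
    pairs = pairing.correlate_pairs(
        pairs, se_meth, expr, alpha=cfg.pair_alpha, fdr_scope=cfg.fdr_scope
    )
    promoters = quantify.promoter_intervals(
        genes, sizes, upstream=cfg.promoter_up, downstream=cfg.promoter_down
    )
    prom_meth = quantify.region_methylation_matrix(promoters, sheet)
    pairs = pairing.correlate_promoters(pairs, prom_meth, expr)
    funnel["passed_pairs"] = sum(1 for p in pairs if p.passed)

    if cfg.probes and cfg.betas and cfg.val_expr:
        probes = io.read_probe_map(cfg.probes)
        betas = io.read_matrix(cfg.betas, beta=True)
        val_expr = io.read_matrix(cfg.val_expr)
        pairs = validation.validate_pairs(
            pairs, probes, betas, val_expr, p_cut=cfg.validation_p
        )
        funnel["validated_pairs"] = sum(1 for p in pairs if p.passed and p.validated)

    pair_tab = pairing.pair_table(pairs)
    pair_path = out / "se_gene_pairs.tsv"
    io.write_results(pair_tab, pair_path)
    written.append(pair_path)
    passed_path = out / "se_gene_pairs_passed.tsv"
    io.write_results(pair_tab[pair_tab["passed"]], passed_path)
    written.append(passed_path)

    overlap_table = None
    if cfg.with_tiles:
        tiles = tile_genome(sizes, width=cfg.tile_width)
        status = quantify.tile_status_matrix(tiles, sheet)
        tile_dm = differential.scan_tiles(status, sheet, alpha=cfg.dm_alpha)
        tile_called = [r for r in tile_dm if r.direction != "none"]
        funnel["dm_tiles"] = len(tile_called)
        stats = differential.dm_tiles_vs_se_overlap(tile_called, se_catalog, sizes)
        overlap_table = pd.DataFrame(
            [
                {
                    "observed": stats.observed,
                    "expected": stats.expected,
                    "ratio": float("nan") if stats.ratio is None else stats.ratio,
                    "p_value": stats.p_value,
                    "n_query": stats.n_query,
                }
            ]
        )
        ov_path = out / "dm_tile_se_overlap.tsv"
        io.write_results(overlap_table, ov_path, sort_by=[])
        written.append(ov_path)

    funnel_path = out / "funnel.tsv"
    io.write_results(
        pd.DataFrame(sorted(funnel.items()), columns=["stage", "count"]),
        funnel_path,
        sort_by=[],
    )
    written.append(funnel_path)
    for stage, count in funnel.items():
        logger.info("funnel %s = %d", stage, count)
    return RunResult(dm_table=dm_table, pair_table=pair_tab, funnel=funnel,
                     overlap_table=overlap_table)
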