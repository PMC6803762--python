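"""Ground-truthed synthetic cohorts for end-to-end testing of the pipeline.

The generator emulates the statistical structure of a two-group
(tumor/control) methylation-capture cohort with matched expression data:

* a catalog of non-overlapping super-enhancers, a planted fraction of which
  is hyper- or hypomethylated in cases by a configurable effect size
  ``delta`` on the methylated *fraction* of the SE;
* per-sample peak BED files in which the peaks inside each SE cover exactly
  the sample's drawn methylated fraction (Beta-distributed jitter around the
  group mean, concentration ``jitter_kappa``), plus Poisson background peaks
  away from SEs and promoters;
* target genes whose expression decreases linearly in their SE's methylated
  fraction plus Gaussian noise (the repression model), planted positive
  "artifact" genes that increase with it, and independent decoy genes;
* promoter methylation that is low for most genes with a configurable
  hypermethylated subset;
* a validation cohort re-drawn from the same truth, measured as per-probe
  beta values (the per-sample SE fraction plus Gaussian probe noise) at
  probes placed uniformly inside each SE.

Everything is reproducible from the seed; the planted truth is returned and
written alongside the data so recovery (sensitivity, empirical FDR,
direction accuracy, pair recovery) can be scored by :func:`truth_eval`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .differential import DifferentialRegion
from .intervals import ChromSizes, GenomicInterval, IntervalSet
from .io import (
    GeneAnnotation,
    PathLike,
    Sample,
    SampleSheet,
    write_bed,
    write_chrom_sizes,
    write_gene_annotation,
    write_matrix,
    write_probe_map,
    write_sample_sheet,
)
from .pairing import SEGenePair


@dataclass
class SimulationConfig:
    """Generator parameters; defaults give a unit-test-scale cohort.

    The cohort sizes mirror a 47-case / 25-control discovery cohort with a
    22 / 6 validation cohort. ``frac_hyper``/``frac_hypo`` of the ``n_se``
    SEs are planted differential with case methylated fraction
    ``f0 + delta`` (hyper) or ``f0 - delta`` (hypo) against a control mean
    of ``f0``. ``min_dm_spacing`` forces planted DM-SEs apart so that each
    target gene's 1 Mb window contains exactly one DM-SE, which makes
    pair-level truth unambiguous; set it to 0 for dense unit-test genomes.
    """

    seed: int = 0
    n_case: int = 47
    n_control: int = 25
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_se: int = 200
    se_length_range: Tuple[int, int] = (5_000, 20_000)
    frac_hyper: float = 0.15
    frac_hypo: float = 0.05
    f0: float = 0.3
    delta: float = 0.3
    jitter_kappa: float = 50.0
    min_se_gap: int = 30_000
    min_dm_spacing: int = 0
    background_peaks_per_mb: float = 3.0
    background_peak_length: Tuple[int, int] = (500, 2_000)
    targets_per_se: int = 3
    decoys_per_se: int = 2
    artifacts_per_se: int = 1
    target_distance_range: Tuple[int, int] = (10_000, 500_000)
    expr_intercept: float = 10.0
    expr_slope: float = 10.0
    expr_noise_sd: float = 1.6
    promoter_low: float = 0.05
    promoter_high: float = 0.5
    promoter_hyper_fraction: float = 0.1
    probes_per_se: int = 4
    probe_noise_sd: float = 0.05
    n_val_case: int = 22
    n_val_control: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.frac_hyper + self.frac_hypo <= 1):
            raise ValueError("hyper + hypo fractions must lie in [0, 1]")
        for mu in (self.f0, self.f0 + self.delta, self.f0 - self.delta):
            if not (0.0 <= mu <= 1.0):
                raise ValueError(
                    f"f0 ± delta must stay in [0, 1]; got f0={self.f0}, delta={self.delta}"
                )
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per group")


@dataclass
class SimulationTruth:
    """Planted ground truth: SE classes, SE-gene links, and parameters."""

    se_class: Dict[str, str]  # se_id -> hyper | hypo | null
    links: List[Tuple[str, str, str]]  # (se_id, gene_id, "negative" | "positive")
    config: SimulationConfig

    def dm_se_ids(self) -> List[str]:
        return [s for s, c in self.se_class.items() if c != "null"]

    def to_tsv(self, se_path: PathLike, link_path: PathLike) -> None:
        pd.DataFrame(
            sorted(self.se_class.items()), columns=["se_id", "true_class"]
        ).to_csv(se_path, sep="\t", index=False)
        pd.DataFrame(
            sorted(self.links), columns=["se_id", "gene_id", "link_sign"]
        ).to_csv(link_path, sep="\t", index=False)


@dataclass
class SimulatedDataset:
    """In-memory handle to everything :func:`simulate` wrote."""

    out_dir: Path
    chrom_sizes: ChromSizes
    se_catalog: IntervalSet
    samples: SampleSheet
    genes: GeneAnnotation
    expression: pd.DataFrame
    probe_map: pd.DataFrame
    betas: pd.DataFrame
    validation_expression: pd.DataFrame
    truth: SimulationTruth

    @property
    def paths(self) -> Dict[str, Path]:
        d = self.out_dir
        return {
            "chrom_sizes": d / "chrom_sizes.tsv",
            "se_catalog": d / "se_catalog.bed",
            "sample_sheet": d / "samples.tsv",
            "genes": d / "genes.tsv",
            "expression": d / "expression.tsv",
            "probe_map": d / "probes.tsv",
            "betas": d / "betas.tsv",
            "validation_expression": d / "expression_validation.tsv",
            "truth_se": d / "truth_se.tsv",
            "truth_links": d / "truth_links.tsv",
        }


def _draw_fraction(rng: np.random.Generator, mu: float, kappa: float) -> float:
    """Beta-jittered methylated fraction around mu; degenerate at 0/1."""
    if mu <= 0.0:
        return 0.0
    if mu >= 1.0:
        return 1.0
    return float(rng.beta(mu * kappa, (1.0 - mu) * kappa))


def _composition(rng: np.random.Generator, total: int, parts: int) -> np.ndarray:
    """Random composition of `total` into `parts` positive integers."""
    if parts <= 1 or total <= parts:
        return np.array([total], dtype=np.int64) if total > 0 else np.zeros(0, dtype=np.int64)
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
    return np.diff(np.concatenate([[0], cuts, [total]]))


def _weak_composition(rng: np.random.Generator, total: int, parts: int) -> np.ndarray:
    """Random composition of `total` into `parts` non-negative integers."""
    if parts == 1:
        return np.array([total], dtype=np.int64)
    return rng.multinomial(total, np.full(parts, 1.0 / parts))


def _peaks_for_fraction(
    rng: np.random.Generator, se: GenomicInterval, fraction: float
) -> List[Tuple[int, int]]:
    """Non-overlapping peaks inside the SE covering round(fraction * length) bp."""
    length = se.length()
    covered = int(round(fraction * length))
    if covered <= 0:
        return []
    if covered >= length:
        return [(se.start, se.end)]
    k = int(min(1 + rng.integers(0, 4), covered))
    peak_lens = _composition(rng, covered, k)
    k = len(peak_lens)
    gaps = _weak_composition(rng, length - covered, k + 1)
    peaks = []
    pos = se.start
    for g, pl in zip(gaps[:-1], peak_lens):
        pos += int(g)
        peaks.append((pos, pos + int(pl)))
        pos += int(pl)
    return peaks


def _place_ses(rng: np.random.Generator, cfg: SimulationConfig) -> List[GenomicInterval]:
    """Non-overlapping SEs, count per chromosome proportional to its length."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    genome = lengths.sum()
    counts = np.floor(cfg.n_se * lengths / genome).astype(int)
    # distribute the remainder deterministically to the largest chromosomes
    order = np.argsort(-lengths, kind="stable")
    for i in range(cfg.n_se - counts.sum()):
        counts[order[i % len(chroms)]] += 1

    ses: List[GenomicInterval] = []
    idx = 0
    margin = 1_000_000  # leave room for target genes beyond the first/last SE
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        clen = cfg.chrom_lengths[chrom]
        se_lens = rng.integers(cfg.se_length_range[0], cfg.se_length_range[1] + 1, size=k)
        usable = clen - 2 * margin
        free = usable - int(se_lens.sum()) - (k + 1) * cfg.min_se_gap
        if free < 0:
            raise ValueError(
                f"chromosome {chrom} too small for {k} SEs with min gap {cfg.min_se_gap}"
            )
        extra = _weak_composition(rng, free, k + 1)
        pos = margin
        for j in range(k):
            pos += cfg.min_se_gap + int(extra[j])
            ses.append(GenomicInterval(chrom, pos, pos + int(se_lens[j]), ".", f"SE{idx:05d}"))
            pos += int(se_lens[j])
            idx += 1
    return ses


def _assign_classes(
    rng: np.random.Generator, ses: List[GenomicInterval], cfg: SimulationConfig
) -> Dict[str, str]:
    """Plant hyper/hypo classes, keeping DM-SEs >= min_dm_spacing apart."""
    n_hyper = int(round(cfg.n_se * cfg.frac_hyper))
    n_hypo = int(round(cfg.n_se * cfg.frac_hypo))
    order = rng.permutation(len(ses))
    chosen: List[int] = []
    for i in order:
        if len(chosen) == n_hyper + n_hypo:
            break
        ok = all(
            ses[i].chrom != ses[j].chrom
            or min(
                abs(ses[i].start - ses[j].end), abs(ses[j].start - ses[i].end)
            )
            >= cfg.min_dm_spacing
            for j in chosen
        )
        if ok:
            chosen.append(i)
    if len(chosen) < n_hyper + n_hypo:
        raise ValueError(
            f"cannot place {n_hyper + n_hypo} DM-SEs with spacing {cfg.min_dm_spacing}; "
            "enlarge the genome or reduce the spacing"
        )
    classes = {se.id: "null" for se in ses}
    for rank, i in enumerate(chosen):
        classes[ses[i].id] = "hyper" if rank < n_hyper else "hypo"
    return classes


def _group_mean(se_class: str, group: str, cfg: SimulationConfig) -> float:
    if group == "control" or se_class == "null":
        return cfg.f0
    return cfg.f0 + cfg.delta if se_class == "hyper" else cfg.f0 - cfg.delta


def _sample_fractions(
    rng: np.random.Generator,
    ses: List[GenomicInterval],
    classes: Dict[str, str],
    groups: Sequence[str],
    cfg: SimulationConfig,
) -> np.ndarray:
    """SE x sample matrix of drawn methylated fractions."""
    out = np.empty((len(ses), len(groups)))
    for i, se in enumerate(ses):
        for j, group in enumerate(groups):
            mu = _group_mean(classes[se.id], group, cfg)
            out[i, j] = _draw_fraction(rng, mu, cfg.jitter_kappa)
    return out


def _plant_genes(
    rng: np.random.Generator,
    ses: List[GenomicInterval],
    classes: Dict[str, str],
    cfg: SimulationConfig,
) -> Tuple[GeneAnnotation, List[Tuple[str, str, str]], Dict[str, Tuple[str, str]]]:
    """Gene table plus planted links.

    Returns (annotation, links, gene_model) where gene_model maps gene_id to
    ("target"|"artifact"|"decoy", se_id).
    """
    rows = []
    links: List[Tuple[str, str, str]] = []
    gene_model: Dict[str, Tuple[str, str]] = {}

    def place_tss(se: GenomicInterval) -> int:
        lo, hi = cfg.target_distance_range
        d = int(rng.integers(lo, hi + 1))
        side = rng.integers(0, 2)
        tss = se.start - d if side == 0 else se.end - 1 + d
        return max(tss, 2_000)

    for se in ses:
        is_dm = classes[se.id] != "null"
        n_targets = cfg.targets_per_se if is_dm else 0
        n_artifacts = cfg.artifacts_per_se if is_dm else 0
        for t in range(n_targets):
            gid = f"{se.id}_tgt{t}"
            rows.append((gid, se.chrom, "+" if rng.integers(0, 2) else "-", place_tss(se)))
            links.append((se.id, gid, "negative"))
            gene_model[gid] = ("target", se.id)
        for t in range(n_artifacts):
            gid = f"{se.id}_art{t}"
            rows.append((gid, se.chrom, "+" if rng.integers(0, 2) else "-", place_tss(se)))
            links.append((se.id, gid, "positive"))
            gene_model[gid] = ("artifact", se.id)
        for t in range(cfg.decoys_per_se):
            gid = f"{se.id}_dcy{t}"
            rows.append((gid, se.chrom, "+" if rng.integers(0, 2) else "-", place_tss(se)))
            gene_model[gid] = ("decoy", se.id)
    genes = GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])
    )
    return genes, links, gene_model


def _expression_matrix(
    rng: np.random.Generator,
    genes: GeneAnnotation,
    gene_model: Dict[str, Tuple[str, str]],
    se_index: Dict[str, int],
    fractions: np.ndarray,
    sample_ids: List[str],
    cfg: SimulationConfig,
) -> pd.DataFrame:
    n_samples = len(sample_ids)
    rows = {}
    for gid in genes.table["gene_id"]:
        kind, se_id = gene_model[gid]
        noise = rng.normal(0.0, cfg.expr_noise_sd, size=n_samples)
        if kind == "target":
            vals = cfg.expr_intercept - cfg.expr_slope * fractions[se_index[se_id]] + noise
        elif kind == "artifact":
            vals = (
                cfg.expr_intercept
                - cfg.expr_slope * cfg.f0
                + cfg.expr_slope * fractions[se_index[se_id]]
                + noise
            )
        else:
            vals = cfg.expr_intercept + noise
        rows[gid] = np.clip(vals, 0.0, None)
    return pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)


def simulate(config: SimulationConfig, out_dir: PathLike) -> SimulatedDataset:
    """Generate a full synthetic study into ``out_dir`` and return handles.

    Writes: chromosome sizes, SE catalog BED, per-sample peak BEDs plus the
    sample sheet, gene annotation, discovery expression matrix, probe map,
    validation-cohort beta matrix and expression matrix, and the truth
    tables. Identical config + seed produce byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)

    sizes = ChromSizes(dict(cfg.chrom_lengths))
    ses = _place_ses(rng, cfg)
    classes = _assign_classes(rng, ses, cfg)
    genes, links, gene_model = _plant_genes(rng, ses, classes, cfg)
    se_index = {se.id: i for i, se in enumerate(ses)}

    groups = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    sample_ids = [f"{g}_{i:03d}" for i, g in enumerate(groups)]
    fractions = _sample_fractions(rng, ses, classes, groups, cfg)

    # promoter methylation: low for most genes, high for a planted subset
    gene_ids = list(genes.table["gene_id"])
    promoter_mu = np.where(
        rng.random(len(gene_ids)) < cfg.promoter_hyper_fraction,
        cfg.promoter_high,
        cfg.promoter_low,
    )
    gene_rows = {row.gene_id: row for row in genes.table.itertuples(index=False)}

    # exclusion zone for background peaks: SEs and promoter windows (padded)
    exclusion: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    excl = IntervalSet(
        [GenomicInterval(se.chrom, max(se.start - 2_500, 0), se.end + 2_500) for se in ses]
        + [
            GenomicInterval(
                str(r.chrom), max(int(r.tss) - 4_000, 0), int(r.tss) + 4_000
            )
            for r in genes.table.itertuples(index=False)
        ]
    )
    exclusion = excl._merged_arrays()

    def background_peaks(chrom: str) -> List[Tuple[int, int]]:
        clen = cfg.chrom_lengths[chrom]
        n = rng.poisson(cfg.background_peaks_per_mb * clen / 1e6)
        lo, hi = cfg.background_peak_length
        peaks = []
        starts_arr, ends_arr = exclusion.get(chrom, (np.zeros(0), np.zeros(0)))
        for _ in range(n):
            plen = int(rng.integers(lo, hi + 1))
            s = int(rng.integers(0, max(clen - plen, 1)))
            k = int(np.searchsorted(starts_arr, s + plen, side="left"))
            if k > 0 and ends_arr[k - 1] > s:
                continue  # rejected: would perturb a planted region
            peaks.append((s, s + plen))
        return peaks

    samples: List[Sample] = []
    for j, (sid, group) in enumerate(zip(sample_ids, groups)):
        peak_list: List[GenomicInterval] = []
        for i, se in enumerate(ses):
            for s, e in _peaks_for_fraction(rng, se, fractions[i, j]):
                peak_list.append(GenomicInterval(se.chrom, s, e))
        for gi, gid in enumerate(gene_ids):
            row = gene_rows[gid]
            frac = _draw_fraction(rng, promoter_mu[gi], cfg.jitter_kappa)
            tss = int(row.tss)
            if row.strand == "+":
                win = GenomicInterval(str(row.chrom), max(tss - 1500, 0), tss + 500)
            else:
                win = GenomicInterval(str(row.chrom), max(tss - 500, 0), tss + 1500)
            for s, e in _peaks_for_fraction(rng, win, frac):
                peak_list.append(GenomicInterval(str(row.chrom), s, e))
        for chrom in cfg.chrom_lengths:
            for s, e in background_peaks(chrom):
                peak_list.append(GenomicInterval(chrom, s, e))
        peaks_path = out / "peaks" / f"{sid}.bed"
        write_bed(peak_list, peaks_path)
        samples.append(Sample(sid, group, str(peaks_path.resolve())))
    sheet = SampleSheet(samples)
    # the on-disk sheet uses paths relative to its own directory (portable)
    portable_sheet = SampleSheet(
        [Sample(s.sample_id, s.group, f"peaks/{s.sample_id}.bed") for s in samples]
    )

    expr = _expression_matrix(rng, genes, gene_model, se_index, fractions, sample_ids, cfg)

    # validation cohort: fresh draws from the same truth
    val_groups = ["case"] * cfg.n_val_case + ["control"] * cfg.n_val_control
    val_ids = [f"val_{g}_{i:03d}" for i, g in enumerate(val_groups)]
    val_fractions = _sample_fractions(rng, ses, classes, val_groups, cfg)
    val_expr = _expression_matrix(
        rng, genes, gene_model, se_index, val_fractions, val_ids, cfg
    )

    probe_rows = []
    beta_rows = {}
    for i, se in enumerate(ses):
        positions = np.sort(
            rng.choice(np.arange(se.start, se.end), size=cfg.probes_per_se, replace=False)
        )
        for k, pos in enumerate(positions):
            pid = f"{se.id}_probe{k}"
            probe_rows.append((pid, se.chrom, int(pos)))
            beta = np.clip(
                val_fractions[i] + rng.normal(0.0, cfg.probe_noise_sd, size=len(val_ids)),
                0.0,
                1.0,
            )
            beta_rows[pid] = beta
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    betas = pd.DataFrame.from_dict(beta_rows, orient="index", columns=val_ids)

    truth = SimulationTruth(classes, links, cfg)

    ds = SimulatedDataset(
        out_dir=out,
        chrom_sizes=sizes,
        se_catalog=IntervalSet(ses),
        samples=sheet,
        genes=genes,
        expression=expr,
        probe_map=probe_map,
        betas=betas,
        validation_expression=val_expr,
        truth=truth,
    )
    p = ds.paths
    write_chrom_sizes(sizes, p["chrom_sizes"])
    write_bed(ses, p["se_catalog"])
    write_sample_sheet(portable_sheet, p["sample_sheet"])
    write_gene_annotation(genes, p["genes"])
    write_matrix(expr, p["expression"], index_label="gene_id")
    write_probe_map(probe_map, p["probe_map"])
    write_matrix(betas, p["betas"], index_label="probe_id")
    write_matrix(val_expr, p["validation_expression"], index_label="gene_id")
    truth.to_tsv(p["truth_se"], p["truth_links"])
    return ds


@dataclass
class RecoveryReport:
    """Recovery of planted truth by a pipeline run."""

    dm_sensitivity: float
    dm_specificity: float
    dm_empirical_fdr: float
    direction_accuracy: float
    n_dm_called: int
    pair_recovery: float
    artifact_removal: float
    pair_empirical_fdr: float
    n_pairs_passed: int
    validation_rate: Optional[float] = None


def truth_eval(
    dm_results: List[DifferentialRegion],
    pairs: List[SEGenePair],
    truth: SimulationTruth,
) -> RecoveryReport:
    """Score DM-SE calls and SE-gene pairs against the planted truth.

    * ``dm_sensitivity`` — planted DM-SEs called with q < alpha (any direction).
    * ``dm_empirical_fdr`` — called SEs that were planted null.
    * ``direction_accuracy`` — true-positive calls with the correct
      hyper/hypo label.
    * ``pair_recovery`` — planted negative links recovered as passed pairs
      (denominator: all planted negative links).
    * ``artifact_removal`` — planted positive links NOT passed.
    * ``pair_empirical_fdr`` — passed pairs that are not planted negative links.
    * ``validation_rate`` — validated fraction of passed planted pairs that
      were assessable (None when validation was not run).
    """
    known = set(truth.se_class)
    unknown = [r.region_id for r in dm_results if r.region_id not in known]
    if unknown:
        raise ValueError(f"DM results contain unknown SE ids: {unknown[:5]}")

    called = {r.region_id: r for r in dm_results if r.direction != "none"}
    dm_true = {s for s, c in truth.se_class.items() if c != "null"}
    null_ses = known - dm_true
    tp = [s for s in called if s in dm_true]
    fp = [s for s in called if s not in dm_true]
    sens = len(tp) / len(dm_true) if dm_true else math.nan
    spec = (len(null_ses) - len(fp)) / len(null_ses) if null_ses else math.nan
    efdr = len(fp) / len(called) if called else 0.0
    dir_ok = sum(1 for s in tp if called[s].direction == truth.se_class[s])
    dir_acc = dir_ok / len(tp) if tp else math.nan

    neg_links = {(s, g) for s, g, sign in truth.links if sign == "negative"}
    pos_links = {(s, g) for s, g, sign in truth.links if sign == "positive"}
    passed = {(p.se_id, p.gene_id) for p in pairs if p.passed}
    pair_rec = len(passed & neg_links) / len(neg_links) if neg_links else math.nan
    art_rem = (
        1.0 - len(passed & pos_links) / len(pos_links) if pos_links else math.nan
    )
    pair_fdr = (
        len(passed - neg_links) / len(passed) if passed else 0.0
    )

    assessed = [
        p for p in pairs
        if p.passed and (p.se_id, p.gene_id) in neg_links and p.validated is not None
    ]
    val_rate = (
        sum(1 for p in assessed if p.validated) / len(assessed) if assessed else None
    )

    return RecoveryReport(
        dm_sensitivity=sens,
        dm_specificity=spec,
        dm_empirical_fdr=efdr,
        direction_accuracy=dir_acc,
        n_dm_called=len(called),
        pair_recovery=pair_rec,
        artifact_removal=art_rem,
        pair_empirical_fdr=pair_fdr,
        n_pairs_passed=len(passed),
        validation_rate=val_rate,
    )


def acceptance_config(seed: int) -> SimulationConfig:
    """The recovery-study conditions: 47/25 cohort, 200 SEs (30 hyper,
    10 hypo, delta 0.3, f0 0.3, lengths 5-20 kb) on a genome large enough
    that each target gene's 1 Mb window holds exactly one DM-SE."""
    return SimulationConfig(
        seed=seed,
        chrom_lengths={f"chr{i}": 30_000_000 for i in range(1, 7)},
        min_dm_spacing=2_200_000,
    )
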