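"""Readers and writers for the pipeline's external tables and interval files.

All genomic inputs arrive as plain text: BED3/BED6 (super-enhancer catalogs,
per-sample MACS-style peak calls — narrowPeak files are accepted because only
the first 3 or 6 columns are read), two-column chromosome-size tables, a
sample sheet binding each sample to its group and peak file, a 4-column gene
annotation (gene_id, chrom, strand, TSS), and TSV matrices (expression,
array beta values). Readers reject malformed records with the offending line
named rather than silently coercing; writers are deterministic byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet

_BED_SKIP_PREFIXES = ("track", "browser", "#")

PathLike = Union[str, Path]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str  # "case" or "control"
    peaks_path: str


@dataclass
class SampleSheet:
    """Cohort description: one row per sample with group label and peak file."""

    samples: List[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in sample sheet: {dupes}")
        bad = [s.sample_id for s in self.samples if s.group not in ("case", "control")]
        if bad:
            raise ValueError(f"samples with group not in {{case, control}}: {bad}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> List[str]:
        return [s.sample_id for s in self.samples]

    def group_ids(self, group: str) -> List[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def require_groups(self, min_per_group: int = 1) -> None:
        n_case = len(self.group_ids("case"))
        n_control = len(self.group_ids("control"))
        if n_case < min_per_group or n_control < min_per_group:
            raise ValueError(
                f"need >= {min_per_group} samples per group, "
                f"got {n_case} case / {n_control} control"
            )


@dataclass
class GeneAnnotation:
    """Gene table with unique gene ids, chromosome, strand, and 0-based TSS."""

    table: pd.DataFrame  # columns: gene_id, chrom, strand, tss

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "strand", "tss"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"gene annotation missing columns: {missing}")
        if self.table["gene_id"].duplicated().any():
            dupes = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))}")
        if (self.table["tss"] < 0).any():
            raise ValueError("negative TSS in gene annotation")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"unknown strand for genes: {self.table.loc[bad, 'gene_id'].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.table)


def read_bed(path: PathLike) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Columns 4 (name) and 6 (strand) are used when present; track/browser
    and ``#`` header lines are skipped. Malformed coordinates raise with the
    line number.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") else None
            strand = "."
            if len(fields) >= 6 and fields[5] != "":
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise ValueError(f"{path}:{lineno}: unknown strand token {strand!r}")
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(interval_set: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write intervals as BED6 in (chrom, start, end) sorted order."""
    rows = sorted(interval_set, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id or ""))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    """Read a two-column (name, length) chromosome-size table."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name = fields[0]
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length") from exc
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name!r}")
            sizes[name] = length
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_sample_sheet(path: PathLike, base_dir: Optional[PathLike] = None) -> SampleSheet:
    """Read the TSV sample sheet (sample_id, group, peaks_path).

    Relative peak paths are resolved against ``base_dir`` (default: the sheet's
    own directory).
    """
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "peaks_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    samples = []
    for row in df.itertuples(index=False):
        p = Path(row.peaks_path)
        if not p.is_absolute():
            p = base / p
        samples.append(Sample(str(row.sample_id), str(row.group), str(p)))
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.group, s.peaks_path) for s in sheet],
        columns=["sample_id", "group", "peaks_path"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: PathLike) -> GeneAnnotation:
    """Read the 4-column gene annotation TSV (gene_id, chrom, strand, tss)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str, "tss": np.int64}
    )
    return GeneAnnotation(df)


def write_gene_annotation(genes: GeneAnnotation, path: PathLike) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


def gtf_to_tss_table(path: PathLike, feature: str = "gene") -> GeneAnnotation:
    """Extract a TSS table from GTF ``gene``/``transcript`` lines.

    The strand-appropriate end is taken as the TSS: the (1-based) start for
    ``+`` strand features, the end for ``-`` strand, converted to 0-based.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature:
                continue
            chrom, start, end, strand, attrs = (
                fields[0],
                int(fields[3]),
                int(fields[4]),
                fields[6],
                fields[8],
            )
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gene_id = item.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                continue
            tss = start - 1 if strand == "+" else end - 1
            rows.append((gene_id, chrom, strand, tss))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])
    return GeneAnnotation(df)


def read_matrix(path: PathLike, beta: bool = False) -> pd.DataFrame:
    """Read a row_id x sample_id numeric TSV matrix.

    Empty cells and ``NA`` become NaN (excluded pairwise downstream).
    ``beta=True`` additionally enforces values in [0, 1]. Duplicate row ids
    and ragged rows are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise ValueError(f"{path}:{lineno}: ragged row ({ncol} columns expected)")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row ids: {sorted(set(dupes))}")
    non_numeric = df.apply(lambda c: not pd.api.types.is_numeric_dtype(c))
    if non_numeric.any():
        raise ValueError(f"{path}: non-numeric columns: {df.columns[non_numeric].tolist()}")
    if beta:
        vals = df.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError(f"{path}: beta values outside [0, 1]")
    return df


def _format_value(x: object) -> str:
    """Render numbers at 6 significant digits; integers exactly; NaN as NA."""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        if float(x).is_integer() and abs(x) < 1e15:
            return str(int(x))
        return f"{x:.6g}"
    if x is None:
        return "NA"
    return str(x)


def write_matrix(df: pd.DataFrame, path: PathLike, index_label: str = "id") -> None:
    """Write a matrix TSV deterministically (6 significant digits, NA for missing)."""
    with open(path, "w") as fh:
        fh.write(index_label + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            fh.write(str(idx) + "\t" + "\t".join(_format_value(v) for v in row) + "\n")


def write_results(
    df: pd.DataFrame, path: PathLike, sort_by: Optional[Sequence[str]] = None
) -> None:
    """Write a result table as TSV with deterministic row/column order.

    Rows are sorted by ``sort_by`` (default: whichever of chrom, start,
    gene_id are present, in that order); floats are rendered at 6 significant
    digits so identical inputs give byte-identical files.
    """
    if sort_by is None:
        sort_by = [c for c in ("chrom", "start", "gene_id", "se_id", "region_id") if c in df.columns]
    out = df.sort_values(list(sort_by), kind="mergesort") if sort_by else df
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def read_probe_map(path: PathLike) -> pd.DataFrame:
    """Read the array probe map TSV (probe_id, chrom, pos); pos is 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": np.int64})
    required = ["probe_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"probe map {path} missing columns: {missing}")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: negative probe positions")
    return df


def write_probe_map(df: pd.DataFrame, path: PathLike) -> None:
    df[["probe_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA", ""])
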