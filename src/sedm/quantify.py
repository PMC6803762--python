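"""Turn per-sample methylation peak calls into region x sample matrices.

Two entry semantics, matching the two scales of the analysis:

* **binary status** for genome tiles — a tile is "methylated" in a sample if
  it has any intersection with that sample's peak calls;
* **net bp** for super-enhancers and promoters — the net length of the
  intersection of the region with the sample's peaks (overlapping peaks
  counted once). Raw bp is stored, not a fraction: the downstream tests are
  rank-based and invariant to per-region scaling.

Duplicate catalog entries with identical coordinates (the same SE reported
from different source cell lines) each keep their own row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet, coverage_in_windows
from .io import GeneAnnotation, PathLike, SampleSheet, read_bed, write_matrix


@dataclass
class RegionMethylationMatrix:
    """Region x sample methylation matrix with region metadata.

    ``values`` is indexed by ``region_id`` with one column per sample-sheet
    sample (sheet order preserved); ``regions`` carries chrom/start/end/kind
    per row in the same order. ``kind`` is "binary" (tile status) or "bp"
    (net intersection length).
    """

    values: pd.DataFrame
    regions: pd.DataFrame  # columns: region_id, chrom, start, end, source_id
    kind: str  # "binary" | "bp"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "bp"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not self.values.index.equals(pd.Index(self.regions["region_id"])):
            raise ValueError("values index does not match region metadata")

    @property
    def region_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def interval(self, region_id: str) -> GenomicInterval:
        if not hasattr(self, "_interval_lookup"):
            self._interval_lookup = {
                rid: (chrom, start, end)
                for rid, chrom, start, end in zip(
                    self.regions["region_id"],
                    self.regions["chrom"],
                    self.regions["start"],
                    self.regions["end"],
                )
            }
        chrom, start, end = self._interval_lookup[region_id]
        return GenomicInterval(str(chrom), int(start), int(end))

    def to_tsv(self, path: PathLike) -> None:
        meta = self.regions.copy()
        meta["kind"] = self.kind
        out = pd.concat(
            [meta.set_index("region_id")[["chrom", "start", "end", "kind", "source_id"]],
             self.values],
            axis=1,
        )
        write_matrix(out, path, index_label="region_id")


def _region_frame(regions: IntervalSet, prefix: str) -> pd.DataFrame:
    rows = []
    for i, iv in enumerate(regions):
        rid = f"{prefix}{i:05d}" if iv.id is None else f"{iv.id}"
        rows.append((rid, iv.chrom, iv.start, iv.end, iv.id or ""))
    df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "source_id"])
    # identical ids from duplicated catalog entries get a disambiguating suffix
    if df["region_id"].duplicated().any():
        counts: Dict[str, int] = {}
        new_ids = []
        for rid in df["region_id"]:
            k = counts.get(rid, 0)
            counts[rid] = k + 1
            new_ids.append(rid if k == 0 else f"{rid}.dup{k}")
        df["region_id"] = new_ids
    return df


def _load_peaks(sample_id: str, path: str) -> IntervalSet:
    try:
        return read_bed(path)
    except OSError as exc:
        raise ValueError(f"cannot read peak file for sample {sample_id!r}: {path}") from exc


def _quantify(
    regions: IntervalSet, samples: SampleSheet, prefix: str, binary: bool
) -> RegionMethylationMatrix:
    meta = _region_frame(regions, prefix)
    by_chrom: Dict[str, np.ndarray] = {}
    for chrom, sub in meta.groupby("chrom", sort=False):
        by_chrom[chrom] = sub.index.to_numpy()
    n_regions = len(meta)
    cols = {}
    for sample in samples:
        peaks = _load_peaks(sample.sample_id, sample.peaks_path)
        col = np.zeros(n_regions, dtype=np.int64)
        for chrom, idx in by_chrom.items():
            starts = meta.loc[idx, "start"].to_numpy(dtype=np.int64)
            ends = meta.loc[idx, "end"].to_numpy(dtype=np.int64)
            col[idx] = coverage_in_windows(peaks, chrom, starts, ends)
        cols[sample.sample_id] = (col > 0).astype(np.int8) if binary else col
    values = pd.DataFrame(cols, index=pd.Index(meta["region_id"], name="region_id"))
    return RegionMethylationMatrix(values, meta, "binary" if binary else "bp")


def tile_status_matrix(tiles: IntervalSet, samples: SampleSheet) -> RegionMethylationMatrix:
    """Binary tile x sample matrix: 1 iff the tile intersects any peak."""
    return _quantify(tiles, samples, "tile", binary=True)


def region_methylation_matrix(
    regions: IntervalSet, samples: SampleSheet
) -> RegionMethylationMatrix:
    """bp-valued region x sample matrix of net peak-intersection lengths."""
    return _quantify(regions, samples, "region", binary=False)


def promoter_intervals(
    genes: GeneAnnotation,
    sizes: Optional[ChromSizes] = None,
    upstream: int = 1500,
    downstream: int = 500,
) -> IntervalSet:
    """Strand-aware promoter windows around each TSS.

    ``+`` strand TSS t -> [t-upstream, t+downstream); ``-`` strand mirrors to
    [t-downstream, t+upstream). Windows are clamped to [0, chrom length).
    A TSS at or beyond its chromosome end is an error.
    """
    out: List[GenomicInterval] = []
    for row in genes.table.itertuples(index=False):
        tss = int(row.tss)
        chrom = str(row.chrom)
        if sizes is not None:
            if chrom not in sizes:
                raise ValueError(f"gene {row.gene_id}: chromosome {chrom!r} not in sizes")
            if tss >= sizes[chrom]:
                raise ValueError(
                    f"gene {row.gene_id}: TSS {tss} beyond end of {chrom} ({sizes[chrom]})"
                )
        if row.strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start = max(start, 0)
        if sizes is not None:
            end = min(end, sizes[chrom])
        if end <= start:  # fully clamped away (TSS at chromosome edge)
            end = start + 1
        out.append(GenomicInterval(chrom, start, end, str(row.strand), str(row.gene_id)))
    return IntervalSet(out)
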