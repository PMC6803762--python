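import numpy as np
import pandas as pd
import pytest

from sedm.differential import DifferentialRegion
from sedm.intervals import GenomicInterval
from sedm.io import GeneAnnotation
from sedm.pairing import correlate_pairs, correlate_promoters, find_targets, pair_table
from sedm.quantify import RegionMethylationMatrix


def dm_se(chrom="chr1", start=2_000_000, end=2_010_000, direction="hyper", rid="SE0"):
    return DifferentialRegion(
        region_id=rid,
        interval=GenomicInterval(chrom, start, end),
        p_value=1e-4,
        q_value=1e-3,
        mean_case=100.0,
        mean_control=10.0,
        direction=direction,
    )


def genes_at(tss_list, chrom="chr1"):
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(tss_list))],
                "chrom": chrom,
                "strand": "+",
                "tss": tss_list,
            }
        )
    )


def meth_matrix(row_values: dict, samples):
    df = pd.DataFrame(row_values, index=samples).T
    df.index.name = "region_id"
    meta = pd.DataFrame(
        {
            "region_id": df.index,
            "chrom": "chr1",
            "start": 2_000_000,
            "end": 2_010_000,
            "source_id": "",
        }
    )
    return RegionMethylationMatrix(df, meta, "bp")


SAMPLES = ["s1", "s2", "s3", "s4"]


class TestFindTargets:
    def test_window_edge_inclusion(self):
        pairs = find_targets([dm_se()], genes_at([1_500_000, 3_500_000, 2_005_000]))
        got = {(p.gene_id, p.tss_distance_bp) for p in pairs}
        # 500 kb away: in; inside the SE: distance 0; 1,490,001 bp away: out
        assert got == {("g0", 500_000), ("g2", 0)}

    def test_cross_chromosome_skipped(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000], chrom="chr9"))
        assert pairs == []

    def test_non_dm_ses_not_paired(self):
        pairs = find_targets([dm_se(direction="none")], genes_at([2_005_000]))
        assert pairs == []

    def test_duplicated_se_rows_pair_independently(self):
        ses = [dm_se(rid="SE0"), dm_se(rid="SE0.dup1")]
        pairs = find_targets(ses, genes_at([2_005_000]))
        assert [p.se_id for p in pairs] == ["SE0", "SE0.dup1"]

    def test_midpoint_distance_reported(self):
        pairs = find_targets([dm_se()], genes_at([1_500_000]))
        assert pairs[0].tss_midpoint_distance_bp == 505_000

    def test_emitted_pairs_respect_window(self, rng):
        tss = rng.integers(0, 6_000_000, 200).tolist()
        pairs = find_targets([dm_se()], genes_at(tss))
        assert all(p.tss_distance_bp <= 1_000_000 for p in pairs)


class TestCorrelatePairs:
    def expr(self, values: dict) -> pd.DataFrame:
        return pd.DataFrame(values, index=SAMPLES).T

    def test_negative_correlation_passes(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000]))
        meth = meth_matrix({"SE0": [0, 100, 200, 300]}, SAMPLES)
        expr = self.expr({"g0": [10, 8, 6, 4]})
        out = correlate_pairs(pairs, meth, expr)
        assert out[0].tau_se == pytest.approx(-1.0)
        assert out[0].expression_direction == "down"

    def test_positive_correlation_filtered(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000]))
        meth = meth_matrix({"SE0": [0, 100, 200, 300]}, SAMPLES)
        expr = self.expr({"g0": [4, 6, 8, 10]})
        out = correlate_pairs(pairs, meth, expr)
        assert out[0].tau_se == pytest.approx(1.0)
        assert not out[0].passed  # sign filter regardless of q

    def test_constant_methylation_never_passes(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000]))
        meth = meth_matrix({"SE0": [50, 50, 50, 50]}, SAMPLES)
        expr = self.expr({"g0": [4, 6, 8, 10]})
        out = correlate_pairs(pairs, meth, expr)
        assert out[0].p_se == 1.0
        assert not out[0].passed

    def test_gene_absent_from_expression_dropped(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000, 2_006_000]))
        meth = meth_matrix({"SE0": [0, 100, 200, 300]}, SAMPLES)
        expr = self.expr({"g0": [10, 8, 6, 4]})
        out = correlate_pairs(pairs, meth, expr)
        assert [p.gene_id for p in out] == ["g0"]

    def test_too_few_shared_samples_rejected(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000]))
        meth = meth_matrix({"SE0": [0, 100, 200, 300]}, SAMPLES)
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g0"])
        with pytest.raises(ValueError, match="shared samples"):
            correlate_pairs(pairs, meth, expr)

    def test_joint_vs_per_se_fdr_scope(self, rng):
        ses = [
            dm_se(rid="SE0", start=2_000_000, end=2_010_000),
            dm_se(rid="SE1", start=30_000_000, end=30_010_000),
        ]
        genes = GeneAnnotation(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(6)],
                    "chrom": "chr1",
                    "strand": "+",
                    "tss": [2_005_000, 2_100_000, 2_200_000,
                            30_005_000, 30_100_000, 30_200_000],
                }
            )
        )
        samples = [f"s{i}" for i in range(12)]
        meth_df = pd.DataFrame(
            {"SE0": rng.integers(0, 500, 12), "SE1": rng.integers(0, 500, 12)},
            index=samples,
        ).T
        meth_df.index.name = "region_id"
        meta = pd.DataFrame(
            {
                "region_id": ["SE0", "SE1"],
                "chrom": "chr1",
                "start": [2_000_000, 30_000_000],
                "end": [2_010_000, 30_010_000],
                "source_id": "",
            }
        )
        meth = RegionMethylationMatrix(meth_df, meta, "bp")
        expr = pd.DataFrame(
            rng.normal(10, 2, size=(6, 12)),
            index=[f"g{i}" for i in range(6)],
            columns=samples,
        )
        pairs_joint = correlate_pairs(
            find_targets(ses, genes), meth, expr, fdr_scope="joint"
        )
        pairs_per_se = correlate_pairs(
            find_targets(ses, genes), meth, expr, fdr_scope="per-se"
        )
        # same raw p-values, possibly different q due to correction scope
        assert [p.p_se for p in pairs_joint] == [p.p_se for p in pairs_per_se]
        with pytest.raises(ValueError, match="fdr_scope"):
            correlate_pairs(find_targets(ses, genes), meth, expr, fdr_scope="global")


class TestCorrelatePromoters:
    def test_zero_promoter_methylation_missing_tau(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000]))
        se_meth = meth_matrix({"SE0": [0, 100, 200, 300]}, SAMPLES)
        expr = pd.DataFrame({"g0": [10.0, 8, 6, 4]}, index=SAMPLES).T
        pairs = correlate_pairs(pairs, se_meth, expr)
        prom_df = pd.DataFrame({"g0": [0, 0, 0, 0]}, index=SAMPLES).T
        prom_df.index.name = "region_id"
        meta = pd.DataFrame(
            {"region_id": ["g0"], "chrom": "chr1", "start": 2_003_500,
             "end": 2_005_500, "source_id": "g0"}
        )
        prom = RegionMethylationMatrix(prom_df, meta, "bp")
        out = correlate_promoters(pairs, prom, expr)
        assert out[0].tau_promoter is None
        assert out[0].p_promoter == 1.0

    def test_promoter_and_se_statistics_coexist(self):
        pairs = find_targets([dm_se()], genes_at([2_005_000]))
        se_meth = meth_matrix({"SE0": [0, 100, 200, 300]}, SAMPLES)
        expr = pd.DataFrame({"g0": [10.0, 8, 6, 4]}, index=SAMPLES).T
        pairs = correlate_pairs(pairs, se_meth, expr)
        prom_df = pd.DataFrame({"g0": [0, 10, 20, 30]}, index=SAMPLES).T
        prom_df.index.name = "region_id"
        meta = pd.DataFrame(
            {"region_id": ["g0"], "chrom": "chr1", "start": 2_003_500,
             "end": 2_005_500, "source_id": "g0"}
        )
        prom = RegionMethylationMatrix(prom_df, meta, "bp")
        out = correlate_promoters(pairs, prom, expr)
        assert out[0].tau_promoter == pytest.approx(-1.0)
        assert out[0].tau_se == pytest.approx(-1.0)
        tab = pair_table(out)
        assert {"tau_se", "q_se", "tau_promoter", "q_promoter"} <= set(tab.columns)
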