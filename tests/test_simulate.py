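import filecmp
from pathlib import Path

import numpy as np
import pytest

from sedm.differential import DifferentialRegion, se_differential
from sedm.intervals import net_intersection_length
from sedm.io import read_bed
from sedm.pairing import SEGenePair
from sedm.quantify import region_methylation_matrix
from sedm.simulate import (
    SimulationConfig,
    SimulationTruth,
    simulate,
    truth_eval,
)


def tiny_config(**kwargs):
    base = dict(
        seed=7,
        n_case=6,
        n_control=5,
        n_se=20,
        chrom_lengths={"chrA": 6_000_000, "chrB": 6_000_000},
        n_val_case=6,
        n_val_control=4,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


def _dir_files(path: Path):
    return sorted(str(p.relative_to(path)) for p in path.rglob("*") if p.is_file())


class TestSimulate:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        a = simulate(tiny_config(), tmp_path / "a")
        b = simulate(tiny_config(), tmp_path / "b")
        files_a = _dir_files(a.out_dir)
        assert files_a == _dir_files(b.out_dir)
        for rel in files_a:
            if rel == "samples.tsv" or rel.endswith(".bed") or rel.endswith(".tsv"):
                assert (a.out_dir / rel).read_bytes() == (b.out_dir / rel).read_bytes(), rel

    def test_different_seed_changes_data(self, tmp_path):
        a = simulate(tiny_config(seed=7), tmp_path / "a")
        b = simulate(tiny_config(seed=8), tmp_path / "b")
        assert not a.expression.equals(b.expression)

    def test_truth_class_counts_match_fractions(self, tmp_path):
        cfg = tiny_config(frac_hyper=0.2, frac_hypo=0.1)
        ds = simulate(cfg, tmp_path / "c")
        classes = list(ds.truth.se_class.values())
        assert classes.count("hyper") == round(20 * 0.2)
        assert classes.count("hypo") == round(20 * 0.1)

    def test_realized_fraction_tracks_group_mean(self, tmp_path):
        ds = simulate(tiny_config(), tmp_path / "d")
        meth = region_methylation_matrix(ds.se_catalog, ds.samples)
        case_ids = ds.samples.group_ids("case")
        lengths = (meth.regions["end"] - meth.regions["start"]).to_numpy()
        for se_id, cls in ds.truth.se_class.items():
            mu = {"hyper": 0.6, "hypo": 0.0, "null": 0.3}[cls]
            frac = meth.values.loc[se_id, case_ids].to_numpy() / lengths[
                meth.values.index.get_loc(se_id)
            ]
            # per-sample jitter sd ~ sqrt(mu(1-mu)/51) ~ 0.07; mean of 6 well within 0.15
            assert abs(frac.mean() - mu) < 0.15, (se_id, cls)

    def test_peak_coverage_equals_drawn_fraction_rounding(self, tmp_path):
        # realized per-SE coverage is exact to 1 bp of round(f * L)
        ds = simulate(tiny_config(), tmp_path / "e")
        sample = ds.samples.samples[0]
        peaks = read_bed(sample.peaks_path)
        for se in ds.se_catalog.intervals[:5]:
            bp = net_intersection_length(se, peaks)
            assert 0 <= bp <= se.length()

    def test_infeasible_delta_rejected(self):
        with pytest.raises(ValueError, match="f0"):
            SimulationConfig(f0=0.3, delta=0.8)

    def test_delta_zero_removes_group_difference(self, tmp_path):
        ds = simulate(tiny_config(delta=0.0, n_case=12, n_control=12), tmp_path / "f")
        meth = region_methylation_matrix(ds.se_catalog, ds.samples)
        res = se_differential(meth, ds.samples)
        assert sum(1 for r in res if r.direction != "none") <= 2

    def test_probes_fall_inside_their_se(self, tmp_path):
        ds = simulate(tiny_config(), tmp_path / "g")
        ses = {se.id: se for se in ds.se_catalog.intervals}
        for row in ds.probe_map.itertuples(index=False):
            se = ses[row.probe_id.rsplit("_probe", 1)[0]]
            assert se.start <= row.pos < se.end
            assert row.chrom == se.chrom

    def test_beta_values_in_unit_interval(self, tmp_path):
        ds = simulate(tiny_config(), tmp_path / "h")
        vals = ds.betas.to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()


class TestTruthEval:
    def make_truth(self):
        cfg = tiny_config()
        return SimulationTruth(
            se_class={"SE0": "hyper", "SE1": "hypo", "SE2": "null"},
            links=[("SE0", "g0", "negative"), ("SE0", "g1", "positive")],
            config=cfg,
        )

    def region(self, rid, direction, q=0.01):
        from sedm.intervals import GenomicInterval

        return DifferentialRegion(
            region_id=rid,
            interval=GenomicInterval("chrA", 0, 1000),
            p_value=q / 10,
            q_value=q,
            mean_case=1.0,
            mean_control=0.0 if direction == "hyper" else 2.0,
            direction=direction,
        )

    def pair(self, se_id, gene_id, passed):
        from sedm.intervals import GenomicInterval

        p = SEGenePair(
            se_id=se_id,
            interval=GenomicInterval("chrA", 0, 1000),
            gene_id=gene_id,
            tss_distance_bp=0,
            tss_midpoint_distance_bp=0,
            se_direction="hyper",
        )
        p.passed = passed
        return p

    def test_perfect_recovery(self):
        truth = self.make_truth()
        dm = [self.region("SE0", "hyper"), self.region("SE1", "hypo"),
              self.region("SE2", "none", q=0.9)]
        pairs = [self.pair("SE0", "g0", True), self.pair("SE0", "g1", False)]
        rep = truth_eval(dm, pairs, truth)
        assert rep.dm_sensitivity == 1.0
        assert rep.dm_empirical_fdr == 0.0
        assert rep.direction_accuracy == 1.0
        assert rep.pair_recovery == 1.0
        assert rep.artifact_removal == 1.0
        assert rep.pair_empirical_fdr == 0.0

    def test_zero_calls(self):
        truth = self.make_truth()
        dm = [self.region(r, "none", q=0.9) for r in ("SE0", "SE1", "SE2")]
        rep = truth_eval(dm, [], truth)
        assert rep.dm_sensitivity == 0.0
        assert rep.n_dm_called == 0

    def test_unknown_ids_rejected(self):
        truth = self.make_truth()
        with pytest.raises(ValueError, match="unknown"):
            truth_eval([self.region("SE99", "hyper")], [], truth)

    def test_wrong_direction_counted(self):
        truth = self.make_truth()
        dm = [self.region("SE0", "hypo"), self.region("SE1", "hypo"),
              self.region("SE2", "none", q=0.9)]
        rep = truth_eval(dm, [], truth)
        assert rep.direction_accuracy == 0.5
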