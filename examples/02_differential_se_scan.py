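"""Differential methylation scan over a simulated two-group cohort.

Simulates a small tumor/control cohort with planted hyper- and
hypomethylated super-enhancers, quantifies per-SE methylation as net peak
intersection bp, and runs the rank-sum scan with BH FDR.
"""

import tempfile

from sedm import SimulationConfig, region_methylation_matrix, se_differential, simulate

cfg = SimulationConfig(
    seed=11,
    n_case=12,
    n_control=10,
    n_se=40,
    chrom_lengths={"chrA": 10_000_000, "chrB": 10_000_000},
)

with tempfile.TemporaryDirectory() as td:
    ds = simulate(cfg, td)
    meth = region_methylation_matrix(ds.se_catalog, ds.samples)
    results = se_differential(meth, ds.samples, alpha=0.05)

hyper = [r for r in results if r.direction == "hyper"]
hypo = [r for r in results if r.direction == "hypo"]
print(f"{len(results)} candidate SEs tested: {len(hyper)} hypermethylated, "
      f"{len(hypo)} hypomethylated at FDR < 0.05")
# hyper = more methylation in cases than controls; hypo = less.

truth = ds.truth.se_class
correct = sum(1 for r in hyper + hypo if truth[r.region_id] == r.direction)
print(f"planted truth: {sum(1 for c in truth.values() if c != 'null')} DM-SEs; "
      f"{correct} of {len(hyper) + len(hypo)} calls match the planted direction")

print("\nstrongest calls (region, q-value, mean case bp, mean control bp):")
for r in sorted(hyper + hypo, key=lambda r: r.q_value)[:5]:
    print(f"  {r.region_id}  {r.direction:5s}  q={r.q_value:.2e}  "
          f"{r.mean_case:8.0f}  {r.mean_control:8.0f}")
# the bp means show the direction: hypermethylated SEs carry more
# methylation-peak coverage in the case group.
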