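"""Paired donor-level comparison of two macrophage populations.

Simulates the paired design — 7 donors, each contributing an oxidative
and a glycolytic population of cells — aggregates cells to donor means,
runs the exact Wilcoxon signed-rank test on both the mean lifetime and
the optical redox ratio, and prints the metabolic call.
"""

from flimmet import compare_experiment, simulate_paired_experiment

table, truth = simulate_paired_experiment(n_donors=7, seed=11)
print(f"{len(table)} cells from {table['donor'].nunique()} donors, "
      f"designed lifetime effect +{truth['effect_tau']} ns\n")

for metric, res in compare_experiment(table).items():
    print(f"{metric}: oxidative={res.mean_a:.3f}  glycolytic={res.mean_b:.3f}  "
          f"W+={res.statistic:.0f}  p={res.p_value:.6g} (n={res.n_pairs} pairs)")
    if res.call_a != "n/a":
        print(f"  -> oxidative population: {res.call_a}; "
              f"glycolytic population: {res.call_b}")
# With all 7 within-donor differences sharing a sign, the exact
# two-sided Wilcoxon p-value is 2/2^7 = 0.015625.
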