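# flimmet

Label-free metabolic profiling of cells from NAD(P)H fluorescence-lifetime
imaging (FLIM/TCSPC) data.

Autofluorescent NAD(P)H decays with a short lifetime (τ₁ ≈ 0.4–0.5 ns) when
free in the cytosol and a long one (τ₂ ≈ 2.5–3 ns) when protein-bound, so the
shape of a pixel's photon-arrival histogram reports on cellular bioenergetics:
cells relying on oxidative phosphorylation show a longer mean lifetime than
cells running glycolysis. `flimmet` implements the full analysis chain used to
classify sorted cell populations (e.g. synovial-tissue macrophage subsets) by
their dominant energy pathway:

* **Decay model.** Each pixel's TCSPC histogram (by default 256 bins over the
  12.5 ns period of an 80 MHz pulsed laser) is modelled as a bi-exponential
  decay without an instrument-response term,

      I(t) = α₁·e^(−t/τ₁) + α₂·e^(−t/τ₂) + C,

  with the amplitude-weighted mean lifetime

      τ_avg = (α₁τ₁ + α₂τ₂) / (α₁ + α₂)

  and the protein-bound fraction α₂/(α₁+α₂) as derived readouts. The optical
  redox ratio ORR = FAD / NAD(P)H combines the two channel intensities.
* **Fitting and quality control.** Bounded Neyman-weighted least squares (or
  Poisson MLE) per pixel or per cell ROI; fits with reduced χ² < 1.3 count as
  good.
* **Image pipeline.** Intensity projection, Otsu segmentation of cells from
  the dark background, per-pixel ORR maps, and per-cell summary tables.
* **Paired statistics.** Donor-level means of both populations compared with
  an exact Wilcoxon signed-rank test (full 2ⁿ sign enumeration at small n) or
  a paired t test; the higher-τ_avg population is called OXPHOS-dominant.
* **Synthetic data.** A ground-truthed generator for photon-count decay cubes,
  two-population scenes, and paired multi-donor experiments, so the whole
  chain is testable without any acquisition hardware or downloads.

## Worked example

```python
from flimmet import compare_experiment, simulate_paired_experiment

table, truth = simulate_paired_experiment(n_donors=7, seed=11)
for metric, res in compare_experiment(table).items():
    print(f"{metric}: oxidative={res.mean_a:.3f}  glycolytic={res.mean_b:.3f}  "
          f"W+={res.statistic:.0f}  p={res.p_value:.6g} (n={res.n_pairs} pairs)")
```

prints

```
tau_avg: oxidative=1.235  glycolytic=0.938  W+=28  p=0.015625 (n=7 pairs)
orr: oxidative=1.531  glycolytic=1.050  W+=28  p=0.015625 (n=7 pairs)
```

All seven within-donor lifetime differences share a sign, so the exact
two-sided Wilcoxon signed-rank p-value is 2/2⁷ = 0.015625: the oxidative
population has the longer mean lifetime (1.235 vs 0.938 ns) and the higher
redox ratio, and is called OXPHOS-dominant. The `examples/` directory holds
one short script per capability (decay model, single-histogram fit, full
scene pipeline, paired comparison), and the `flimmet` CLI exposes
`simulate`, `fit`, `analyze`, `compare` and `pipeline` subcommands for shell
use.

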