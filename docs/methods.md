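# Methods

## Decay model

Each TCSPC histogram is modelled as a background-offset bi-exponential,

    I(t) = α₁·e^(−t/τ₁) + α₂·e^(−t/τ₂) + C,

where τ₁ is the short lifetime of free NAD(P)H, τ₂ the long lifetime of
protein-bound NAD(P)H, α₁/α₂ the component amplitudes and C a constant
background-light level in counts per bin. No instrument-response function is
convolved; consequently the fit starts at the histogram peak, where the
rising edge (which only the IRF can explain) ends. Amplitudes are referenced
to t = 0 by evaluating the model on absolute bin-center times, so excluding
pre-peak bins does not bias the amplitude ratio. Components are canonicalised
to τ₁ ≤ τ₂ after every fit or construction, which makes the free/bound labels
deterministic; fits whose two lifetimes collapse within 10⁻³ ns are reported
as mono-exponential (α₂ = 0) because the split is unidentifiable.

Derived readouts: amplitude-weighted mean lifetime
τ_avg = (α₁τ₁ + α₂τ₂)/(α₁+α₂) (invariant to the amplitudes' common scale, so
normalised or raw amplitudes give the same value), bound fraction
α₂/(α₁+α₂), and optical redox ratio ORR = FAD / NAD(P)H — deliberately the
plain channel ratio, not the FAD/(FAD+NADH) normalisation used by some other
groups. A higher τ_avg (or ORR) indicates dominance of oxidative
phosphorylation; a lower one indicates preferential glycolysis.

All lifetimes are in nanoseconds. The default time axis derives from an
80 MHz pulsed laser: 256 bins spanning the 12.5 ns repetition period
(≈ 48.8 ps per bin). Incomplete-decay wrap-around across laser periods is not
modelled; with τ₂ ≤ ~3 ns and a 12.5 ns period the residual signal at the
period end is ≲ 1.5 % of the peak, which the background term absorbs.

## Fitting and quality control

The default objective is Neyman-weighted least squares — residuals weighted
by 1/max(count, 1) — whose minimised value is the classical photon-counting
χ² statistic; this matches the reduced-χ² quality rule. A Poisson
maximum-likelihood objective (analytic gradient, L-BFGS-B on rescaled
coordinates) is available for very low counts, where Neyman weights are
known to bias amplitudes. Both run from a deterministic heuristic start:
background from pre-peak bins, τ₂ from a log-linear fit to the last 30 % of
the tail, τ₁ = 0.4 ns, amplitudes split 50/50 from the peak height. Bounds:
τ ∈ [0.01, 10] ns, α ≥ 0, C ≥ 0.

Goodness of fit is the reduced χ²: Σ(obs−model)²/max(obs, 1) over the fitted
bins, divided by (fitted bins − free parameters), with all five parameters
(α₁, τ₁, α₂, τ₂, C) counted free (three for the mono-exponential variant).
The "good fit" rule is strict: reduced χ² < 1.3, a threshold that only makes
sense for the *reduced* statistic (whose null expectation is ≈ 1). Histograms
with fewer than 100 photons are not fitted; per-pixel fitting can optionally
sum a 3×3 neighbourhood for such pixels instead of skipping them.

Two aggregation routes exist. Per-pixel fitting with ROI averaging over
quality-passing pixels preserves intra-cell heterogeneity; fitting one
ROI-aggregated decay per cell pools ~10⁵–10⁶ photons and is far better
conditioned, so it is the default for population summaries. ROIs with fewer
than 10 quality-passing pixels (pixel route) or below the photon floor
(aggregate route) are dropped with a log entry.

## Image pipeline

Cell segmentation is Otsu's threshold on the NAD(P)H intensity projection,
8-connected components, and a 25-pixel minimum area — the simplest scheme
that removes background artefacts; the threshold method is pluggable. A
guard rejects segmentations where the foreground class does not exceed the
background by at least five Poisson standard deviations, which prevents
pure-noise fields from yielding spurious ROIs; the segmentation is
characterised (and tested) for signal-to-background ≥ 10. Per-pixel ORR maps
mark pixels with zero NAD(P)H signal as missing (NaN, never 0). The per-ROI
ORR is the ratio of channel means over the ROI's pixels, which is robust to
near-zero individual pixels; the per-pixel map is emitted alongside. ORR
intensities are not background-subtracted beyond masking.

## Paired statistics

The experimental unit is the donor: cell-level values are averaged per donor
and population, and within-donor differences are tested two-sided. The
default test is the Wilcoxon signed-rank with an exact null — zero
differences dropped, absolute differences mid-ranked, and for n ≤ 20 the
distribution of the positive-rank sum built from all 2ⁿ equiprobable sign
assignments (exact even under ties); larger samples use the tie-corrected
normal approximation. The paired t test is available as the parametric
alternative. At n = 7 the smallest attainable two-sided p is 2/128 =
0.015625, and the test's actual size at nominal 5 % is 6/128 ≈ 4.7 %. The
metabolic call labels the higher-τ_avg population OXPHOS-dominant and the
lower one glycolysis-dominant, with differences below 10⁻⁶ ns indeterminate.
No multiple-testing correction is applied across the two metrics.

## Synthetic data

The generator emulates the study design the analysis assumes: sparse
non-overlapping cell disks on a dark background, two populations, Poisson
photon statistics (multinomial signal over bin-integrated decay
probabilities, plus independent Poisson background per bin), and a paired
multi-donor layout. Defaults — generator choices, not measurements:
oxidative population τ₁ = 0.4 ns, τ₂ = 2.8 ns, bound fraction 0.35,
ORR 1.5; glycolytic τ₁ = 0.4 ns, τ₂ = 2.5 ns, bound fraction 0.20, ORR 1.0;
10⁴ photons per cell pixel and 5 background counts per pixel, balancing
realism against desk-scale runtime. The paired-experiment simulator draws a
donor-specific baseline (SD 0.10 ns across donors), adds a +0.3 ns lifetime
and +0.5 ORR effect for the oxidative population, and scatters 20 cells per
population around the donor means (SD 0.08 ns / 0.15 ORR). The FAD channel
is constructed per cell so the ratio of ROI mean intensities matches the
cell's target ORR in expectation.

All randomness flows from one explicit seed through
`numpy.random.SeedSequence` spawning (separate streams for layout, cell
parameters, and photons), so every artefact is bit-reproducible.

What the generator does *not* emulate: optics (PSF blur, scattering,
detector afterpulsing), the instrument response function, photobleaching,
cell-shape irregularity, and subcellular lifetime structure. Tests passing
on these data therefore validate the estimator and inference chain under
the model's own assumptions — correctly specified decays and clean
segmentation — not robustness to instrument effects on real acquisitions.

## Numerical choices and limitations

* Default test/analysis problem sizes (128×128 or smaller scenes, 10⁴
  photons/pixel, 100–1000 statistical replicates) are chosen so the full
  suite runs in minutes on one CPU; all sizes scale up via the spec objects.
* Degenerate inputs: all-zero histograms, empty masks and blank images
  return explicit empty results or typed errors, never silent zeros.
* Fit non-convergence is reported via flags (`converged`, `quality_pass`),
  not exceptions, so pixel loops survive pathological histograms.
* The Neyman χ² is known to run slightly below 1 in expectation for bins
  with single-digit counts; with the default photon budgets the mean reduced
  χ² of correctly specified fits stays within [0.85, 1.15].
* Cube I/O uses multi-page TIFF with JSON metadata (ImageDescription tag,
  sidecar honoured); vendor TCSPC formats (.sdt/.ptu) are out of scope, as
  are phasor-space analysis, triple-exponential models and FAD lifetime
  fitting.
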