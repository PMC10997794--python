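# Methods

## Measurement model

The pipeline treats a spread nucleus as a set of co-registered 2D
grayscale channels with an isotropic pixel calibration (µm/px), plus
per-nucleus axis traces (polylines flagged synapsed/unsynapsed). It is a
faithful re-implementation of a macro-style focus-quantification
workflow, organized as five stages.

**Focus segmentation.** A difference of Gaussian blurs acts as a
band-pass that suppresses both pixel noise (scales below σ_low) and
diffuse background (scales above σ_high); focus borders are the
connected components of the thresholded filtered image. Defaults are
σ_low = 1.6 px, σ_high = 2·σ_low = 3.2 px, matched to a
diffraction-scale PSF of ≈0.16 µm at 0.1 µm/px. These values are
artifact choices — focus-calling thresholds in practice are calibrated
empirically per staining set, which is why the threshold is an explicit
parameter: by default `median + k·MAD` of the filtered image with k = 6
(robust to the sparse bright foci), or an absolute value for fixed-gain
acquisitions. Components use 4-connectivity (more conservative splitting
of adjacent puncta; 8-connectivity available), area limits [4, 10000] px,
and deterministic ids in raster order of each component's top-most,
left-most pixel. There is no watershed splitting: puncta closer than the
resolution merge into one focus by design. Large (PAR-type) clusters are
foci with equivalent diameter strictly greater than 1 µm.

**Co-cluster calling.** The ≥50% area-overlap criterion is evaluated
against the single best-overlapping partner focus (ties to the lower
id), not the union of partners; the union variant exists behind
`union_partners=True` for sensitivity analysis. Overlap is asymmetric by
definition — the denominator is the MEI4 focus area.

**Integrated intensity.** Measured on the original unprocessed image as
the sum over focus pixels minus `area × median(all image pixels)`. The
whole-frame median is used (a per-mask option exists for crowded
frames). Negative values are kept: clamping would destroy the exact
invariance under uniform additive offsets and the linearity under gain
that the tests assert. Note a genuine limitation: a smooth background
*gradient* is only corrected in the mean — per-focus residuals of order
±gradient×area remain, which slightly degrades the linearity of measured
vs true amplitude on gradient-heavy frames. Per-cell summaries use the
standard midpoint median for even n, undefined (NaN) for cells without
co-clusters.

**Axis densities.** Polyline length is the sum of Euclidean inter-vertex
distances times the pixel size. DMC1/RPA2 merging follows the
center-in-signal rule: two foci merge iff the centroid pixel of either
lies inside the other's pixel set (touching without center overlap does
not merge); candidate pairs resolve greedily by descending overlap area
with id tie-breaks, each focus merging at most once — chains are not
formed. Axis association uses nearest point-to-polyline distance with a
0.3 µm default cutoff; the cutoff is an artifact choice, since published
counts of "axis-associated" foci do not state a numeric criterion.
Densities divide class counts by class length; the
unsynapsed-to-synapsed ratio is NaN (never infinite) when the synapsed
density is zero or its length class is empty. The synapsis classifier
uses strictly >70% of total axis length.

**Statistics.** Mann–Whitney U is exact (full enumeration of the
permutation null) when combined n ≤ 12 with no ties, else a tie- and
continuity-corrected normal approximation; the exact-with-ties
enumeration lives only in the test oracle. Fisher's two-sided p sums
hypergeometric probabilities of tables no more probable than the
observed one (the common convention; doubling conventions exist), with
p = 1 and an undefined odds ratio for degenerate margins; the reported
odds ratio is the conditional MLE. The regression F-test is
`F = (slope/SE)²` on (1, n−2) dof, identical to the squared-t two-tailed
test. Nothing applies multiple-testing adjustment. Mixed-model
likelihood-ratio testing of categorical cell classifications is out of
scope; Fisher's exact test is the in-repo alternative for 2×2 tables.
The standard tests are computed via scipy.stats behind this module's
interface; the independent enumeration/closed-form oracles in the test
suite keep that path honest.

## Synthetic data

The simulator generates what the pipeline measures, not microscope
physics: axes are bounded-turning random walks (step 4 px, max turn
0.5 rad) rejected if they exit a circular nucleus mask; whole axes are
flagged synapsed greedily and at most one axis is split so the realized
synapsed length fraction matches the target almost exactly. Puncta are
isotropic Gaussians rendered analytically on ±5σ windows over a constant
background plus a linear gradient of random orientation, with additive
Gaussian noise (optional Poisson shot noise) and clipping at zero.
Co-focus partners share an exact center (configurable jitter) and
correlated amplitudes (shared base × 5% lognormal jitter), reflecting
that one physical cluster drives both channel signals. A minimum
center-to-center separation is enforced by rejection sampling, with a
wider exclusion radius around the rare large foci so dim puncta are not
swallowed by their skirts. Density mode replaces fixed counts with
per-trace Poisson counts at class-specific per-µm rates, each focus
assigned to one of the two channels by a fair coin.

Default conditions (chosen once, as a realistic scaled model of a mouse
spermatocyte spread imaged at 0.1 µm/px): 512×512 px field, 19 axes of
10–18 µm (~270 µm total axis), 120 co-foci + 30 singles per channel +
2 large foci, amplitude 100 ± 10 AU on background 50 AU with gradient
amplitude 10 AU and noise sd 20 AU (nominal SNR 5), PSF σ 1.6 px.
Presets: `seeding_deficient_like` plants 48 co-foci (2.5× fewer, within
the 1.8–3.9× band of reported seeding-defect reductions) at 150 AU
(1.5× brighter); `growth_deficient_like` keeps 120 co-foci at 60 AU and
no large foci; `asynapsis_density_like` plants 0.4/0.2 foci per µm on
unsynapsed/synapsed axes (ratio 2.0) with per-cell synapsed fractions
drawn from U(0.35, 0.85). Amplitude distributions of real foci are not
published; these values were chosen for testability, not photometric
realism. Other things real spreads have that the simulator does not:
chromatin texture, axis-correlated background, anisotropic PSFs,
overlapping nuclei, stage-dependent focus size distributions. Passing
tests therefore demonstrate the correctness of the measurement
operations and estimator recoveries under the stated statistical
structure, not the performance on real microscope data.

All randomness flows from one integer seed; per-cell streams derive from
`SeedSequence([seed, cell_index])`, so cohorts are bit-reproducible and
cells regenerable in isolation.

## Numerical and design choices

- Coordinates are 0-based (row, col); centroids are unweighted pixel
  means (intensity-weighted available via `weighted_centroid`).
- Gaussian filtering uses reflective boundaries; kernels are truncated
  at 4σ (scipy convention), which the impulse-response test accounts
  for.
- Degenerate inputs are explicit: empty foci raise on overlap; zero
  margins give Fisher p = 1; constant x raises for regression; a
  single-vertex trace has length 0; zero synapsed length flags the
  density ratio undefined.
- Validation problem sizes (50-nucleus recovery runs, 30-cell arms,
  200-cell density cohorts, 10⁴ null simulations) were fixed as the
  package's standard validation conditions; the recovery suites use
  amplitudes ≥5× the noise sd and center separations ≥4 detection sigmas
  — the regime in which exact planted-count recovery is a fair demand of
  a thresholding detector without watershed splitting.
- The density-ratio recovery analysis runs the estimator (merging, axis
  assignment, density computation) on planted focus positions directly;
  rendering-and-detection recovery is established separately. This keeps
  the two error sources (detection vs estimation) independently
  attributable.

## Known limitations

- Whole-frame median background correction leaves gradient residuals
  (see above); use the nucleus-mask background option on crowded frames.
- No automatic thresholding: a threshold calibrated on one acquisition
  set does not transfer across gain settings unless expressed in robust
  (MAD) units.
- Merged puncta are not split; counts saturate at high focus densities
  (visible in crowded wild-type-like frames as a few-percent undercount
  when separations fall below ~4σ).
- The simulator's nucleus is a disk and axes do not bundle or pair;
  synapsis is a per-trace flag, not a geometric pairing of two axes.
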