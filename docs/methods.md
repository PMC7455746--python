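# Methods

This note documents the models, defaults and numerical choices behind
vesiquant, and what the synthetic-data tests do and do not demonstrate about
real data.

## Image model and segmentation

An equatorially sectioned giant vesicle is modelled as a ring whose radial
cross-section is Gaussian, `I(d) = A·exp(−(d−r)²/2σ²)` — the profile of a
thin bilayer convolved with a Gaussian point-spread function. The generator
optionally blurs with a Gaussian PSF and adds Poisson shot noise plus
additive Gaussian read noise; no other camera model is attempted. Vesicle
centers are rejection-sampled so rings neither overlap nor approach the
border within `r + 3σ`, because the analysis is only defined for
well-separated, fully visible vesicles.

Segmentation binarizes the membrane channel (Otsu by default; a fixed
threshold is available for reproducibility), flood-fills the dark
background inward from the image border with 4-connectivity, and labels the
remaining enclosed dark components with 8-connectivity as candidate lumina.
The asymmetric connectivity pair prevents the fill from leaking diagonally
through a one-pixel ring. Candidates below `min_area_px` (default 20) or
whose bounding box intersects the border margin (default 2 px) are dropped;
of nested candidates — the appearance of a multilamellar vesicle — only the
outermost is kept, since lamellarity cannot be decided from one channel.

Geometry: area and centroid by pixel counting; perimeter by the Crofton
(intercept-counting) estimate, which is asymptotically unbiased for smooth
shapes; circularity `4πA/P²`; *apparent radius* `P/2π` under a
perfect-circle assumption (a square lumen of side `s` maps to `2s/π`,
documenting the bias of that assumption). The circularity cutoff defaults
to 0.85; it is configuration, not a claim — rasterized discs score ≈1.0 and
2:1 ellipses ≈0.85 under the Crofton perimeter.

**Radius refinement.** The thresholded lumen boundary sits on the *inner*
flank of the membrane ring, at `r − σ·√(2·ln(A/T))` for threshold `T`, so
the lumen-equivalent-area radius `√(A/π)` systematically underestimates the
ring-peak radius by one to two ring widths. Because the radial rays and the
radius-change statistic need the membrane-peak radius, `detect_lumina`
refines `radius_px` to the argmax of the azimuthally averaged radial
membrane profile (64 angles, 0.25 px steps, parabolic sub-sample peak
interpolation). The unrefined equivalent-area radius is retained as
`radius_area_px` and the perimeter-based apparent radius is reported
separately.

## Membrane profiling

The automated readout casts 63 equally spaced rays (starting at 0 rad) from
the centroid to 1.5× the radius, samples by bilinear interpolation at
0.5 px steps, records the per-ray maximum and averages. Rays with any
sample outside the image are dropped and counted in `n_rays_used`; padding
them instead would bias the maxima. Nearest-pixel sampling is available
behind a flag.

The per-ray maximum of an interpolated, discretely sampled Gaussian ridge
undershoots the true peak: the radial grid can straddle the peak by up to a
quarter pixel and bilinear interpolation smooths curvature. The undershoot
is ≈3.5% at a ring sigma of 1.5 px and ≈12% at 0.75 px. Consequently,
absolute intensity recovery is accurate only when the ring cross-section is
sampled by at least ~1.5 px of sigma (finer pixels or wider PSF); at
coarser sampling the statistic remains *proportional* to the true membrane
intensity (bilinear sampling is linear in the image), so enrichment
classification, which compares test and control populations measured
identically, is unaffected. The fidelity tests therefore use well-sampled
rings, and the recovery regression is specified at adequate sampling.

The manual mode extracts a straight cross-section and accepts it only if it
shows exactly two peaks (prominence and minimum-separation thresholds are
explicit configuration; defaults: prominence 3× the robust noise SD of the
profile's context, separation half a radius). Profiles with fewer or more
peaks — background crossings or adjacent vesicles — return a discard
verdict carrying the peak count; a discard is a result, not an error.

## Enrichment statistics

The threshold is `mean + 2·SD` of the negative control, with the sample SD
(n−1) since control groups can be small; classification uses a strict `>`,
so a vesicle exactly at the threshold is not enriched (both choices are
tested and documented). Under a Gaussian null this admits
`P(Z > 2) ≈ 2.28%` false positives, which the Monte-Carlo acceptance test
verifies. The threshold is affine-equivariant: rescaling or offsetting both
populations together leaves the classification unchanged. Welch's t-test,
type-7 (linear-interpolation) quartiles with 1.5×IQR Tukey whiskers, CV and
Pearson correlation follow their standard definitions via scipy/numpy;
per-repeat correlations are summarised as mean ± SD over repeats.

## Kinetics

Each trace is fitted with a four-parameter logistic by bounded least
squares (`scipy.optimize.least_squares`, trf) from 8 deterministic starts on
a grid of 4 midpoints × 2 steepnesses spanning the observation window —
seedless and reproducible. Reported summaries are the maximum slope
`A·k/4` in a.u./min and the plateau time `t₀ + ln(19)/k` (the time the
fitted curve reaches 95% of its amplitude) in hours; these are this
package's explicit operationalisations of "rate" and "plateau time" for a
sigmoidal recruitment curve. A trace is a responder when the fit converged
and `A > 3 × residual RMS`; failed fits return `converged=False` rather
than raising. Both summaries transform exactly under time rescaling and
intensity affine maps, which the tests check.

Apparent-radius change uses `Δr = r(t_last) − r(t_first)` with a
probability-normalized histogram in 0.25 µm bins centered on 0. Vesicles
across time points are linked by mutual-nearest-centroid matching within a
configurable shift tolerance, appropriate for surface-immobilized vesicles.

## MS quantification

Duplicate injections are averaged per (sample, transition) before anything
else. Calibration pools the pre- and post-run dilution series into a single
OLS line with intercept retained (the response is linear, not necessarily
through the origin); drift between blocks is thus averaged, not
interpolated. Back-calculated negative concentrations (sub-blank signal at
trace levels) are clamped to zero and flagged. Isotope bookkeeping counts
one heavy-G3P moiety (+3 heavy carbons) per glycerol backbone and a second
for the PG/PGP headgroup glycerol; nominal reporting uses 1 Da per heavy
carbon, with the exact ¹³C–¹²C increment (1.003355 Da) behind a flag.
Optional blank subtraction for the naturally occurring heavy-isotope
background is off by default. Proteomics-style normalization divides a
peptide's integrated counts by an invariant reference peptide measured in
the same sample.

## Synthetic-data generator: scope and defaults

The generator's role is to produce data with the statistical structure the
analysis assumes, together with exact ground truth. Defaults describe the
study conditions: 0.2 µm/px and 16-bit depth (configuration — acquisition
metadata, not claims), vesicle radii 2–6 µm (apparent diameters 4–12 µm),
ring sigma 0.15 µm with a 0.1 µm PSF, per-vesicle enriched reporter
amplitudes lognormal (long right tail, matching the wide dispersion of
single-vesicle reporter intensities), enriched fraction 0.5; kinetic
cohorts over 16 h sampled every 15 min with lognormal amplitude
(400 ± 150 a.u.), steepness (0.05 ± 0.02 /min) and midpoint
(240 ± 90 min), half non-responders — placing plateau times around 4–6 h
and maximum rates of a few a.u./min; MS tables with slope
1000 counts/µM, intercept 50 counts, six calibration levels emitted in both
a pre and a post block, duplicate injections, and 5% lognormal count CV.

What the generator does **not** emulate: optical sectioning away from the
equator, out-of-focus light and vesicle-to-vesicle background structure,
reporter photobleaching and probe depletion, membrane undulations or
non-circular vesicles, NBD self-quenching, chromatographic peak overlap or
retention-time drift. Passing tests therefore demonstrate that the
*computational* pipeline recovers known truth under its stated assumptions,
not that those assumptions hold for any particular microscope or LC-MS
system.

## Problem sizes and numerical choices

The segmentation recovery test uses 100 vesicles across ten 512×512 fields
(peak SNR ≈ 40); brute-force flood-fill equivalence is checked on random
images up to 64×64, where exhaustive BFS is cheap. The null-classification
Monte Carlo uses 10⁵ draws; kinetic recovery uses 50 traces at 5% noise;
MS recovery uses 100 species-samples at 5% CV. These sizes make each
statistical check's tolerance comfortably larger than its sampling error.
All generators are pure functions of their spec (seed included), the
logistic fitter's multi-start is deterministic, and the pipeline writes
CSVs with pandas' default float formatting, so identical config + seed
gives byte-identical tabular outputs.

## Known limitations

- Radius accuracy relies on a roughly circular, closed ring; strongly
  deformed vesicles fail the circularity filter rather than being measured.
- The per-ray-max statistic is upward-biased by noise (a maximum over ~60
  samples) and downward-biased by under-sampling; at the default SNR the
  two effects are small but not zero.
- The logistic family cannot represent non-monotonic recruitment
  (photobleaching after saturation); such traces fit poorly and show up via
  `residual_rms`.
- Calibration assumes detector linearity across the dilution range;
  saturation at the top level would bias the pooled slope.
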