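# Methods

## Measurement model

A dark-field acquisition of an ex-vivo lens is an 8-bit grey image in
which only scattered light is recorded: background pixels sit near zero,
lens pixels scatter in proportion to local opacity. Two observations are
made per lens, `before` and `after` an intervention, plus a transmission
spectrum T(λ) on 380–780 nm at each timepoint. The two endpoints are

* the dark-field quotient `Q_DFI = Σ p_before / Σ p_after` over a circular
  scoring region containing the lens, and
* the transmission quotient `Q_T(λ) = T_after(λ) / T_before(λ)`.

Both are ratio statistics of paired measurements, so multiplicative
acquisition factors that are stable across the pair (illumination level,
exposure) cancel. Groups are summarized as mean ± SEM with the Bessel
(n−1) correction; SEM is refused for n < 2 rather than reported as 0.
No inferential test between groups is computed; the endpoint of a cohort
run is the set of group means with their SEMs and the resulting ordering.

## Lens detection

Detection runs per image, independently for before and after (no
registration step is assumed between the two acquisitions):

1. **Gaussian low-pass**, reflective borders, default bandwidth σ = 5 px
   at a 1920-px-wide frame and scaled proportionally with frame width
   (`sigma=None`). The smoothed, real-valued grid is used for detection
   only; scoring always reads the raw 8-bit values.
2. **Global threshold.** The default rule applies Otsu's criterion to
   log1p-compressed intensities and maps the threshold back to the linear
   scale (`otsu-log`). On the linear scale, a bright opacity texture adds
   a third histogram mode that drags the Otsu threshold upward and
   shrinks the detected blob in the after-image only — a differential
   error that biases the quotient. The log scale compresses foreground
   structure and keeps the background/lens split stable across the pair
   (on noiseless two-level phantoms both rules are exact; with textured
   phantoms the linear rule leaves a ~1% quotient bias, the log rule
   < 0.15%). Plain `otsu` and `fixed:<v>` remain available.
3. **Largest 8-connected component**, ties broken by the component whose
   lexicographically smallest (row, col) pixel comes first.
4. **Circle fit**: center = pixel centroid; radius = 99th percentile of
   pixel-center distances to the centroid. The percentile rule tracks the
   disc rim while ignoring thin radial structures (cortical spikes) that
   an extreme-distance rule would follow. An algebraic boundary fit would
   be a reasonable alternative; it is not the default because the
   percentile rule degrades more gracefully on ragged thresholded blobs.
5. **Rasterization**: the scoring mask is the fitted circle itself
   (pixel centers within the radius), not the thresholded blob, so
   interior dark (clear) pixels are included in the sums exactly as a
   circular scoring region implies. Masks covering > 95 % of the frame
   are rejected as illumination faults.

Pixel sums are exact integer arithmetic. Saturated pixels (255) are
counted at face value with the saturation fraction logged.

## Near-zero denominators in Q_T

Below the lens's UV cut-on, T_before approaches zero and the ratio is
numerically meaningless. Wavelengths with T_before ≤ a floor (default
0.005, i.e. 0.5 % transmission) are flagged and excluded from group
summaries; per-wavelength effective n is reported alongside the mean and
SEM, and wavelengths with fewer than two unflagged values are flagged in
the summary rather than averaged. Wavelength grids must match exactly
between the two spectra of a pair; no interpolation is performed.
Transmission is stored as a fraction; values slightly above 1 (instrument
blanking) are accepted up to 1.5.

## Synthetic phantoms

The generator emulates the features of real dark-field cohorts that the
pipeline must be robust to, with analytic ground truth:

* **Geometry**: a disc of clear-lens scatter (default 30 counts) on a
  dim background (3 counts), default frame 1920×1080, disc radius 25 % of
  the frame height. The ground-truth mask is the exact disc
  rasterization.
* **Aging drift**: the after-image multiplies the disc by
  `aging_factor ≥ 1`, modelling the brightening every lens shows over the
  experiment even without irradiation.
* **Morphologies**, added to the after-image and scaled by
  `severity ∈ [0, 1]` (peak amplitude 120 counts at severity 1):
  nuclear = centred Gaussian blob (σ = r/3); cortical = 12 radial wedge
  spikes inward from the rim; posterior subcapsular = an off-centre patch
  at 0.5 r toward the posterior pole (+x); Y-sutural = three arms through
  the centre, 120° apart.
* **Noise**: additive Gaussian (then rounding and clipping to [0, 255]);
  vignetting is an optional radial quadratic factor, off by default.
* **Spectra**: a sigmoidal UV cut-on rising to a visible plateau
  (default 0.85 at cut-on 420 nm, slope 15 nm), sampled at 1 nm over
  380–780 nm; the after-spectrum applies either uniform attenuation or a
  blue-weighted profile interpolating linearly from k_blue at 400 nm to
  k_red at 700 nm (clamped outside). Measurement noise is drawn
  independently per timepoint.

Every output is a pure function of its configuration including the seed;
per-lens seeds in cohorts derive deterministically from a master seed.

`expected_qdfi` provides the oracle: with ground-truth sums S_b (base
disc), aging a and texture mass ΔS, the continuous closed form is
`S_b / (a·S_b + ΔS)`. Because images are quantized to 8 bits, the
*noiseless* rendering of a uniform disc rounds to a whole count, so the
quantized noiseless pair (the default oracle) is the right reference for
noiseless pipeline runs, while additive noise dithers the quantization
and makes the continuous form the right reference for noisy runs. The
distinction matters at the ~1 % level when `base_level × aging` lands
mid-way between integers.

### What the phantoms do not model

Ring-light optics, spatially correlated speckle, refractive distortion at
the lens rim, partial lens damage, misalignment between timepoints, and
any biochemical mechanism of opacification. Passing tests therefore show
that the measurement chain is correct and stable under the modelled
perturbations — not that segmentation would be error-free on arbitrary
real acquisitions.

### The `effect-sizes` preset

A demonstration cohort whose group effect sizes match published group
quotients for this experiment type: control 0.82 (aging only, so
a = 1/0.82), UVB 0.78, UVA 0.74, blue 0.69, with severities solved
analytically from the closed form — calibrated to output, not
mechanistic. Morphology assignment per group
(blue→cortical, UVA→nuclear, UVB→posterior subcapsular) follows the kinds
of opacity reported after irradiation and is otherwise a demonstration
choice. Spectral attenuations place UVB between blue and UVA in
transmission loss — reproducing the reported disagreement between the two
measurements' rankings — with the control at a uniform 0.95 aging
quotient (the exact control level is a free parameter, not a reported
value).

## Cohort handling

Manifests list one record per lens with group membership and the four
measurement files; lens ids must be unique, group labels come from the
closed set {UVB311, UVA370, BLUE460, CONTROL}, and non-excluded records
must reference all four files. Excluded lenses (e.g. visible damage after
irradiation) stay in the manifest with a reason and are skipped with a
log line. Per-lens failures during a run (unreadable file, failed
detection) are collected and reported; the run continues and exits with a
partial-failure code.

## Problem sizes and defaults used in validation

Tests and the acceptance script exercise the chain on quarter-resolution
frames (480×270, detection σ = 1.25) with cohorts of 20 lenses per group
at noise sd 2 — the geometry scales linearly and quarter resolution keeps
end-to-end cohort experiments (including a 100-cohort ordering-recovery
estimate) fast enough to run routinely. The bookkeeping check mirrors the
study-sized cohort shape: 24/22/28/80 lenses with two UVB and two blue
exclusions, 154 records total.

## Known limitations

* Single-lens frames only; multiple lenses in one frame would be merged
  or mis-ranked by the largest-component rule.
* The circular scoring region is assumed to contain the whole lens;
  strongly elliptical projections would clip.
* One spectrum per lens per timepoint (single-point measurement); no
  spatial spectral maps.
* 8-bit ingestion: higher-depth input is right-shifted with a warning.
* Histogram "linearization" is implemented as a min–max linear stretch
  (rank-preserving, idempotent); histogram equalization is available
  separately for comparison but is not the default rendering.
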