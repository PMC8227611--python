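# lenscat

Quantification of cataract development in ex-vivo lenses from paired
dark-field images and transmission spectra.

In a dark-field setup only light scattered inside the sample reaches the
camera, so an opacifying lens appears as a brightening disc on a black
background. Given an image pair taken before and after an intervention
(UVB 311 nm, UVA 370 nm, or blue 460 nm irradiation, or plain storage for
controls), `lenscat`:

1. detects the lens as a circular region of interest (Gaussian low-pass →
   Otsu threshold on a log intensity scale → largest connected component →
   robust circle fit);
2. sums the raw 8-bit pixel values inside the circle of each image and
   forms the **dark-field quotient**

   ```
   Q_DFI = Σᵢ pᵢ(before) / Σᵢ pᵢ(after)
   ```

   Scattering structures brighten the after-image, so Q_DFI < 1 signals
   opacification; values near 1 mean little change;
3. forms the per-wavelength **transmission quotient** from plate-reader
   spectra on 380–780 nm

   ```
   Q_T(λ) = T_after(λ) / T_before(λ)
   ```

   with Q_T = 1 meaning no transmission change;
4. aggregates lens cohorts per group as mean ± SEM (sample standard
   deviation with the n−1 denominator, divided by √n);
5. renders diagnostic panels (min–max contrast stretch, false-color LUT,
   red detection circle).

Because raw acquisitions of this kind are rarely public, the package ships
a first-class synthetic phantom generator: bright scattering discs with an
aging brightness drift, four opacity morphologies (nuclear blob, cortical
spikes, posterior subcapsular patch, Y-sutural arms), additive sensor
noise, and paired sigmoidal transmission spectra with uniform or
blue-weighted attenuation. Every phantom carries an analytic ground truth
(disc mask, expected pixel sums, expected quotient), so the whole chain is
verifiable end to end.

It is intended for vision researchers running ex-vivo photic-stress
experiments and for image-analysis developers who need a validated
reference implementation of before/after ratio scoring.

## Worked example

Simulate a calibrated demonstration cohort (20 lenses per group at
480×270 resolution, noise sd 2) and run the full analysis:

```
$ lenscat run --preset effect-sizes --outdir demo --seed 1
scored 80 lenses
Q_DFI ordering (most affected first): BLUE460 < UVA370 < UVB311 < CONTROL
```

`demo/report.md` then contains (output of the run above):

```
| group | n | mean Q_DFI | SEM |
|---|---|---|---|
| UVB311 | 20 | 0.7802 | 0.0001 |
| UVA370 | 20 | 0.7403 | 0.0001 |
| BLUE460 | 20 | 0.6901 | 0.0001 |
| CONTROL | 20 | 0.8203 | 0.0001 |
```

The `effect-sizes` preset calibrates each group's aging factor and opacity
severity so the *expected* quotients are 0.69 / 0.74 / 0.78 / 0.82 for
blue / UVA / UVB / control; the scored means above recover those targets
to ±0.001, i.e. blue light is scored most cataractogenic and the control
group shows only the aging drift (Q_DFI ≈ 0.82). The report also ranks
groups by mean Q_T from the paired spectra, where the preset places UVB
between blue and UVA by design.

Other entry points: `lenscat simulate` (write a cohort to disk),
`lenscat segment` (single image → circle JSON/overlay), `lenscat score`
(manifest → per-lens TSV + group summary), `lenscat spectra` (manifest →
Q_T curves), `lenscat render` (diagnostic panel), or the library API
(`lenscat.segment_lens`, `lenscat.score_pair`, `lenscat.compute_qt_curve`,
`lenscat.simulate_cohort`, ...).

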