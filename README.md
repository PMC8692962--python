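# cornoct

Automatic segmentation of corneal layer interfaces in anterior-segment
OCT B-scans, and quantification of the epithelial/stromal thickness and
curvature changes induced by overnight orthokeratology (Ortho-K) lens
wear.

Ortho-K lenses reshape the cornea during sleep; the refractive effect is
carried mainly by central thinning of the corneal epithelium (~50 µm
layer) rather than by the stroma. Measuring that requires tracing three
interfaces in each OCT cross-section — the corneal anterior surface, the
faint epithelial posterior surface, and the corneal posterior surface —
and comparing per-eye thickness profiles before and after lens wear.
`cornoct` implements that measurement chain for researchers working with
ultra-high-resolution corneal OCT, plus a synthetic B-scan generator with
known conic ground truth so the whole chain can be validated end to end
without clinical data.

## Method

For a B-scan of one principal meridian (2048 × 1365 px covering
8.93 × 2.00 mm by default):

1. **Apex detection.** The corneal apex is the brightest region of the
   scan (specular reflex). Its centre defines a Cartesian frame with
   x lateral (mm) and z axial, tissue in the −z direction.
2. **Bi-conic exclusion mask.** Pixels outside two aspheric boundaries
   `Z = T + (√(R² − (Q+1)X²) − R)/(Q+1)` (upper: R = 10 mm, Q = −0.2,
   T = 0.01 mm; lower: R = 5 mm, Q = −0.1, T = −0.8 mm) are zeroed,
   removing eyelids, iris and artefacts while leaving the cornea intact.
3. **Prior-guided tracing.** Scheimpflug topography elevation profiles of
   the anterior and posterior surfaces are fitted to 5th-order
   polynomials (RMS gate 2.5 µm) and registered apex-to-apex. Along 129
   evenly spaced depth columns ("Z-lines"), the brightest pixel within
   ±10 µm of the prior is taken as a surface candidate.
4. **Robust quintic fitting.** Candidates are fitted to a 5th-order
   polynomial; points further than 7 µm from the fit are discarded and
   the fit repeated until no outlier remains.
5. **Epithelial posterior surface.** A 4th-order base curve through ≥5
   operator seed points guides the same brightest-pixel search (restricted
   between the seed endpoints and strictly below the anterior fit),
   followed by the same robust quintic fit.
6. **Profiling.** Axial thickness `t(x) = z_upper(x) − z_lower(x)`
   (epithelium, stroma = cornea − epithelium, cornea); horizontal and
   vertical meridian profiles are proportionally harmonized to agree at
   x = 0; zone means over the central (0–2 mm diameter) and paracentral
   (2–5 mm) zones; central radii of curvature
   `ρ = (1 + z′²)^{3/2}/|z″|` at x = 0.
7. **Cohort statistics.** Kolmogorov–Smirnov normality screening, paired
   two-sided t-tests per measure, pointwise change/significance profiles,
   and clinical-style summary tables.

The library follows a model/results pattern:
`CornealSegmentationModel(scan, priors, seeds).fit()` returns a
`SegmentationResult` (fits, diagnostics, `summary()`), and
`PairedCohort(table).fit()` returns a `PairedCohortResult` with the
paired tests and tables.

## Worked example

```python
from dataclasses import replace
from cornoct import CornealSegmentationModel, fit_prior
from cornoct.synthetic import (RenderSpec, half_resolution,
                               make_ground_truth, make_priors_and_seeds,
                               render_bscan)

gt = make_ground_truth()                      # R 7.86 mm, epi 53.6 um, stroma 515.7 um
spec = replace(RenderSpec(calibration=half_resolution()),
               speckle_shape=None, additive_sigma=0.0)
scan, truth = render_bscan(gt, spec)
ant, post, seeds = make_priors_and_seeds(gt, seed=1)
result = CornealSegmentationModel(scan, fit_prior(ant), fit_prior(post),
                                  seeds=seeds).fit()
print(result.summary())
```

prints

```
Corneal OCT segmentation
============================================================
subject: -  visit: -  meridian: horizontal  eye: OD
apex (row, col): (82.0, 512.0)   masked fraction: 50.2%
------------------------------------------------------------
surface                inliers  iters  rms (um)  max|r| (um)
anterior                   128      1      0.37         1.54
posterior                  121      1      0.28         1.46
epithelial-posterior        71      1      0.14         0.30
------------------------------------------------------------
central radius anterior                 7.850 mm
central radius posterior                7.862 mm
central radius epithelial-posterior     7.856 mm
surface ordering (ant > epi > post): OK
```

The three interfaces converge in one outlier-rejection pass each with
sub-micrometre residuals; the anterior central radius (7.85 mm) recovers
the configured 7.86 mm conic, and the central epithelial thickness
(`result.thickness_profile("epithelium")`, zone mean 53.45 µm) recovers
the configured 53.6 µm to within half a micrometre.

A full pre/post study runs from the shell:

```bash
cornoct run --seed 1 --out out/          # simulate 45 subjects, segment, tabulate
cornoct simulate --n 2 --out sim/        # or write scans/priors/seeds to disk
cornoct segment --scan sim/S001_pre_horizontal.tiff \
    --prior-anterior sim/S001_pre_horizontal_anterior.csv \
    --prior-posterior sim/S001_pre_horizontal_posterior.csv \
    --seeds sim/S001_pre_horizontal_seeds.csv --out seg/
cornoct cohort --in out/cohort.csv --out tables/
```

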