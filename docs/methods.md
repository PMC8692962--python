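# Methods

This note documents the measurement model behind `cornoct`, its tunable
parameters, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinate frame and calibration

Each B-scan is a grayscale grid of `depth_px × width_px` pixels covering
`depth_mm × width_mm` (defaults 1365 × 2048 px over 2.00 × 8.93 mm, i.e.
1.47 µm axial and 4.36 µm lateral pitch). All geometry is done in
millimetres with the origin at the detected corneal apex: x runs along
the scanned meridian (positive = nasal for right eyes on horizontal
scans, superior on vertical scans) and z is axial with the eye in the
negative-z direction. Working in apex-centred mm keeps 5th-order
polynomial design matrices well conditioned (|x| ≤ 4.5); pixel indices
appear only at image lookup.

## Apex detection

The apex is the centre of the scan's brightest region — physically, the
near-saturating specular reflex where the beam meets the cornea at
normal incidence. The operator: Gaussian-smooth the image with
σ = 25 µm in both axes, threshold at the 99.5th intensity percentile,
take the largest connected super-threshold component (size ties go to
the component reaching the smaller column index), and use its
pedestal-subtracted intensity-weighted centroid for the apex *column*.
The apex *row* is localised separately as the full-width-at-half-maximum
centroid of the brightest band in the laterally-smoothed-only column at
that position. The split matters: smoothing axially with σ = 25 µm
merges the anterior and epithelial bands (53.6 µm apart) and the
super-threshold blob extends into the stroma below the interface, so a
plain 2-D blob centroid lands ~50–100 µm *inside* the cornea rather
than on the anterior surface — which would corrupt both the exclusion
boundaries and the prior registration that are anchored to the origin.
On rendered fixtures the split operator localises the apex to < 0.5 px
axially and a few pixels laterally even under speckle.

## Exclusion boundaries

Two aspheric curves `Z = T + (√(R² − (Q+1)X²) − R)/(Q+1)` bound the
plausible corneal cross-section; pixels above the upper curve
(R = 10 mm, Q = −0.2, T = +0.01 mm) or below the lower curve (R = 5 mm,
Q = −0.1, T = −0.8 mm) are zeroed. The upper boundary sits 10 µm above
the anterior apex; the lower tolerance (−0.8 mm) clears any
physiological corneal thickness. Columns beyond a boundary's lateral
domain are left unmasked by that boundary. Intersecting boundaries are
a configuration error.

## Surface tracing and robust fitting

Detection runs on 129 evenly spaced Z-lines spanning the full scan
width (one aligned with the origin; the count must be odd, the span is
configurable). The guide for the two outer surfaces is a 5th-order
polynomial fitted to topographer elevation profiles (quality flag at
RMS ≥ 2.5 µm — a warning, not a gate); the anterior prior is translated
apex-to-origin and the *same* translation is applied to the posterior
prior, since both profiles share the topographer's frame and the
posterior search depends on their preserved depth separation.

Per Z-line the candidate is the brightest unmasked pixel within ±10 µm
of the guide, with ties broken toward the guide and then toward the
shallower pixel; its axial position is refined by a parabolic vertex
through the peak pixel and its two axial neighbours, clamped to half a
pixel. Without the refinement the one-sided intensity pedestal at the
outer interfaces (air above the anterior surface, aqueous below the
posterior) biases the raw brightest pixel by ~0.5–1 µm. Z-lines with no
candidate brighter than one 8-bit grey level are flagged invalid, never
interpolated; more than 50 % invalid lines raises a trace failure and
the scan is excluded (the counterpart of dropping unsegmentably blurry
clinical scans).

Candidates are fitted by iterated least squares: fit a quintic, drop
*all* points with residual > 7 µm, repeat until no point is dropped.
Dropping all offenders per round guarantees termination (the point set
strictly shrinks). A floor of 8 inliers keeps the quintic
overdetermined; falling below it is a convergence failure. The
epithelial posterior surface uses a 4th-order base curve through ≥ 5
seed points (endpoints at the visible span limits), restricts
candidates to Z-lines between the seed endpoints and strictly below the
fitted anterior surface, and then runs the same robust quintic fit.

## Thickness, harmonization, zones, radii

Thickness is axial — `t(x) = z_upper(x) − z_lower(x)` at fixed x — not
surface-normal, matching the Z-line geometry; it is evaluated only on
the intersection of the two fits' inlier spans. An optical-to-geometric
refractive-index division is available (default 1.0: no optical-path
correction is applied, and none is assumed in the synthetic renderer).
Stroma is defined as cornea minus epithelium, so cornea = epithelium +
stroma holds by construction (asserted to 0.01 µm).

Horizontal and vertical profiles of the same eye/visit are harmonized
by scaling each profile by `target / own_centre` with the target the
mean of the two x = 0 values; this equalises the centres while
preserving each profile's shape.

Zone summaries are unweighted means/SDs over Z-line positions with
|x| ≤ 1 mm (central, 0–2 mm diameter) and 1 < |x| ≤ 2.5 mm
(paracentral, 2–5 mm diameter). Central-zone cohort reporting pools the
two meridians' positions; paracentral reporting stays per meridian.

The central radius of curvature is the osculating-circle radius
`(1 + z′²)^{3/2}/|z″|` at x = 0 — evaluated on a quintic *refitted to
the inlier points within |x| ≤ 2.5 mm* rather than on the full-width
fit. The full-width quintic's curvature at the apex is systematically
biased by truncation of the conic's x⁶ term (+0.04 mm at
R = 7.86/Q = −0.2, up to +0.38 mm for steep corneas), while the
central-window refit recovers conic radii to well under 0.05 mm across
R ∈ [6, 9] mm, Q ∈ [−0.4, 0.2]. A Kasa least-squares circle fit over
|x| ≤ 1.5 mm is retained as an independent cross-check mode.

## Paired cohort statistics

Each measure (zone mean or central radius, per layer/surface and
meridian) is compared pre vs post with a two-sided paired t-test;
normality of the paired differences is screened with a one-sample
Kolmogorov–Smirnov test against a normal with the sample's own mean and
SD (advisory only — the t-test runs regardless). Percent change is the
mean of per-subject percent changes, not the percent change of means.
Pointwise change profiles report an uncorrected p per lateral position;
positions with fewer than two complete pairs are reported missing.
Degenerate cases are defined explicitly: post identical to pre gives
t = 0, p = 1; identical *nonzero* differences make the t statistic
undefined (the cohort aggregation reports the limit p = 0 with a
warning). Table output prints p < 0.01 as "<0.01".

## Synthetic generator

The generator is the test bed standing in for clinical data. A ground
truth is an anterior conic (R, Q) plus two thickness profiles,
`t(x) = baseline + amplitude·exp(−x²/2w²)` (µm); the epithelial
posterior and corneal posterior surfaces are the anterior sag minus the
accumulated axial thicknesses, consistent with the axial thickness
definition above.

Rendering draws each interface as a Gaussian axial band (σ = 3 µm, the
instrument's axial resolution) over a uniform stromal fill, composited
by **maximum** so the brightness peak of each band sits exactly on the
true surface; additive compositing would shift the detectable peak
~0.5–1 µm toward the one-sided pedestal, a fixture artifact rather
than a property of the method. Band reflectivity ordering is anterior >
posterior > epithelial-posterior, making the epithelial step genuinely
the hardest, and the anterior band carries a narrow saturating specular
reflex at the apex (amplitude 2 × band, σ 0.15 mm) — the image feature
that makes brightest-region apex detection possible on real scans.
Noise is multiplicative gamma speckle (shape k = 4, mean 1) plus
additive Gaussian grey-level noise (σ = 2); all draws derive from
explicit seeds. Topography priors are the true surfaces sampled at
0.25 mm over ±4 mm with 1 µm noise; seeds sit on the true epithelial
posterior surface over ±2.5 mm with ≤ 3 µm jitter.

Cohort simulation (default 45 subjects, 2 meridians × pre/post each)
draws per-subject baselines (epithelium 53.6 ± 4.2 µm, stroma
515.7 ± 28.1 µm, anterior radius 7.86 ± 0.27 mm horizontal /
7.60 ± 0.27 mm vertical, Q = −0.2) and applies a change model per
measure: central epithelial change −12.8 µm (SD 6.0 µm when
stochastic), central stromal change +4.8 µm (SD 16.1), anterior radius
+0.24/+0.34 mm (h/v). A configured thickness change is interpreted as
the induced **central-zone mean** change: the Gaussian bump's peak
amplitude is the configured change divided by the zone-average bump
factor (≈ 0.856 for the 1 mm default width), so the manifest truths
equal the configured changes exactly on the detection grid. The
implied peak thinning (12.8/0.856 ≈ 15 µm at the centre) is the
physiologically expected profile shape for a centre-peaked response.

What the generator does **not** emulate: refraction bending of deeper
surfaces (rendering is geometric, consistent with n_index = 1),
physically accurate OCT speckle statistics, motion artefacts, lens
decentration, or eyelid/iris structures. Passing tests therefore
demonstrate the correctness of the measurement chain on geometrically
faithful, radiometrically simplified images — not robustness to every
clinical artefact.

Two interactions between the truth parameterisation and the method are
worth knowing. First, the geometry is anchored at the anterior surface,
so a post-wear epithelial bump also displaces the epithelial-posterior
and posterior surfaces; a 1 mm-wide bump is below the resolving power of
a full-width quintic, which smears it laterally in the posterior fit —
measured central stromal change consequently overshoots its configured
zone mean by ~1 µm, and the deeper surfaces' central radii change even
when clinically they would not. Second, the measured epithelial change
is unaffected (the anterior and epithelial fits share the bump's
representation error), which is why the change recovery is accurate to
~0.1 µm while absolute zone means carry a ~0.2 µm quintic-truncation
offset.

## Problem sizes and determinism

The validation suite and the acceptance script run cohorts at half
pixel resolution (1024 × 682 over the unchanged 8.93 × 2.00 mm field)
with rendering noise disabled — at that scale a 45-subject,
180-scan cohort segments in well under a minute while every recovery
tolerance is still met; single-scan checks also run at full resolution.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, so cohorts, renders and statistics are
bit-reproducible; overlay PNGs are rasterised directly into arrays so
identical inputs give byte-identical files.

## Known limitations

- Topography-to-OCT registration is apex-to-apex translation only; no
  rotation, scaling, or per-surface refinement.
- Thickness is axial, which slightly overestimates normal thickness
  away from the apex (≈ 2 % at x = 2.5 mm for R = 7.86 mm).
- The 129-line full-width default leaves ~10 % of lines invalid where
  the cornea leaves the field of view or the prior span ends; fits are
  supported on the remaining span.
- No multiple-testing correction on pointwise significance profiles —
  they are descriptive, matching standard practice in this literature.
- Interactive seed selection is modelled as a file/programmatic
  interface; no GUI is provided.
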