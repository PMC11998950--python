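# Methods

This note documents the models, conventions and defaults behind
`tubehct`, in the spirit of a package methods appendix: what is assumed,
what is tunable, and what passing tests do and do not demonstrate.

## The measurement

A centrifuged microhaematocrit tube stacks, bottom to top: sealant plug,
packed red cells, buffy coat, plasma. Hematocrit is measured from an
image of the vertical tube by three horizontal marker rows —

* `lower`: plug-top / red-cell interface,
* `buffy`: red-cell / plasma interface,
* `upper`: plasma top —

as `Hct = 100·(lower − buffy)/(lower − upper)`. Rows are real-valued
(markers are continuous on screen), row 0 is the image top and rows grow
downward, so `lower > upper`. The ratio is invariant to uniform zoom and
translation; quantization happens only at reporting, where values are
rounded to 0.1 percentage points with halves away from zero (so the exact
ratio 56.25 reports as 56.3). One screen pixel of marker movement is
worth `100/total_px` points; the `resolution` helper expresses this for a
phone viewport as `100/(occupancy × viewport_px)` percent per logical
pixel — 0.23 for a 586-px viewport at 75 % occupancy, 0.14 (printed as
0.1-point graduations) for a 932-px viewport. An MHR scale, for
comparison, has 1 % divisions read at best to 0.5 %.

## Camera model and capture gate

The capture gate mirrors the app behaviour: the indicator is green only
when |pitch| < 5° **and** |yaw| < 5°, strictly — exactly 5° fails. Roll
and setback are not gated.

Projection is an undistorted pinhole. World frame: the tube lies in the
z = 0 desk plane along +y (plug end at −y), z up. The camera sits at
(0, −setback, height) — height defaults to 19.5 cm, the tripod-mounted
capture distance — and at the nadir pose looks straight down with image
rows along −y (plasma appears at the image top). Pitch rotates about the
horizontal axis perpendicular to the tube, positive tilting the view
back toward the tube centre (a set-back camera re-centres the tube at
pitch = atan(setback/height)); yaw tilts side-to-side; roll turns the
image, positive tilting the tube's image top to the right. Default
intrinsics put a 75 mm tube at 19.5 cm across 75 % of a 1136-px raster
(focal ≈ 2215 px).

`apparent_hct` projects the three physical interface points and applies
the marker ratio to the projected rows: an analytic prediction of what a
perfect measurement would read at a given pose. At nadir, depth is
constant along the tube and the result equals the true Hct exactly; off
nadir the depth gradient along the tube shears the row spacing and the
ratio acquires a parallax bias of approximately

```
bias ≈ 100 · r(1−r) · L_fill · sin(pitch) / D
```

(r = Hct/100, `L_fill` = plug-top-to-plasma-top column length, D =
camera–tube distance). The bias is linear in the column length and in
sin(pitch), and independent of focal length (ratios cancel). Note the
stated capture triple 33°/10 cm/19.5 cm is over-determined
(atan(10/19.5) ≈ 27°); pitch, setback and height are treated as
independent inputs and never forced to be consistent.

## Synthetic renderer

`render_tube` renders by inverse mapping: every pixel's ray is cast
through the pinhole and intersected with the desk plane, and the hit
point is classified against the tube geometry in physical coordinates.
Zone boundaries in the raster therefore coincide exactly with pinhole
projections of the physical interfaces, and ground-truth marker rows are
recorded at sub-pixel precision from the same projection. Determinism:
byte-identical output for identical (tube, pose, config, seed).

Defaults and their reasoning:

* **Tube**: 75 mm length, 1.1 mm bore, 10 mm plug — standard
  microhaematocrit tube dimensions. **Fill length 25 mm** (plug top to
  plasma top): a short finger-prick column of the kind image-based
  measurement is most useful for (small samples that a mechanical reader
  handles poorly). Because parallax bias is linear in column length,
  this default also controls the angle-bias magnitudes: at 25 mm the
  20°-pitch condition sits near +1.0 points and the 33°/10 cm condition
  near +1.6; a fully filled 50–60 mm column would roughly double both,
  pushing even the 20° condition past the 1.2-point agreement bound.
* **Buffy coat**: 0.5 mm band above the packed cells. The truth `buffy`
  marker sits at the red-cell/plasma interface (top of the packed
  column), not the top of the buffy band.
* **Meniscus**: the red-cell/plasma interface and the plasma top carry a
  parabolic meniscus profile with signed centre-line depth
  `meniscus_depth_mm` (positive = concave, default 0). Truth markers
  record the **maximum excursion** (centre-line extremum) of the curved
  boundary, mirroring the human instruction to mark the meniscus at its
  extremum; the same rule is applied at the plasma top by analogy.
* **Palette**: six flat zone colors (background, glass, plug, red cells,
  buffy, plasma) with a minimum pairwise max-channel separation of 30
  (the default palette's is 45), validated at configuration time.
* **Noise**: i.i.d. Gaussian per channel, clipped, default σ = 2 DN —
  mild sensor noise. Lighting gradients, haemolysis, reflections and
  other photographic artefacts are deliberately not modelled.
* **Auto-framing**: a pitched camera at 19.5 cm would push the tube off
  the default raster; in the lab one simply slides the sample into
  frame. The renderer instead shifts the *virtual principal point* so
  the projected tube midpoint lands at the raster centre — a pure image
  translation that leaves row differences, hence the measured ratio,
  exactly unchanged, keeping the raster path consistent with
  `apparent_hct` to machine precision. The framing additionally carries
  a seeded ±0.5 px sub-pixel dither: a real sensor grid has no fixed
  phase relative to the scene, and without the dither every cohort
  member would share the same boundary quantization error, turning a
  zero-mean rounding error into a systematic one.

## Interface detection

Detection replaces the human for testing. The tube is the largest
connected component of pixels nearer (Chebyshev) to a tube color than to
the background, after a binary opening; its principal axis gives the
in-plane tilt (rejected beyond ±45°, the caller should rotate first).
Rows intersecting the component are classified by nearest palette
centroid on the row-mean color, with rows farther than half the minimum
palette separation from every centroid labelled unknown (confidence =
fraction classified; >50 % unknown is an error). Marker rows are read
from a narrow strip along the tube's centre line — where a curved
meniscus attains its maximum excursion — with single-row label blips
removed by a sliding mode filter. A transition is localized at the
shared pixel edge between the last row of one zone and the first row of
the next (midpoint of any unknown gap), expressed in the same continuous
row coordinate as the renderer's truth (pixel i spans [i, i+1)), which
keeps the estimator within ±0.5 px and unbiased over dithered cohorts.
Degenerate tubes resolve naturally: no red cells → buffy marker equals
lower; no plasma → buffy equals upper.

Detection is deterministic given the image bytes. Real photographs are
supported only best-effort: the palette must be supplied, and nothing
here attempts segmentation under uncontrolled lighting.

## Agreement and reliability statistics

All statistics operate on a long-format trial table (sample × rater ×
method × trial → Hct) validated for key uniqueness and balance.

* **Bland–Altman**: differences x − y; limits of agreement mean ± 1.96 ×
  SD (sample SD, n−1 — used throughout the package). "Good agreement"
  means |mean difference| < 1.2 points: 1.2 % of a typical 45 % Hct is
  ≈ 0.5 points, the smallest difference an MHR scale credibly resolves.
  The wording "mean ± 1.96 of the difference" is read as the standard
  construction, mean ± 1.96 × SD of the differences.
* **ICC**: default form is two-way random-effects, absolute-agreement,
  single-measure (ICC2,1) — absolute agreement is the natural partner of
  Bland–Altman; all six McGraw–Wong forms are selectable. The 95 % CI is
  the standard F-based interval. Computation is delegated to pingouin
  and cross-checked in the tests against an explicit mean-squares
  oracle. Zero total variance yields a flagged undefined ICC rather
  than a number. Intra-rater designs use the repeated trials as
  measurements; inter-rater designs compare raters' trial-mean
  ("definitive") values.
* **Typical error**: SD of between-trial difference scores ÷ √2 (the
  sports-science convention the term comes from), averaged over trial
  pairs when more than two trials exist.
* **RM-ANOVA**: one-way repeated measures with subject blocking, partial
  η² = SS_effect/(SS_effect + SS_error), bands 0.02/0.13/0.26
  (small/medium/large). Sphericity correction (Greenhouse–Geisser) is
  off by default and available behind a flag. Identical conditions give
  η² = F = 0, p = 1 by convention (0/0 otherwise).
* **Paired t + Bonferroni**: adjusted p = min(1, p·m). **Cohen's d** =
  mean difference ÷ pooled SD (pooled even for paired data, by the
  stated definition), bands 0.2/0.5/0.8 on |d|.

## Validity simulation

`run_validity_simulation` renders each of n samples (true Hct uniform on
38–48 %, the healthy range) under four conditions — 0°, 10°, 20° pitch
and 33° pitch with 10 cm setback — measures every image with the
detector (ground-truth fallback on detection failure, recorded
per-measurement), simulates MHR readings as true Hct plus N(0, 0.25)
reader noise quantized to 0.5 points, and runs the ANOVA, post hoc
paired t tests and Bland–Altman of every condition against the nadir
reference. Because the capture protocol centres the tube in the frame,
the 10° and 20° condition poses carry the implied re-centring setback
(height·tan(pitch)); the 33° condition keeps its stated 10 cm. The
default run (20 samples) reproduces the qualitative agreement split:
mean differences vs nadir of roughly +0.5 (10°), +1.0 (20°) and +1.6
(33°/10 cm) points, i.e. good agreement below 20° and poor at the steep
set-back pose. Problem sizes in the test suite (20-tube cohorts, 200 ICC
replicates at 20 × 3) were chosen as the smallest that make the checks
statistically meaningful.

## What the synthetic experiments do and do not show

The renderer emulates geometry faithfully (projection, meniscus,
quantization, sensor noise) but not photometry: flat zone colors, no
lighting gradients, no blur, no glass refraction. Passing the end-to-end
tests therefore demonstrates that the *measurement logic* — ratio
computation, capture gating, parallax behaviour, detection conventions,
statistics — is correct, not that detection would survive real
photographs, which remain the domain of the manual markers. The in-vivo
angle experiment this simulation mirrors showed a larger steep-pose bias
(≈ +4.6 points) and a *smaller* 20° bias than pure parallax predicts;
the discrepancy is expected, since real captures add off-axis and
framing effects no ideal pinhole model reproduces, and the simulation
aims at the qualitative split, not those magnitudes.

## Records and export

Sample records (id, sex pass-through, reported Hct, markers, pose, image
path, timestamp, version) persist in a human-readable JSON-lines store;
loading revalidates the stored Hct against the markers and warns on
disagreement beyond the reporting precision. Export is CSV (or XLSX)
with a fixed column order; export → import → export is byte-stable.
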