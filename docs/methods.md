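# Methods

## Scope and design

The package reproduces a digital-histology validation workflow: four
quantitation algorithms (positive pixel counting, color deconvolution,
nuclear morphometry, a trainable region classifier), the agreement
statistics used to compare them with manual measurement, and a
synthetic-scene generator that stands in for the stained sections. The
generator is first-class code: its scenes carry pixel-level ground truth
and manual-annotation proxies, so every claim the test suite makes is
checked against a known answer rather than against another algorithm.

## Conventions

All rasters are 8-bit RGB, row-major, origin top-left, with a
microns-per-pixel (mpp) calibration; polygons live in pixel coordinates and
are rasterized by a pixel-center half-open rule (a center exactly on the
boundary counts when the interior lies below/right, implemented as a +1e-9
nudge of the sample point). Hue is circular on [0, 1) with red at 0;
saturation is 1 − min/mean (0 for black), intensity the channel mean.
Optical density is −log₁₀(max(I, 1)/255) per channel: base-10, incident
intensity 255, and a 1-count clamp so an opaque pixel maps to ≈2.41 rather
than infinity. One consequence worth stating: these definitions are the
single source of truth for every consumer (the PPC hue gate, the
deconvolution OD space, the classifier's HSI features), so there is no
risk of two modules disagreeing about what "saturation" means.

## Positive pixel counting

A pixel is positive iff the circular hue distance to `hue_center` is at
most `hue_width / 2` and saturation ≥ `saturation_threshold`; intensity
plays no role in the gate and only sub-classes positives into weak
[175, 220), medium [100, 175), strong [0, 100) on the channel-mean scale
(half-open, upper-exclusive, so the classes partition; positives at
intensity ≥ 220 are counted as negative — too bright to be stain). The
defaults (0.1, 0.6, 0.04) are the settings validated for red
micro-hemorrhage on violet tissue. The weak/medium/strong boundaries are
conventional brightfield values exposed in `PPCParams`; total positive
area is insensitive to them by construction.

## Color deconvolution

Stain vectors are unit OD columns; missing columns are completed by
Gram–Schmidt (cross product when two are supplied), so the matrix is
always invertible and a caller may specify only the stain of interest —
e.g. the silver gray (0.24, 0.24, 0.24), which normalizes to
(0.577, 0.577, 0.577). Concentrations are the matrix inverse applied to
each pixel's OD triple. Negative concentrations (noise outside the stain
simplex) are clamped to zero and the clamp fraction and worst magnitude
are reported on the result object; with three near-orthogonal-ish channels
and additive sensor noise, most background pixels clamp by a tiny amount
in the residual channel, so a large clamp *fraction* with a small clamp
*magnitude* is normal, and only the magnitude signals a miscalibrated
matrix. Positivity for %Pos uses a concentration threshold, default 0.05 —
a repository convention (the commercial cutoff is unpublished), exposed in
every API that consumes it. OD × %Pos is exactly the product of the mean
positive concentration and the positive percentage.

The default counterstain vector is derived from the violet background
palette constant. The gray-vs-violet pair is closer in OD direction than a
typical hematoxylin/DAB pair, which is precisely why deconvolution (not a
hue gate) is the right separator for silver material; the palette was
chosen chromatic enough that the matrix inversion does not amplify sensor
noise into the silver channel.

## Nuclear morphometry

Pipeline: deconvolve the DAB channel → Gaussian smoothing with a physical
`averaging_radius_um` (default 1 µm; clamped to 1 px with a warning when
the calibration makes it sub-pixel) → threshold at
`segmentation_intensity_threshold` → distance-transform watershed →
ellipse-moment measurement. The segmentation threshold default is 0.5,
i.e. half the soma DAB concentration of the reference palette: a
half-maximum cut locates the contour where the smoothed edge profile
crosses 50%, which is the true object boundary, so measured areas are
stable under the pre-smoothing radius. A lower cut (e.g. 0.15) sits about
one smoothing-sigma outside the edge and systematically inflates areas —
enough to push sub-40 µm² somata past the 40 µm² filter.

The curvature threshold controls splitting of touching objects. The
commercial parameter's internals are unpublished; here it is realized as
the prominence (h-maxima depth) of distance-transform peaks that survive
as watershed markers, with depth = 0.4 µm per unit of curvature threshold.
Only the direction is treated as contractual — lower thresholds split
more — and the direction is what the tests pin down; the 0.4 µm/unit scale
is a package convention chosen so the validated setting of 2.5 resolves
moderately overlapping somata.

Filtering keeps objects with area ≥ `min_nuclear_size_um2` and elongation
(minor/major axis of the second-moment ellipse) ≥ `min_elongation`. The
validated presets are cortex {40 µm², 0.2, 2.5} for bushy microglia and
peduncle {25 µm², 0.2, 2.5} for the smaller amoeboid cells; the package
treats preset choice as a per-region decision, and the pipeline's
preset-mismatch run exists to demonstrate why. Cell density is
n / (ROI area in mm² × 0.040 mm), the 40 µm vibratome section thickness
applied uniformly.

## Region classifier

The commercial classifier is an evolutionary pipeline-search system whose
internals are unpublished; this package keeps its *contract* — train on
expert-annotated regions, emit dense class maps, report FPR and positive
recognition rate — and replaces the optimizer with a fixed 13-feature bank
(per-channel mean/SD, saturation-weighted circular hue mean, saturation
and intensity means, gradient energy, gray-level entropy, and the fraction
of pixels darker than mean − 1 SD as a granule-load proxy) feeding a
100-tree random forest seeded for determinism. Patches are 32 px with
stride 16 and per-pixel majority vote over covering patches. Training
regions are registered (image content hash + polygon) and `evaluate`
refuses regions that intersect them — the leakage guard is part of the
evaluation contract, not a convenience.

## Agreement statistics

Pearson r uses the standard product-moment form with a two-sided
t-transform p-value at n − 2 df, and refuses zero-variance inputs.
Bland-Altman reports the mean paired difference, its SD (n − 1
denominator), and limits at mean ± 1.96 SD. The difference direction is
fixed as manual − automated and stamped into every report's metadata, so
"the automated method reads low" is always a positive mean difference.
No proportional-bias or repeated-measures extension is provided.

## What the generator emulates — and what it does not

Each scenario encodes the mechanism the corresponding experiment probes:

- **cv_necrosis** — necrotic patches are a thresholded smoothed Gaussian
  field (quantile-thresholded, so the requested area fraction is hit
  almost exactly); necrotic and intact tissue differ in both mean color
  and granule texture, so texture features carry real signal.
- **hemorrhage** — bleeds are clumps of discrete red-cell blobs; the
  manual proxy is one padded convex hull per clump and therefore *must*
  exceed the pixel-exact red area whenever gaps exist. The negative bias
  of automated counting is thus true by construction, which is the point:
  the harness tests whether the pipeline *reports* it, not whether it
  exists. The whole-hemisphere regime draws per-section bleed fractions
  tightly around 0.1354% — with between-section signal variance that small,
  hull-structure noise dominates and whole-frame correlation collapses
  while small annotated fields (bleed loads varied 0.4–3%) stay
  concordant.
- **ihc_microglia** — somata are non-overlapping disks whose radii put
  bushy cells well above the 40 µm² cut (≥ ~1.5× it, so segmentation
  jitter cannot break exact count recovery) and amoeboid cells between
  the 25 and 40 µm² cuts. Bushy process strokes are rendered at a DAB
  intensity below the segmentation threshold: they shape the image, not
  the countable objects.
- **silver** — gray (equal-RGB) deposit dots at density d outside and
  `concentration_factor` × d inside the rostral subregion; the subregion
  is ~4% of the ROI, so a 5× concentration factor yields a subregion
  %Pos several-fold above the whole-ROI value.

Noise is additive per-channel Gaussian, clipped to [0, 255]; every palette
separation margin exceeds the default amplitude (3 counts) several-fold.
Scene defaults are hundreds of pixels per side rather than whole-slide
scale — replication cohorts are sized to run in seconds, which is the
package's choice for a test harness.

Deliberately not modeled: photorealistic tissue texture, vessels and
anatomy, section-thickness and 3-D effects, staining-batch and scanner
color variation, ICC color management, white-matter (Nissl-poor) necrosis,
and microglial process/ramification morphometry. Passing tests therefore
demonstrate algorithmic correctness and the validation design's logic on
idealized material; they do not certify performance on real slides, where
stain variability and morphology are far richer.

## Determinism

Every generator is a pure function of (params, seed); study runs derive
all per-scene seeds from a master seed via `numpy` seed sequences, and
re-running a configuration reproduces `report.json` byte for byte (wall
times go only to the log). The classifier's random forest is seeded and
single-threaded, and trained models serialize/reload to identical
predictions.

## Known limitations

- The vendor's exact HSI saturation formula, positivity cutoff, curvature
  semantics, and classifier internals are unpublished; each is replaced by
  a documented convention, so absolute numbers are not comparable to the
  commercial implementation even where the validated parameter values are
  reused.
- The gray-intensity-to-OD measurement step that produced the
  (0.24, 0.24, 0.24) silver vector is not implemented; OD vectors are
  accepted directly.
- Manual annotation is emulated by closing + convex hulls of truth
  clumps; real annotators are less regular, so proxy-based agreement
  statistics are cleaner than real inter-method data would be.
- `quantify_stain`'s mean OD is a mean of *positive* pixels only; with no
  positives it is 0 by definition, making OD × %Pos continuous at zero.
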