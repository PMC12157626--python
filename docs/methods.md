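# Methods

This note documents the quantification procedures, the synthetic-scene
model used to exercise them, the numerical conventions, and the design
choices made where the recipes left room.  Nothing here states a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The enrichment pipeline

Input: a two-channel image — GFP (construct of interest) and RFP (Zyxin
LIM-region reporter marking strained-actin sites).

**Reference mask** (RFP channel only): background subtraction (sliding
paraboloid, radius 3 px), Gaussian blur (σ = 1 px), Triangle auto-threshold
on a 256-bin histogram, one binary erosion, then removal of connected
components smaller than 30 px (8-connectivity).  The processed image
exists only to define the mask.

**Measurement** (original channels): RFP_i and GFP_i are mean gray values
inside the mask; GFP_o is the mean GFP gray value over the whole image
outside the mask.  The enrichment score is `(GFP_i − GFP_o) / RFP_i`.
Algebraically the score is invariant to a uniform GFP offset, exactly
linear in GFP gain, and zero for spatially uniform GFP; the suite checks
these identities on random images to ≤ 1e-9.

**Normalization**: within each trial, every raw score is divided by the
mean raw score of the designated reference (wild-type) group of that
trial, making the reference group's mean exactly 1 per trial.  The recipe
phrase "scale values to a maximum of 1" is implemented as division by the
reference **mean** — the operative wording is "normalized to the average …
value" — so individual reference images may exceed 1.

**Group comparison**: classical one-way fixed-effects ANOVA
(F = MS_between/MS_within on (k−1, N−k) df) on the normalized scores; the
p-value comes from the F distribution (`scipy.stats.f`).  If every group
is internally constant the result is flagged degenerate rather than
reported as a finite F.  No post-hoc tests are added.

Open points resolved as options: intensity statistics default to means
(`stat="mean"`), with integrated density (`stat="sum"`) available; GFP_o
uses the full mask complement by default, with an optional cytosol-region
restriction (`outside_region=`); the erosion count defaults to 1.
Scores with and without erosion differ (erosion trims the mask rim), but
the ordering of group means across localization levels is unchanged either
way — the suite checks both facts.

## 2. The object-counting pipeline

Each time-lapse frame is processed independently: background subtraction
(sliding paraboloid, radius 3 px), Rényi-entropy auto-threshold, removal
of particles smaller than 10 px, and a count of surviving components.
Per-frame re-thresholding is deliberate (the mask recipe applies "in each
frame"); a fixed-threshold mode exists for sensitivity analysis.  A
constant frame has no defined threshold and yields count 0 with a logged
warning, so fully darkened series terminate cleanly.  Counts are absolute
by default; frame-0 normalization is optional in the summary layer, which
reports per-timepoint mean and sample SD (ddof = 1) per condition.

## 3. Image operators

All operators work on 2-D arrays, row-major, 0-based; all are
deterministic and shape-preserving.

* **Background subtraction** — grayscale opening with a non-flat
  structuring element: a spherical cap of the stated radius (rolling
  ball), or a paraboloid of rotation `z = −d²/(2r)` whose apex curvature
  matches that ball, truncated at twice the radius (sliding paraboloid).
  Erosion treats out-of-image samples as +∞ and dilation as −∞, so the
  envelope never exceeds the image and the residual is ≥ 0.  The reference
  platform's shrink/interpolate accelerations are intentionally omitted:
  exactness over speed at these image sizes.
* **Gaussian blur** — separable convolution, kernel truncated at 4σ and
  renormalized, half-sample symmetric boundary (preserves total
  intensity).  "Radius = 1 px" in the recipe is read as σ = 1 px, the
  parameter the reference platform's filter takes.
* **Auto-thresholds** operate on 256-bin histograms: native bins for
  8-bit images, min–max linear rescale for 16-bit/float (the behaviour of
  the platform the recipes ran on).  Foreground is strictly above the
  threshold bin; ties go to background.  *Triangle*: chord from the
  histogram peak to the farthest occupied tail bin (histogram mirrored
  first if the long tail is on the low side), threshold at the bin
  farthest below the chord, ties to the lowest bin.  *Rényi entropy*:
  three candidates maximize the summed background+foreground Rényi
  entropies at orders α = 0.5, 1 (Shannon/Kapur limit) and 2 — each an
  exact argmax over all bins — combined by the published weighted rule on
  the sorted triple (weights depend on whether candidates agree within 5
  bins); the combination is a convex mixture, so the result always lies
  within the candidate range.  Histograms occupying fewer than two bins
  raise a degenerate-histogram error; callers decide the fallback.
* **Erosion** — removes foreground pixels with ≥ 1 background neighbour in
  the 8-neighbourhood; out-of-image counts as background.
* **Labeling/particle filter** — run-based union-find connected components
  (4- or 8-connectivity; 8 is the default used by both pipelines, matching
  the reference platform), labels numbered in row-major order of first
  appearance.  "Smaller than N px" removes area < N; area = N survives.

## 4. The synthetic scene model

The generator emulates the statistical structure — not the biophysics — of
live two-channel images of dorsal-mesoderm explants:

* **Filaments**: `n_filaments` (default 10) random line segments, length
  0.3–0.6 of the canvas side, Gaussian cross-section with σ = 1.5 px.
  Each carries one contiguous **strain-site** sub-segment covering
  `strain_fraction` (default 0.3) of its length.  Compartment masks cut
  the profiles at 2σ from the centreline, so the strain mask is a subset
  of the filament mask by construction.
* **RFP channel**: diffuse background (20) + dim filament (amplitude 60)
  + bright strain sites (amplitude 400), in pre-noise counts/pixel.
* **GFP channel**: a diffuse cytosolic pool (120 counts/px) of which a
  fraction `enrichment_rho ∈ [0, 1]` relocalizes to the strain sites.  In
  the default budget-conserving mode the total noiseless GFP photon count
  is constant across rho (redistribution, not addition), which lets the
  score's offset-invariance be probed independently of total brightness.
  An additive mode (`conserve_total=False`) instead adds strain signal of
  amplitude `rho · gfp_strain` (default 2000) on a fixed diffuse pool;
  time-lapses use this mode so that structure brightness is a free,
  realistic parameter rather than tied to the cytosol budget.
  Optional round puncta model the anterior-node phenotype.
* **Noise** (applied after compositing, then quantization to 8/16-bit or
  float): per-pixel Poisson photon noise, additive Gaussian read noise
  (σ = 2), and impulse ("hot pixel") noise — a fraction 1.5e-4 of pixels
  replaced by near-saturating outliers (8000 × U(0.5, 1)).  The impulse
  component matters: real 16-bit microscopy frames are anchored by bright
  outliers and structures thousands of counts above a noise bulk that
  occupies only a few of the 256 histogram bins.  Without that anchoring
  the entropy threshold on a structure-free frame can split inside the
  noise bulk and percolating supra-threshold noise mimics objects; with
  it, late drug-treated frames correctly count ~0 (single-pixel impulses
  never survive the ≥ 10 px filter).
* **Time-lapses**: single-channel (GFP) stacks, default 16 frames at
  1 frame/min spanning 0–15 min inclusive.  The strain-associated
  component of frame *t* is scaled by `exp(−t·interval/τ)`; diffuse pool
  and puncta stay constant.  τ = ∞ is the vehicle control.  For noiseless
  stacks the decay law holds to machine precision (checked).
* **Determinism**: a scene is a pure function of its spec; all randomness
  derives from `numpy.random.SeedSequence(seed)` with fixed spawn order
  (geometry first, then per-channel or per-frame noise streams), so
  identical specs give bit-identical images and a time-lapse shares its
  geometry with the single scene of the same seed.

What the generator does **not** model: optical PSF and TIRF vs confocal
sectioning, cell boundaries (the whole frame is cytosol), filament
curvature or crossing statistics, photobleaching, stage drift, and object
motion.  Passing tests therefore demonstrate that the pipelines recover
the designed contrasts under this noise model — not performance on real
explant images, where segmentation-free GFP_o in particular will mix
extracellular background into the outside mean.

## 5. Problem sizes and numerical choices

Synthetic cohorts in the tests and in `scripts/acceptance.py` use 256×256
scenes — large enough for ~10 filaments with > 30-px strain segments and
sub-second per-image processing — with the cohort sizes stated alongside
each check (typically 10 images per group or 10 seeded time-lapses per
condition; explant counts per condition are not something the protocol
fixes, so these are the package's own defaults).  The default canvas for
interactive use is 512×512, 16-bit.

Floating tolerances: the normalization identity is asserted to 1e-12;
score identities to 1e-9; operator-vs-oracle comparisons to 1e-10 (or
exact, for integer/boolean outputs).  Threshold criteria are maximized
exactly over all 256 bins; when two bins tie to the last floating-point
bit the argmax is convention-dependent, so oracle comparisons accept
either bin of an exact tie.  ANOVA with zero within-group variance is
reported as degenerate (F = ∞, or NaN when the group means also agree)
rather than raising.
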