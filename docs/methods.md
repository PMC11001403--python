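# Methods

## The triage problem

Serial crystallography datasets are collections of independent detector
frames, one per X-ray pulse, stored as multi-event HDF5 files.  Frame
quality failures of interest here are *stereotyped*: they affect a fixed
detector region (one panel, one row band, one ASIC) in a consistent way —
e.g. a gain-switching miscalibration that fires whenever the diffuse
water-ring intensity on a panel enters a critical range.  That structure
is what makes a per-frame classifier on raw ROI pixels viable: the
decision boundary is a localized intensity pattern, not diffraction
physics.

## Geometry model

A CrystFEL-style geometry description maps each panel's rectangle in the
raw data slab (`min_fs/max_fs/min_ss/max_ss`, 0-based inclusive) into the
laboratory frame through two direction vectors and a corner position.
Only this key subset is parsed; everything else (photon-unit conversion,
camera length, masks) is irrelevant to triage and ignored with a notice.
Conventions, fixed to avoid off-by-one ROI bugs: raw data space is
`(row=ss, col=fs)`; rectangles are half-open internally; assembly rounds
each pixel's lab position to the nearest canvas cell, treats a
two-pixels-one-cell collision as a validation error, and fills gaps with
NaN so they can never bias a statistic.  Sub-pixel interpolation is
deliberately out of scope — the assembled image exists for orientation,
not measurement.

## ROI profiles and inflection-point auto-labelling

The 1D "vertical" projection is defined along the ROI slab's slow-scan
(row) axis in data space, averaging across fast-scan columns.  The mean
rather than the sum keeps profiles comparable across ROI widths.

A degree-*n* polynomial (default 4, matching the standard workflow) is
fitted by least squares on an abscissa rescaled to [-1, 1] for
conditioning, then converted back to row units.  Inflection points are
the real roots of the analytic second derivative inside `[0, L-1]`,
ascending.  Two numerical guards matter:

* Coefficients whose total contribution over the domain is below
  1e-10 of the profile scale are zeroed before root finding.  Without
  this, fitting a linear profile at order 4 leaves ~1e-16 relative
  residue in the cubic/quartic terms whose "roots" appear as spurious
  in-domain inflections.
* Roots within 1e-9·L of the domain ends are clipped onto the domain
  rather than discarded, so boundary inflections are not lost to
  floating-point jitter.

Auto-labelling uses the *first* (lowest-row) inflection as the frame
signature; when a fit has several inflections the first is the most
stable under the artefact models considered (a band offset moves the
leading curvature change).  Frames with no in-domain inflection are
labelled `skip` and excluded from training.  Signatures are binned at a
fixed width (default L/20, scale-relative); the most populated bin wins,
ties broken toward the lower bin for determinism.  Frames in the winning
bin are good, the rest bad.  The rule presumes a majority-good dataset;
the diagnostics report the dominant fraction and set a warning flag below
0.5 (configurable), because on a majority-bad subset the rule inverts and
the annotations must be reviewed before use.

### The quartic validation family

Inflection recovery under noise is validated on detrended quartics
constructed from their curvature roots: d²p/dx² = 12(x−r1)(x−r2),
integrated twice and with the best-fit line subtracted (which leaves the
inflections untouched but makes the profile's range reflect its curvature
structure, like a ring bump crossing a panel, rather than the raw
quartic's end-point growth).  The family places r1 ∈ [25, 40] and
r2 ∈ [60, 75] on a 101-point profile: inflections straddling the profile
midpoint, at least 20 rows apart and 25 rows from either edge.  The
1-row recovery guarantee under 1%-of-range Gaussian noise is a property
of such *interior* inflections, where the data constrain the curvature on
both sides; roots crowding one domain end are ill-conditioned (the fit
sees the curvature change from one side only) and can move by several
rows at the same noise level.  That boundary sensitivity is a real
limitation of the method, not of the test.

## Classification

Features are the raw, unscaled ROI pixel intensities, row-major flattened
— the declared feature definition of the workflow.  Optional per-feature
standardization (fitted on the training split only) is exposed for the
scale-sensitive families (logistic regression, KNN); trees are
scale-invariant and ignore it.

The split is a seeded uniform permutation with the training side taking
`floor(train_frac · N)` frames; fractions must sum to 1 exactly (the
"100% rule" — renormalizing a typo silently would bias the experiment).
An optional stratified mode splits per class.  Each seeded component
(split, generator) draws from a stream tagged with a component-specific
constant alongside the user seed, so feeding the same integer everywhere
cannot make two components replay the same permutation — without this,
generator class assignment and split order correlate perfectly and the
"random" test set degenerates to one class.

Default hyperparameters, chosen once as the standard textbook settings:
KNN K = 5 (odd avoids binary-vote ties), random forest 100 trees,
decision tree unlimited depth, logistic regression L2 with the default
regularization and up to 1000 lbfgs iterations.  Class encoding is
good = 1 (positive).  Models persist via joblib in a self-describing
payload (format tag, algorithm, hyperparameters, ROI fingerprint, feature
width, seed, training class counts); restoring checks the format tag and
prediction checks width and ROI fingerprint, so a model can never be
applied to pixels from a different region without an error.

## Evaluation metrics

Implemented from the definitions (positive = good): accuracy (TP+TN)/N
and misclassification (FP+FN)/N, complementary by construction;
per-class precision, recall, F1 (harmonic mean) and support; per-class
misclassification = 1 − recall, which is the quantity quoted when a
sorted dataset is audited per actual class (a per-class table's
correct/incorrect columns sum to 100%).  Ratios with zero denominators
are NaN plus an explicit `undefined` flag — a single-class prediction
should look broken, never 100% precise.  Rates are stored in [0, 1] and
formatted as percentages only at rendering.

## Batch sorting

Work is partitioned into contiguous per-file event ranges (default 64
events), classified, and merged in canonical (path, event) order, making
the output invariant to worker count and scheduling.  Execution tiers:
process pool when `workers > 1`, serial otherwise; the tier is logged per
run.  Unreadable files are logged, marked failed in the summary, and do
not abort the run.

## Synthetic data: what it emulates and what it does not

Each frame is a diffuse ring (Gaussian radial profile around the beam
centre, computed through the true panel geometry), `n_spots` Bragg-like
2D Gaussians at uniform positions, and i.i.d. Gaussian pixel noise.  Bad
frames additionally carry the miscalibration artefact on a slow-scan row
band of one panel: an additive offset (default) or a clipping ceiling.
Defaults — 600 frames, 30% bad, two 32×64 panels, ring amplitude 10,
spot amplitude 50, noise σ = 1, artefact offset 5σ on a 12-row band —
describe a clearly-present but pixel-level-noisy artefact on a
majority-good run, the regime the tool is built for.  Bad frames are the
first ⌈frac_bad·n⌉ indices of a seeded shuffle (exact class counts);
HDF5 timestamps are disabled so equal seeds give byte-identical files.

Not emulated: photon counting statistics, detector gain stages and
nonlinearity, real diffraction physics (spot positions obey no lattice),
jet shadows, beam-centre drift.  Passing tests therefore demonstrate
that the pipeline recovers a *localized additive/clipping* class
difference through its full I/O, geometry, labelling and model plumbing
— not that any classifier family will reach a particular accuracy on a
given beam time's artefact.  On real data the families genuinely differ
(KNN on raw high-dimensional pixels is typically the weakest, as its
distance concentrates; the forest is typically strongest), and the test
suite's accuracy bounds (forest ≥ 0.95, all families ≥ 0.80 on the
600-frame default stack) reflect the synthetic regime only.

The profile-fit auto-labelling validation uses a spot-free, low-noise
variant (no spots, σ = 0.02, offset 15, signature bin width 0.2 rows):
inflection signatures are only a usable frame fingerprint when the
profile is dominated by the smooth background, and the strong random
spots of the default stack jitter the fitted curvature frame to frame.
That, too, mirrors practice: profile fitting is the right
pre-classification tool for gross, consistent intensity changes, and
manual annotation remains necessary when it is not.

## Problem sizes

Test-suite and acceptance-script runs use 40–600-frame stacks with
two 32×64 panels (2048-pixel feature vectors) — sizes at which every
stage, including the 100-tree forest, completes in seconds while leaving
all class-separation effects far above sampling noise.

## Known limitations

* Event-list syntax is the `path //event` dialect; paths containing the
  literal substring `//` are not representable.
* The assembled image is nearest-cell; geometries whose rotated panels
  round two pixels onto one cell are rejected rather than resolved.
* No masking support: non-finite pixels are zeroed (and counted in the
  log), which slightly biases features on dead regions.
* The dominance rule labels exactly one histogram bin good; a good
  population straddling a bin boundary needs a wider bin width.
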