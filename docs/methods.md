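# Methods

This note documents the models, parameters and numerical choices behind
`fibrequant`, and what the synthetic validation does and does not demonstrate.

## Pipeline model

The analysis assumes three co-registered 16-bit channels: a membrane mask
(laminin α2) outlining every fibre, a primary sarcolemmal stain (dystrophin)
and a tertiary stain that is either sarcolemmal (α-sarcoglycan,
β-dystroglycan) or sarcoplasmic (f/d myosin). Processing has three stages.

**1. Tissue and artefacts.** Tissue is the smoothed (`sigma` = 2 px),
thresholded mask channel, closed (r = 3), hole-filled, small components
dropped (default minimum 100 µm², kept below the minimum fibre area so an
isolated small fibre still counts), then dilated by 3 px to recover the outer
membrane edge that smoothing pulls inward. A contrast guard (1000 AU between
threshold classes) prevents pure-noise images from yielding spurious tissue.
Artefacts are regions saturated in ≥ 2 channels at ≥ 90 % of full scale
(tissue folds saturate all channels, debris typically two); saturated cores
are dilated by 1 px, and tissue components that are mostly saturated are
excluded outright.

**2. Fibre segmentation.** The laminin band is thresholded by Otsu within
tissue on the raw channel (raw, not smoothed, so the band width is not
inflated). Fibre interiors are the membrane-enclosed laminin-negative pockets
(hole-filling the membrane mask distinguishes them from open inter-fibre
space). Every remaining tissue pixel joins its nearest interior, so each fibre
claims its own membrane band, and a band shared by touching fibres is split
along the equidistant line (the band skeleton). Candidates pass a filter
cascade, each failure logged with a reason: image-border contact (incomplete
rings), area outside [150, 12000] µm² (excludes debris and merged clumps;
small newly-regenerating/atrophic fibres are below the detection design, a
known limitation), solidity < 0.80 (excludes longitudinal/oblique profiles),
mean ring thickness > 5 µm (mask-quality control), and ring-dominant fibres
with no sarcoplasm left. These values are declared defaults, all configurable;
the method's source defines only their purposes, not values.

**3. Per-fibre characterisation.** Each fibre is partitioned into the
laminin-positive ring (or a fixed-width band, configurable) and the remaining
sarcoplasm; the partition tiles the fibre exactly. The ring mid-line is the
iso-contour of the fibre's interior distance transform at half the mean band
depth, traced sub-pixel, lightly smoothed (the raw EDT's discrete shells
otherwise make the contour zig-zag and inflate its length by ~5 %), and its
polyline length is the circumference.

### Positivity and coverage

The per-fibre threshold is `mean + k·sd` of the fibre's sarcoplasm pixels
(default `k` = 3, reported per fibre; at least 25 sarcoplasm pixels or the
fibre is flagged unquantifiable — kept in morphometrics, excluded from
positivity denominators). The statistic is affine-equivariant, so positivity
calls are invariant under any `aI + b` (a > 0) intensity transform. Positive
objects are 8-connected supra-threshold ring components of ≥ 3 px (single-pixel
noise suppression).

Coverage estimators:

* **projection** (default): each object pixel is assigned to its nearest
  mid-line vertex; the covered arc is the circumference minus the largest
  circular gap between assigned vertices, plus one vertex spacing for the
  half-open ends. Gaps below 2.5 vertex spacings are treated as full coverage
  (vertex-projection granularity).
* **literal**: `Σ (border − 2 × radial width) / 2` over objects, divided by
  half the ring's pixel-edge count. Border lengths and the denominator are
  both 4-neighbour pixel-edge counts, so the staircase inflation of digitised
  curves cancels in the ratio; the two radial end segments are measured
  directly as the object's border edges interior to the band.
* **angular sweep** (reference): rays from the fibre centroid binned at about
  four ring pixels per bin (denser binning leaves empty bins and degrades the
  ratio; a bin counts as covered when most of its ring pixels are positive, so
  partially painted end bins average out).

On noise-free synthetic fibres the three agree within 2 percentage points at
every grid coverage when averaged per coverage; individual fibres can differ
by up to ~3 points because the polygonal fibre outline concentrates edge
measure unevenly around the ring.

Classes are 0–25 / 25–50 / 50–75 / 75–100 % with left-closed boundaries;
exactly 25.0 % remains protein negative and `CP > 25 %` defines a positive
fibre. Colocalisation reports raw tertiary means over primary-positive and
primary-negative ring pixels; an empty side is missing (NaN), never zero, so
degenerate 0 %/100 %-coverage fibres cannot bias section aggregates.

### Myosin threshold

The regeneration threshold comes only from negative control sections
(≥ 50 control fibres enforced): by default the 99.5th percentile of per-fibre
sarcoplasm means (robust to outlier control fibres), with `mean + k·sd`
(k = 5) as the alternative. A fibre is positive iff its sarcoplasm mean
strictly exceeds the threshold. The threshold is persisted to JSON so test
sections are classified against an explicit, auditable value.

### Section summaries

Section mean intensity is the unweighted mean of per-fibre ring means (large
fibres do not dominate; a pixel-pooled variant is not provided). All
percentages use quantifiable analysed fibres as denominator; rejected and
unquantifiable counts are reported alongside rather than silently folded in.
Cumulative-frequency tables are emitted at 1-percentile resolution. Records
are sorted by label before aggregation, so summaries are bit-identical under
input permutation and re-runs. Replicate comparison reports min, max, mean and
percent variability `(max − min)/mean × 100` per endpoint.

## Synthetic sections

The generator emulates: packed near-convex polygonal fibres (8–16 vertices,
diameters 25–45 µm, aspect ≤ 1.1, 5 % radial jitter) on a jittered grid at
0.5 µm/px; laminin rings of 1.25–2 µm (≥ 3 px — thinner bands alias against
the EDT shell structure); one contiguous dystrophin arc per fibre subtending a
chosen angular fraction at 30000 AU over an 8000 AU cytoplasmic background
(the membrane background is set equal to the cytoplasmic one, matching the
thresholding assumption); tertiary intensity coupled to primary presence
(24000/12000 AU) or myosin at 4× background in an exact count of fibres;
additive Gaussian noise (default sd 500 AU) clipped to [0, 65535]; and
injected near-saturated fold streaks and debris blobs recorded in the truth.

Truth coverage is the swept angular fraction; fibres are kept near-round so
the angular and arc-length parametrisations agree to well under a point.
Deliberately not modelled: optical PSF, uneven illumination, Poisson photon
noise, longitudinal fibres, real staining heterogeneity within a ring.
Passing validation therefore shows the *algorithmic* chain recovers known
geometry and intensities under noise — not that the defaults are optimal for
any particular scanner or staining protocol.

## Validation problem sizes

The reference experiments (`fibrequant.experiments`, driven by
`scripts/acceptance.py` and the acceptance tests) use: 200-fibre sections over
the coverage grid {0, 0.1, …, 1.0} at noise sd 500 for coverage recovery and
segmentation fidelity; 44 noise-free fibres (four per grid coverage) for
estimator cross-validation; 50-fibre sections with one fold streak for
artefact exclusion; 40 fibres at 50 % coverage for colocalisation; five
100-fibre negative control sections, one 200-fibre 30 %-myosin test section
and one fresh 200-fibre negative section for myosin sensitivity/specificity;
and five 50-fibre replicate sections for the reproducibility harness. These
sizes give binomial standard errors comfortably inside the stated tolerances
while keeping a full validation run under a minute on one CPU.

## Known limitations

* Whole-slide pyramids are out of scope: inputs above a configurable pixel
  bound are rejected with guidance to tile or downsample; there is no tiled
  stitching of label maps.
* Longitudinal fibres are excluded by design (solidity filter), as in the
  underlying assay's intended cross-sectional mounting.
* The literal coverage estimator inherits pixel-edge measure quirks on very
  small fibres (circumference ≲ 100 px).
* Heavily damaged tissue beyond the saturation-based artefact rules will
  contaminate results; the rules target folds and debris, not arbitrary
  artefact taxonomies.
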