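# Methods

This note records the models implemented in `confinetrack`, the
parameter choices that matter, and what the synthetic benchmark does
and does not demonstrate.

## Synthetic movies

**Motion model.**  Channels narrower than the cells confine migration
to an effectively one-dimensional track, so motile cells follow a
persistent random walk along the channel axis: each frame a cell
advances `speed × frame_interval / pixel_size` pixels in its current
direction and reverses with probability `switch_prob`; cross-axis
position is the lane centre plus Gaussian jitter (σ = 0.2 px).
Channel ends and same-lane neighbours act as reflecting walls (the cell
reverses direction rather than truncating its step), so the programmed
speed is preserved exactly in the ground-truth step lengths.  Immotile
cells only jitter; the jitter is deliberate, because a perfectly static
cell is identical to the temporal-median background and therefore
invisible to the segmentation by construction.

**Appearance.**  Cells are dark ellipses (semi-axes 1.3 r along the
channel, min(r, half-width − 0.7 px) across it) on a brighter
background, because the segmentation's black top-hat enhances locally
dark objects; fast uropod-bearing cells carry a small trailing blob.
Channel walls are rendered static and disappear under background
subtraction.  Defaults: background 200, wall contrast 60, cell contrast
80 on an 8-bit scale; additive Gaussian noise with configurable σ.
Pixel calibration defaults to 1 µm/px; every physical quantity flows
through `ChannelGeometry.pixel_size_um`, so nothing depends on that
default.

**Geometries.**  Straight channels: 8 µm wide, 10 µm high lanes,
frames every 10 min.  Constriction channels: 12 µm × 12 µm lanes with
12 µm-long, 4 µm-wide throats, frames every 4 min, four throats 60 µm
apart by default.  Cell radii (3.5 µm straight, 4 µm constriction) are
simulator choices sized to the channels, not measured values.

**Constriction transits.**  Transit delay is an explicit per-cell
behavioural parameter, not a mechanical nucleus model: a cell arriving
at a throat holds at the entrance and emerges on the far side exactly
`delay` frames later, compressed to the throat width while inside, so
the scripted event satisfies `exit − entry = delay`.  After the last
throat, cells bounce between the throat's far side and the channel end
rather than parking — a parked cell would merge into the
temporal-median background and shed ghost detections.  Scripted
ground-truth events are derived from the trajectory by the same
entry/exit rule the detector uses (margin = one cell radius), which is
what makes exact end-to-end recovery a meaningful test of the
segmentation + tracking chain rather than a tautology: the positions
travel through rendering, thresholding and LAP linking before the rule
is applied again.

**What the simulator does not emulate:** phase-contrast halos, focus
drift, cell division and death, shape change beyond the uropod and
throat compression, photobleaching, and mechanical nucleus deformation.
Passing tests show the analysis chain is correct on movies obeying the
stated appearance model; they do not certify performance on real
phase-contrast data.

## Segmentation

Pipeline order is fixed: median filter (disc, r = 2 px) → signed
subtraction of the temporal-median background → mean filter (disc,
r = 2 px) → black top-hat (disc, r = 15 px; must exceed the cell
radius) → Yen threshold on the response rescaled to 8 bits → binary
opening (r = 1) → hole filling → removal of components < 30 px² →
8-connected labelling → unweighted binary centroids (0-based, x =
column).  All sizes are configurable (`SegmentationParams`).

Numerical choices:

* **Background median with an even frame count** returns the lower
  midpoint of the two central order statistics — a pure order
  statistic, integer-preserving, and exactly reproducible by a
  per-pixel sort oracle.
* **Signed residuals.**  The background-subtracted image is not clipped
  at zero; cells are darker than background, so clipping would delete
  them before the top-hat.
* **Background domain.**  `segment_movie` median-filters every frame
  first and takes the temporal median of the filtered stack, so frame
  and background live in the same denoised domain; `compute_background`
  itself is the pure temporal median of whatever stack it is given.
* **Yen threshold** maximizes
  TC(t) = −ln(G1·G2) + 2·ln(P1·(1−P1)) over the 256 bins, ties toward
  the lowest bin, cuts with an empty class excluded.  Class masses are
  accumulated in exact integer arithmetic and divided once, so the
  argmax carries no summation-order error and agrees bin-for-bin with a
  naive exhaustive maximizer.  A single-valued histogram has no
  threshold and is rejected; `segment_frame` maps that case to "no
  detections".
* **Per-frame thresholding** was chosen over per-movie (the original
  workflow leaves this open); it adapts to slow illumination drift at
  the cost of frame-to-frame threshold jitter.

Static cells are absorbed into the temporal median and go undetected;
this is faithful to the method and covered by a dedicated test.

## Tracking

Two Jaqaman-style LAP passes.  Linking costs penalize cross-lane
displacement; the default `anisotropic` cost is
`c = dx² + (1 + w)·dy²` with w = 15.  An alternative `trackmate` mode
implements the TrackMate feature-penalty convention
`p = 3·w·|y_a − y_b|/(y_a + y_b)`, `c = d²(1 + p)²` for users wanting
drop-in parity; neither is asserted to be byte-identical to the
original configuration, whose penalty formula is not published.
Gating always uses the plain Euclidean distance (100 px linking,
150 px gap closing, gaps ≤ 15 frames), which keeps those bounds
interpretable regardless of the penalty.

Every detection may stay unmatched at a birth/death cost
`b = 1.05 × max admissible cost` in the current matrix, so linking is
preferred whenever admissible but never forced.  The assignment is
solved globally (`scipy.optimize.linear_sum_assignment` on the
augmented matrix); on ≥ 200 random instances the total cost equals
exhaustive enumeration.  Among exactly equal-cost optima the solver's
deterministic choice is returned (runs are reproducible; the
lexicographically-smallest guarantee of an enumeration is not
promised).  Gap closing may chain joins (A→B, B→C); observations are
concatenated without interpolation.  Tracks shorter than 5 observations
(configurable) are flagged, never deleted, so the detection partition
is preserved.

## Motility metrics

Step velocity uses consecutive observations including across closed
gaps: `v = ‖Δr‖ · pixel_size / (Δt · frame_interval)`.  Straightness is
**displacement / path length**: the quantity is sometimes described in
the opposite orientation, but reported values in this assay family live
in [0, 1] (0.10–0.34 for lymphoma lines), which fixes the ratio's
direction; tracks with path < 1 px have undefined straightness and are
excluded from straightness statistics only.  Per-condition velocity is
reported both as the mean of per-track means (primary — robust to
track-length imbalance) and as the pooled step mean (secondary).

Group comparisons are declared, never inferred: one-way ANOVA with
Bonferroni-adjusted pairwise t post-tests, exact Mann–Whitney for
groups of ≤ 8 tie-free observations (normal approximation with tie
correction otherwise), or Kruskal–Wallis with Dunn's rank z post-tests
(pooled-rank variance with tie correction, Bonferroni-adjusted).

## Constriction passages

A passage at throat k is a move of the track centroid from beyond
`center_k − length/2 − margin` to beyond `center_k + length/2 + margin`
(or the mirror image); entry is the last frame on the starting side,
exit the first frame on the far side, and the time is frame-quantized.
The margin defaults to one cell radius (4 px at the default
calibration).  Enter-and-retreat attempts produce no event; oscillating
cells produce direction-flagged events but count once per throat
(counts are distinct tracks).  This entry/exit rule is this package's
formalization of a criterion that is applied manually in practice;
"passage complete" is read as the centroid clearing the margin, not the
whole cell outline.

## Proteomics

Sample clustering is UPGMA (unweighted average linkage, Euclidean
distance) via `scipy.cluster.hierarchy.linkage`, validated against a
brute-force UPGMA oracle for up to 7 samples; WPGMA would weight
clusters equally regardless of size and is intentionally not the
default.  Intensities are clustered raw by default with a `log2`
option, since normalized reporter intensities are the conventional
input and the transformation choice is not standardized.  The
motility-protein subset is supplied as a flag column or list file; no
canonical list is bundled.  Fold changes are ratios of group mean
intensities; group mean intensity is the plain arithmetic mean.

The synthetic fixture plants two effects on log-normal base
intensities (median ~10⁸): a lineage signature on 30% of unflagged
proteins separating B-like (cHL, T-cHL) from T-like (ALCL) groups, and
a configurable fold change (default 1.5×) on flagged motility proteins
in T-cHL and both ALCL groups relative to cHL.  Sample-level noise is
multiplicative and uniform within ±5% — "5% noise" read as a bounded
instrument tolerance; with two samples per group this keeps
mean-intensity ratios within ±0.1 of the planted fold for ≥95% of
proteins, which a heavier-tailed noise model at the same nominal level
would not.

## Problem sizes and determinism

The end-to-end benchmark uses 20 cells × 60 frames per velocity
condition (≥ 1000 ground-truth steps, enough for the 2% law-of-large-
numbers check and 15% recovery tolerance), 5-cell movies for
detection/tracking fidelity, 3-cell constriction movies of 90 frames,
1000 histograms / 200 assignment instances / 50 stacks for the oracle
checks, and 1000 null replicates for the type-I calibration.  Every
stochastic stage draws from an explicit seed; identical seeds give
bit-identical movies, tracks and artifacts (the pipeline manifest
records SHA-256 hashes to make this checkable).

## Known limitations

* The simulator's appearance model is far simpler than phase-contrast
  reality; segmentation parameters tuned here are starting points for
  real data, not guarantees.
* Immotile-cell velocity is only observable through jitter; real assays
  would quantify immotile fractions separately.
* No track splitting/merging (cells touching in a lane may swap
  identities in principle; the y-penalty and lane geometry make this
  rare in the simulated regime).
* The per-line velocities and straightness values printed for the real
  cell lines cannot be reproduced here: the raw movies are not
  deposited, so validation is property-based on synthetic data
  throughout.
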