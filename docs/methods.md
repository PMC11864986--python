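# Methods

This note documents the models, estimators and numerical choices behind
`tectomap`, and what the synthetic-data validation does and does not show
about real recordings.

## Coordinate conventions and data model

All spatial analyses operate on labelled 3D point clouds: soma centroids in
right-handed µm coordinates, one (left) hemisphere, with axis x running
anterior→posterior, y mediolateral and z superficial→deep through the
periventricular cell-body layer. A mirroring utility
(`overlap.mirror_hemisphere`) reflects far-hemisphere points across a
mediolateral midline before pooling; synthetic data are generated
one-sided and never need it. Fluorescence is an ROI × time matrix at a
fixed volume rate (5 Hz by default) in arbitrary units; no ΔF/F baseline
estimation, motion correction or segmentation is performed here — inputs
are assumed to be extracted traces.

## Stimulus protocol and regressors

The protocol is a fixed event sequence: grating (20 s), eight circling-dot
presentations (clockwise/anticlockwise × smooth/saltatory, the set of four
shown twice, each lasting one revolution = 2πr/v ≈ 22.6 s for r = 18 mm,
v = 5 mm/s), grating (20 s), a 2 s OFF luminance ramp, a 2 s ON ramp after
a 20 s dark delay, and two looms 60 s apart. All other gaps are the 20 s
inter-trial interval; the protocol opens and closes with one such
baseline interval, giving ≈ 565 s ≈ 10 min in total. The loom expansion
(83 ms) is shorter than one frame at 5 Hz and is rounded up to a single
frame when discretized.

Each of the 8 stimulus classes maps to one regressor column (both gratings
share a column; each dot variant pools its two presentations; both looms
share one): a boxcar over the class's presentation frames convolved
causally with exp(−t/τ). τ defaults to 7 s, the deconvolution constant
appropriate for nuclear-localized GCaMP6s off-kinetics, and is exposed.
The kernel is truncated at 10⁻¹² of its peak; each column is scaled to
unit maximum. The normalization cancels in R² and rescales slopes
uniformly, so it does not affect responder selection or any downstream
statistic computed from z-scaled scores.

## Response scores

Scores are computed per ROI and stimulus as slope × R² from a simple OLS
with intercept of the trace on the regressor, restricted to the stimulus
time window: first onset of the class to last offset plus `window_pad`·τ
(default pad 3, capturing the convolved tail that carries most of the fit
information). The intercept absorbs baseline offsets — without it R² is
corrupted by any DC level. Scores are invariant to adding a constant to
the trace and scale linearly with trace gain; negative slopes (suppressed
ROIs) are retained.

Responders are ROIs strictly above the population 95th percentile of the
score for at least one stimulus. The percentile is computed per stimulus
column; a pooled variant is available (`pooled=True`) since either reading
of "population percentile" is defensible. Scaling is a per-column z-score
against a reference population — by design the *full* recorded population,
not the responders or the labelled subset, so labelled ROIs scored later
remain on the population scale.

## Functional types

F-types are derived in two stages on the 8-dimensional scaled score
vectors of responders:

1. **Exemplars** by affinity propagation: similarity −‖x−y‖², preference =
   median similarity. We run damping 0.7 with a 50-iteration label
   stability window (max 1000 iterations) rather than the common defaults
   (0.5, 15): at damping 0.5 the message passing oscillates indefinitely on
   data containing tight archetype blobs or duplicates, while very high
   damping can freeze labels before messages settle and collapse the
   solution onto a single exemplar. Damping changes only the update
   trajectory, not the fixed point. Non-convergence raises with the
   iteration count rather than returning degenerate centers.
2. **Dendrogram cut**: exemplars with fewer than `min_members` (default
   10) associated ROIs are pruned, their members left unlabelled; the
   survivors are agglomerated with complete linkage on correlation
   distance (1 − Pearson r between exemplar score vectors) and cut into
   exactly k flat clusters. k is a free parameter (default 17; the demo uses k = 5, matching its 5 planted archetypes). Superclusters are a coarser cut (k = 5) of the *same*
   dendrogram, deliberately avoiding any dependence of statistics on a
   stochastic 2-D embedding; UMAP (n_neighbors 25, min_dist 0.7) is
   provided for visualization only.

Separately recorded labelled ROIs take the f-type of their nearest
retained exemplar under the same squared-Euclidean similarity; exact ties
go to the lowest exemplar index.

## Spatial layering

`NND(a→b)` is the mean over type-a cells of the exact 3D Euclidean
distance to the nearest type-b cell (KD-tree search; self excluded on the
diagonal, which is flagged absent for singleton types). Each type's row of
the NND matrix is its spatial-neighbourhood profile; profiles are
clustered with complete linkage on Euclidean distance and cut into
`n_layers` (default 3) layers.

The claim that layering exceeds chance is formalized as a permutation
test. The statistic is the ratio of mean between-layer to mean
within-layer pairwise profile distance at the chosen cut (∞ when every
layer is a singleton — treated as consistent with any null of the same
value, keeping the p-value conservative in degenerate geometries). Type
labels are permuted over fixed coordinates; p = (1 + #{null ≥ obs}) /
(n_perm + 1), so the floor at n_perm = 100 is 0.0099. With labels
independent of position the test holds its nominal level (verified over
200 synthetic repetitions in the acceptance suite).

Marker intensity profiles along an anatomical axis follow the chain
max-project the thin slab → mean over the in-plane dimension → z-score per
specimen → centered simple moving average (window 3, edges truncated) →
mean ± s.e.m. across specimens. A constant region raises (z-score
undefined) rather than returning NaNs.

## Anatomical overlap of t/f-clusters

A t/f-cluster is the set of recorded neurons sharing one t-type and one
f-type; clusters with more than `min_size` (default 10) members enter the
analysis. The overlap of two clusters fits a Gaussian KDE to each soma
cloud — bandwidth 0.75 interpreted as the scalar covariance-scaling factor
of `scipy.stats.gaussian_kde` (kernel covariance = 0.75² × sample
covariance), *not* an absolute µm bandwidth — evaluates both on one grid
(default 50³) covering the joint bounding box padded by 3 effective
bandwidths, normalizes each sampled density to sum 1, and sums the
pointwise minimum. The statistic is symmetric by construction, bounded in
[0, 1], exactly 1 for identical clouds, < 10⁻⁶ for clouds 100 effective
bandwidths apart, and stable to grid refinement (< 0.01 change on
doubling; verified against an independent dense-quadrature oracle).
Degenerate clouds (singular covariance) raise.

The separation test compares, within each group (each t-type, or
symmetrically each f-type), the pairwise overlaps of its subclusters
against a null in which t-type labels of *all* ROIs are permuted globally
and clusters are re-formed (re-forming, rather than permuting within the
fixed cluster structure, matches a whole-dataset label shuffle and lets
cluster sizes vary as they would under the null). Per-group and pooled
two-sided Mann–Whitney U tests are Bonferroni-corrected over (number of
groups + 1). The number of shuffles defaults to 100 (20 in the demo
config) and is exposed.

## Transcriptomic identity from function and position

Trace correlations are plain Pearson coefficients on raw traces; per ROI
the mean correlation to same-type ROIs (self excluded) and to all
other-type ROIs, compared per type with a paired two-sided t-test,
Bonferroni over types. Exactly constant traces are excluded with a
warning.

The SVM comparison trains `SVC(kernel='rbf', C=1, gamma='scale')` on
stratified 90% splits with training rows resampled with replacement to
`upsample_to` per type (default 1000), evaluating raw accuracy on the
held-out 10%; repeated `n_repeats` (default 20) times, once more per
feature set with globally shuffled labels as a negative control. Feature
sets are the scaled 8-D response vectors, the raw 3D positions in µm, and
their concatenation. Positions are deliberately *not* standardized by
default, mirroring the stated procedure; a flag exists because RBF kernels
are scale-sensitive. Stratified splits (rather than fully random ones)
guarantee every type appears in every training fold at small n.
Confusion matrices are row-normalized true-positive rates averaged over
repeats; feature sets and real-vs-shuffled runs are compared by two-sided
Mann–Whitney U on the per-repeat accuracies.

## Centroid ↔ ROI correspondence

Inputs are assumed co-registered into one pixel frame (registration
itself is out of scope). Each centroid seeds a 3×3 in-plane pixel
neighbourhood (3×3×1; a 3×3×3 option exists) on its plane; the fractional
overlap with an ROI is |neighbourhood ∩ ROI pixels| / 9 — the
neighbourhood, not the ROI, is the denominator, which keeps "fractional"
comparable across ROI sizes. Assignment is to the argmax if positive;
exact ties break by smaller distance to the ROI's pixel centroid, then by
lower ROI id; centroids outside the frame are left unassigned with a
warning. ROIs receiving several centroids are flagged.

## Synthetic data: what it emulates, and what it does not

The generator plants every structure the pipeline is supposed to recover:

* **Layered mosaic point clouds** — each t-type occupies one depth slab
  (disjoint intervals along z) and keeps a hard-core minimum same-type
  spacing, realized by dart-throwing with rejection (simple and auditable;
  an explicit error names the offending type when the requested density is
  infeasible). An optional linear density gradient runs along the
  anterior–posterior axis. Defaults: 6 types, 2 per slab, slabs
  (0–20), (25–45), (50–70) µm in a 300 × 200 µm sheet, 6 µm exclusion
  radius — magnitudes chosen to resemble a larval tectal hemisphere.
* **Functional archetypes** — each archetype responds to one primary
  stimulus (amplitude 1) and one secondary (0.4). Traces are baseline
  (1.0) + amplitudes × regressors + white noise (σ = 0.2 by default, i.e.
  SNR 5 against the unit primary response) + Gaussian random-walk drift
  (off by default). The real noise process of nuclear GCaMP imaging is not
  characterized here; these are placeholders for sensitivity sweeps, not
  claims about the data.
* **Coupling** — the archetype of each ROI is drawn from
  P(archetype | t-type, anterior/posterior bin). Factories cover
  type-only, position-only, convex-mixture and "type_position" couplings;
  the last gives every t-type a different preferred archetype at each
  pole, the configuration in which within-type functional subclusters are
  anatomically segregated and the overlap shuffle test has power.

One global seed fans out through `numpy.random.SeedSequence` children per
component, so stages can be regenerated independently and all outputs are
bit-reproducible under a fixed seed.

What passing on synthetic data does **not** show: robustness to
registration error, non-stationary baselines, neuropil contamination,
unbalanced or mislabelled t-types, non-Gaussian soma distributions, or
archetypes that are mixtures rather than points. The generator makes no
attempt to emulate raw frames or scRNA-seq counts.

## Problem sizes and scale choices

The demo configuration runs 1,998 ROIs × 2,827 frames end to end (< 1 min
on one CPU) with 100 layering permutations, 20 overlap shuffles on a 20³
grid, and 10 SVM repeats upsampled to 300 per type. The validation suite
uses 200 repetitions for the layering-null calibration and 100 for the
overlap-test calibration, with 16³ overlap grids and 30 shuffles — sizes
chosen so the discrete permutation p-values still resolve the α = 0.05
decision while the whole suite stays desk-scale. The full-scale
procedure parameters (95th percentile, pruning at 10 members, bandwidth
0.75, k = 17, 20 repeats × 1000 upsampled) remain the package defaults in
`config.py`.

## Known limitations

* Affinity propagation's exemplar count is controlled indirectly by the
  preference; there is no automatic selection of k, by design.
* The KDE overlap depends on the grid only weakly but on the bandwidth
  factor strongly; 0.75 is the reference convention here and comparisons
  should hold it fixed.
* The layering-null statistic is this package's formalization of a
  qualitative claim ("organization disappears when labels are shuffled");
  alternative statistics (e.g. silhouette of the layer cut) would be easy
  to slot in.
* Mann–Whitney tests treat subcluster pairs as exchangeable units;
  overlaps sharing a cluster are not strictly independent, which the
  shuffle-based null mitigates but does not remove.
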