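# tectomap

Multimodal correspondence analysis of neuron types in the larval zebrafish
optic tectum: do transcriptomically defined cell types (t-types) predict a
neuron's visual function (f-type), and how much does anatomical position
add?

The package re-implements, as a tested and reusable pipeline, the analysis
chain that links three descriptions of the same neurons — transcriptomic
label, visually evoked calcium response, and 3D soma position — and ships a
synthetic-data generator with planted structure so every stage can be
validated end to end without the original imaging data.

It is written for systems-neuroscience analysts working with volumetric
two-photon calcium imaging, in situ hybridization (HCR) cell maps, and
registered atlas coordinates.

## What it computes

**Stimulus regressors.** The visual protocol (forward grating, eight
circling-dot presentations, a second grating, OFF/ON luminance ramps, two
looms; 20 s inter-trial intervals, 60 s between looms) is built as an event
timeline, and each of the 8 stimulus classes yields a regressor: a boxcar
over its presentation windows convolved causally with the nuclear GCaMP6s
decay kernel e^(−t/τ), τ = 7 s, scaled to unit maximum.

**Response scores.** For ROI i and stimulus s, the trace is regressed on
regressor s over the stimulus window (OLS with intercept) and

    score(i, s) = β̂ · R²,

β̂ being the slope (equivalent to ΔF/F against a unit-max regressor).
Responders exceed the population 95th percentile for at least one stimulus;
scores are z-scaled against the full population.

**F-types.** Affinity propagation (similarity = −‖x−y‖², median preference)
picks exemplar ROIs in 8-dimensional score space; exemplars with < 10
members are pruned, survivors are agglomerated with complete linkage on
correlation distance (1 − r) and cut into k flat f-types.

**Spatial layering.** For every ordered t-type pair (a, b), the mean 3D
nearest-neighbour distance NND(a→b) is computed exactly; complete-linkage
clustering of NND profiles groups t-types into anatomical layers, and a
label-permutation null (p = (1 + #{null ≥ obs}) / (n_perm + 1)) tests
whether the layering exceeds chance.

**Anatomical overlap.** Neurons sharing one t-type and one f-type form a
t/f-cluster; for two clusters the Gaussian KDE of each soma cloud
(bandwidth factor 0.75 in the covariance-scaling convention of
`scipy.stats.gaussian_kde`) is sampled on a shared 50³ grid, normalized to
sum 1, and

    overlap(P, Q) = Σ_grid min(p, q)  ∈ [0, 1].

Within-type subcluster overlaps are compared against globally t-shuffled
controls by two-sided Mann–Whitney U tests, Bonferroni-corrected.

**Type identity.** Within- vs between-t-type pairwise trace correlations
(paired t-tests, Bonferroni), per-type mean score profiles, and an SVM
comparison (RBF kernel, C = 1, γ = 'scale', stratified 90/10 splits,
training upsampled per type, shuffled-label controls) asking whether
response vectors, 3D positions, or both best predict t-type.

**Correspondence.** HCR centroids are matched to functional ROI masks by
the largest fractional overlap of a 3×3 pixel neighbourhood, with
distance-then-id tie-breaks.

## Worked example

The numbered scripts under `analysis/` run the demo study (6 t-types in 3
depth slabs, ~2,000 ROIs, 5 Hz traces; each t-type prefers different
functional archetypes at the anterior vs posterior pole):

```sh
python analysis/01_simulate.py
python analysis/02_score_responses.py
...
python analysis/07_match_centroids.py
```

Output (abridged):

```
simulated 1998 ROIs over 2827 frames
713 responders (35.7% above the per-stimulus 95th percentile)
13 exemplars from 713 responders; 707 ROIs labelled with 5 f-types
6 t-types grouped into 3 layers (sizes {1: 2, 2: 2, 3: 2})
layering statistic 25.95, permutation p = 0.0099
overall real-vs-shuffled p = 1.93e-06 (Bonferroni 1.35e-05)
response  accuracy 0.355 (shuffled 0.182, p = 0.00018)
position  accuracy 0.522 (shuffled 0.185, p = 0.00018)
combined  accuracy 0.500 (shuffled 0.175, p = 0.00018)
matched 1998 centroids at 0.5 px mask jitter: 99.8% correct, 0 unassigned
```

Reading: the planted depth slabs are recovered exactly and survive the
permutation null (p = 0.0099 is the floor at 100 permutations); real
within-type subcluster overlaps fall below the shuffled controls (the
planted anterior/posterior segregation is detected); position predicts
t-type better than functional responses, and combining the two does not
beat position — with all three classifiers far above their shuffled-label
controls. Tables land in `results/demo/`.

The same chain is available as one command (`tectomap run --seed 0 --config
configs/demo.yaml --out results/demo`), with per-stage subcommands
`simulate`, `score`, `ftype`, `layers`, `overlap`, `classify`, `match`.

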