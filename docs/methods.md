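# Methods

This note records the models, conventions and design choices behind
`olfmap`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the synthetic
data do and do not establish about real recordings.

## Response intensity

A response is the spike count in the half-open window **[0.05, 1.05) s**
relative to stimulus onset, minus the count for the solvent-matched control
stimulus (mineral oil or water, per the odor's solvent) of the same neuron
and trial. The 50-ms offset is the odor's travel delay from the valve to
the antenna. Half-open boundaries make spikes exactly on an edge
unambiguous; the protocol the window imitates does not specify inclusivity.

Negative control-subtracted values are *kept* in the response matrix.
Rectification to zero happens only where a statistic requires non-negative
input: lifetime sparseness, functional-map weighting, and Bray–Curtis
dissimilarities. For multi-neuron classes, averaging first-round counts
before or after control subtraction is algebraically identical (both are
affine), so only one order is implemented.

Aggregation is `first_round` by default (each neuron's first stimulus
round, then the mean over the neurons of a class), matching the rationale
that first presentations are measured under the most comparable adaptation
state; `mean` (all trials per neuron, then neurons) is available.

## Lifetime sparseness

S = (1/(1 − 1/N)) (1 − (Σ r_j/N)² / (Σ r_j²/N)), with negative r_j set to
zero first. S is scale-invariant and bounded in [0, 1]; floating-point
excursions beyond the bounds are clipped. An all-zero rectified vector
makes S a 0/0 and raises an error rather than returning an arbitrary value;
paired OSN/PN comparisons exclude such silent classes and report them.

## Tuning-curve ordering

Curves are displayed center-out: responses ranked descending (ties broken
by odor id, fixed before any stochastic step), rank 1 at position ⌊N/2⌋,
rank 2 immediately right, rank 3 left, alternating outward and spilling to
the other side when one side fills. Only the visual layout is conventional;
sparseness is computed on the unordered vector.

## Odor-space analyses

- **Distances.** Odors are columns of the class × odor matrix. Cosine
  distance ignores amplitude (pattern similarity), Euclidean distance is
  amplitude-sensitive, correlation distance is 1 − Pearson r. A zero-norm
  (cosine) or zero-variance (correlation) vector has no defined angle; its
  distance is set to 1 with a logged warning.
- **Clustering.** Ward linkage is applied to the *given* distance matrix
  via the Lance–Williams recurrence (SciPy's `linkage` on the condensed
  matrix). For non-Euclidean dissimilarities this departs from Ward's
  sum-of-squares derivation but matches the common practice of the
  numerical tools this models itself on. Flat clusters are connected
  components below a cut height — an absolute linkage distance (default
  0.6) or a fraction of the maximum merge height (default 0.7 for
  Euclidean distances, whose scale is data-dependent). A scale-free
  `cut_dendrogram_k` (cut into exactly k clusters) is used to ask whether
  the top of the tree separates known groups.
- **Signature glomeruli.** A glomerulus carries a cluster's pattern if its
  mean response across the cluster's odors is ≥ 30 spikes/s.
- **PCA** is computed by SVD on mean-centered, *unstandardized* data, so
  explained-variance fractions refer to raw response variance; a
  `standardize` flag exists. Items are odors (or pooled time × odor
  observations for trajectories).
- **ANOSIM.** R = (r̄_between − r̄_within)/(M/2) on average-ranked
  distances, M = n(n−1)/2. Given a raw matrix, responses are rectified and
  Bray–Curtis dissimilarities used. p-values use the add-one permutation
  estimator (1 + #{R_perm ≥ R})/(n_perm + 1), which cannot return 0;
  default 10,000 permutations. Sequential-Bonferroni (Holm) correction is
  applied only to pairwise post-hoc comparisons among >2 groups.
- **Matrix correlation.** Pearson r over upper-triangle pairs with a
  parametric t-based p (df = n_pairs − 2). Distance pairs are not
  independent, so the p is indicative; the label-permutation control
  (default 100 runs, mean ± sd) is the robust check. Glomerular anatomical
  distance is the Euclidean distance between atlas centroids — a modeling
  choice, since "anatomical distance" admits several definitions.

## Density and functional maps

Skeleton edges are subdivided into equal pieces of ≤ 0.5 μm and piece
midpoints binned by the floor convention onto an isotropic 1-μm³ grid of
135 × 135 × 105 voxels; region bounding boxes (calyx 55 × 46 × 32 μm, LH
52 × 53 × 43 μm) sit centered in the grid, and each region is analyzed on
its own grid. The histogram is smoothed with a **9 × 9 × 9** normalized
boxcar ("filtered three-dimensionally"; full width 9, with a per-axis
override). Boundaries are zero-padded, so mass within 4 voxels of an edge
is attenuated — the simplest defensible convention; interior mass is
conserved to machine precision. When a class has several sister skeletons,
their unsmoothed histograms are averaged before smoothing (`pick="first"`
mimics single-exemplar use); smoothing before averaging differs only at
boundaries.

A functional map is Σ_c max(r_c, 0) · D_c with no normalization of D_c —
a plain product-sum; per-image max scaling exists for visualization only.
Map similarity uses correlation distances on flattened 3D voxel arrays
(2D projections are available as an alternative flattening). Classes with
responses but no reconstruction are skipped and logged, mirroring the
incomplete coverage typical of reconstruction datasets.

## Temporal analyses

PSTHs are trial-averaged rates in uniform bins (default 100 ms, 50 ms
available) over the recording span [-1, 3] s. The trajectory PCA basis is
fitted once on the pooled (time × odor) × class observations of raw binned
rates — not per time bin and not smoothed — so all odors move through one
shared space. The inter-odor separation time course is the mean pairwise
Euclidean distance between odor rate vectors per bin; its argmax (earliest
bin on ties) is the separation peak. Oscillatory synchrony is out of scope:
it requires simultaneous local-field-potential references that spike-train
data do not contain.

## The synthetic-data generator

The generator defines the study conditions under which all properties are
tested:

- **Panel**: 17 odors, 8 attractive / 9 aversive, dissolved in mineral oil
  except every eighth odor in water (the acids' stand-in), dilution 10⁻³.
- **Tuning model**: one class per glomerulus (default 31), glomeruli and
  odors partitioned into 3 planted groups (attractive odors = group 0,
  aversive split over the rest). Baseline tuning is exponential with mean
  8 spikes/s — most responses weak, a few strong, as in recorded response
  histograms — and within-group responses are multiplied by the gain
  (default 6). These defaults put roughly 12–20% of class–odor pairs above
  50/30 spikes, the sparse-strong-response regime of the recorded system.
- **Spike trains**: inhomogeneous Poisson by thinning against the peak
  rate (exact for piecewise-smooth profiles) over [-1, 3] s; baseline
  5 spikes/s; the stimulus transient starts at 0.05 s, rises as an alpha
  function to a peak at **150 ms**, and decays toward a sustained plateau
  (half the peak shape), normalized so a trial of amplitude A adds A
  expected spikes to the counting window. Sisters (default 3 per class,
  exposed as a parameter since the true per-glomerulus count varies) share
  the class profile up to independent multiplicative trial noise
  (N(1, 0.2), clipped at 0 with a logged warning).
- **Atlas**: centroids in a 100 × 100 × 60 μm box, interpolating between
  uniform placement and placement around planted group centers
  (`spatial_clustering` ∈ [0, 1]) — the "neighboring glomeruli respond
  alike" arrangement.
- **Skeletons**: per class one tree per region, rooted at the region entry
  face, built as biased random walks toward a target locus with branches
  walking to sub-targets drawn around the locus (sd = `spread_sd`), so the
  arbor collapses onto the locus line as spread_sd → 0. LH loci are
  organized by planted group — the attractive group dorsal, the aversive
  groups converging on a common ventral zone, as the valence-segregated
  wiring it emulates — while calyx loci are uniform. Regions are
  axis-aligned boxes in template space; registration of real image stacks
  is out of scope, synthetic data are born registered.

What passing tests on these data establish: the *analysis chain* is
correct and recovers planted structure (group clustering ARI, valence map
segregation, sister reliability, 150-ms separation peak). What they do not
establish: values that depend on the biological population itself —
the exact threshold-fraction percentages, the OSN→PN correlation level and
its shuffle floor, PCA variance fractions, or real LH/calyx map geometry.
Those require the recorded tables and reconstructions as inputs.

## Numerical conventions

- Half-open intervals everywhere (windows, voxels, cuts); floor binning.
- Tie-breaks are deterministic and fixed before any stochastic step
  (smallest label first; earliest bin on timecourse ties).
- Every stochastic stage takes an explicit seed; the pipeline derives
  per-stage sub-seeds by hashing the stage name into the global seed, so
  stages are independently reproducible and below 2³¹.
- Permutation p-values use the add-one estimator; shuffle controls use
  uniform permutations (fixed points allowed — at n ≈ 29 the expected
  single fixed point biases the control negligibly).
- Wilcoxon rank-sum comparisons use the Mann–Whitney implementation:
  exact for small tie-free samples, tie-corrected normal approximation
  otherwise.

## Problem sizes

The default pipeline run simulates 31 classes × 3 sisters × 19 stimuli ×
2 trials and builds maps on the full 135 × 135 × 105 grid (~30 s on one
CPU). The multi-seed recovery studies use 20 seeds at 31 classes with LH
maps on a coarser 34 × 34 × 29 grid of 2-μm voxels — map clustering is
scale-free (correlation distance), so the coarse grid tests the same
property at a fraction of the cost. The ANOSIM null calibration uses 500
replicates of 12 items with 199 permutations each.

## Known limitations

- No biophysics: Poisson spiking with a fixed rate profile; no membrane
  dynamics, adaptation across trials, or lateral inhibition mechanisms —
  the OSN→PN transformation is *described*, not modeled.
- Ward on non-Euclidean distances is a heuristic (documented above).
- Zero-padded smoothing attenuates mass near region boundaries.
- The parametric p in matrix correlation ignores pair dependence.
- Synthetic skeletons are statistical stand-ins, not anatomical
  reconstructions; their density maps have no biological geometry beyond
  the planted locus structure.
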