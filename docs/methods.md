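# Methods

This note records the model, its assumptions, the numerical choices made
where the design was genuinely open, and what the synthetic test-bed does
and does not demonstrate.

## Signal model and similarity

The unit of analysis is a subject's region-by-time matrix: one averaged
BOLD series per atlas region, preprocessed upstream (the package never
filters or detrends).  Pairwise similarity is the cosine dissimilarity
S(i,j) = 1 − cos(x_i, x_j) ∈ [0, 2].  For band-passed, effectively
zero-mean signals this equals 1 − Pearson correlation, so the method is
driven purely by second-order temporal structure.

**Sign convention.**  S is a dissimilarity (0 = identical), while affinity
propagation expects larger-is-more-similar inputs and the neighbourhood
preference is meant to average a region's *most similar* neighbours.  The
package therefore runs message passing on s = −S and evaluates "n largest"
on that scale; raw S is kept for reporting.  Running the update equations
on S directly would make the algorithm group the least-similar regions,
contradicting the construction's intent.  Self-similarity is excluded from
the preference pool: a region is not its own neighbour.

## Affinity propagation

The message updates are the standard responsibility/availability pair with
preferences on the diagonal of the working similarity matrix.  Parameters
that the construction leaves open, and the defaults chosen:

| parameter | default | why |
|---|---|---|
| damping λ | 0.5 | the classic message-damping weight; smaller values oscillate on near-symmetric inputs |
| max_iter | 1000 | hard cap; typical fixtures converge in 50–200 iterations |
| conv_window | 50 | iterations the exemplar set must stay unchanged before stopping |

The off-diagonal availability rule alone never lets exemplars emerge, so
the standard self-availability a(j,j) = Σ_{i′≠j} max(0, r(i′,j)) is used.
Exemplars are {k : r(k,k) + a(k,k) > 0} on damped messages; non-exemplars
join the exemplar with maximal raw similarity, ties broken toward the
lowest region index; exemplars are forced to self-membership.

No numerical jitter is injected: given fixed inputs the run is
bit-reproducible.  The cost is that *exactly* symmetric degenerate inputs
(e.g. two regions with identical signal direction and identical similarity
profiles) have no deterministic tie-break and can oscillate until max_iter;
such inputs are resolved by the fallback (promote the best r+a candidate,
flag non-convergence).  Reference implementations instead add tiny random
noise, which is why exemplar *sets* agree with them on random fixtures but
individual runs on degenerate fixtures may differ.

## Community matrices

Neighbourhood sizes n = 5, 10, 15, 20, 25, 30 (the default grid) each
yield one binary co-clustering matrix; K is their mean, so entries lie on
the 1/L lattice with L = 6.  Small n inflates preferences and produces
many clusters, large n fewer — the cluster count decreasing in n is
asserted as a median trend in the tests.  On fixtures with fewer than 31
regions the grid is clipped to [1, N−1] with duplicates dropped and L
adjusted; K(i,i) := 1 by convention, and all downstream enumeration uses
the strict upper triangle in lexicographic order (N(N−1)/2 edges; 4005 at
N = 90).

## Selection protocol

Each resampling iteration draws a stratified 50/50 split (stratification is
a package choice: unstratified splits can empty a class at small n), and
the difference statistic is computed **from the training half only** — the
non-leaking reading of the protocol; the test half never influences which
edges are selected.  The final reported difference matrix uses all
subjects.  Per-iteration sub-seeds derive deterministically from one master
seed, and subjects are canonically ordered by subject identifier before
splitting, so results are invariant to manifest order.  Frequency ties in
the consistent selector break by higher mean D_abs across the iterations
where the edge appeared, then lexicographically — the construction defines
no tie rule, and determinism is required.  Typical h grids at full
parcellation scale are 350…600 (step 50) for the high-accuracy selector
and 50…1000 (step 50) for the consistent one; when a grid of h values is
given, the pipeline reports per-h accuracy summaries and carries forward
the h with the best mean held-out accuracy.

## Classification

A linear-kernel SVM with C = 1.0, unweighted hinge loss and no feature
standardisation (community values already lie in [0, 1]).  Patients are
the positive class, so sensitivity is the true-positive rate among
patients and specificity the true-negative rate among controls; every
report stores raw confusion counts and derives the rates from them.

## Synthetic test-bed

Subjects are T independent draws of a zero-mean multivariate normal whose
correlation matrix encodes (a) equicorrelated blocks (ρ_within = 0.8,
ρ_between = 0) and (b) planted edges with group-specific correlations,
plus additive white noise (σ = 0.2, shrinking observed correlations by
1/(1+σ²) ≈ 0.96).  The implied matrices are projected to the nearest valid
correlation matrix before sampling; the projection must not move a planted
correlation by more than 0.1, otherwise the settings are rejected as
geometrically infeasible.  This matters in practice: a region can only
join an equicorrelated block *wholesale* — correlating strongly with some
members but not others of a tight block has no valid geometry.

The standard planted benchmark therefore uses three blocks (sizes 6, 7, 7)
plus three initially unattached regions that each join one whole block in
patients (ρ: 0 → 0.8), i.e. exactly 20 planted edges whose co-clustering
probability shifts strongly between groups, with 20 + 20 subjects and
T = 200 time points.  On this benchmark the difference statistic ranks
≥ 90% of planted edges in the top m+5, held-out accuracy averages ≥ 0.9,
and shuffling group labels drives accuracy to chance — the synthetic
analogue of a real two-group separation and its null.

What the generator does *not* emulate: BOLD spectra and autocorrelation,
hemodynamic variability, motion and physiological artifacts, site effects,
and between-subject anatomical variability.  Passing tests demonstrate the
statistical machinery (clustering consistency, selection, classification)
under a correct second-order model, not robustness to realistic fMRI
noise.  Gaussian signals are sufficient for that purpose because every
stage of the method depends on the data only through pairwise correlation.

## Problem sizes used in the test-bed

Unit fixtures use 4–36 regions; the planted benchmark 23 regions and 40
subjects over 10 simulation seeds with 10 resampling iterations each;
reference-agreement checks use 50 random fixtures with N ≤ 40.  These sizes
were chosen as the smallest at which each property is informative and
stable across seeds; the full pipeline runs unchanged at 90-region scale
(the edge-pool and level-count checks exercise it).

## Known limitations

* Convergence of message passing is not guaranteed on adversarially
  symmetric inputs; diagnostics record per-level convergence flags.
* The difference statistic is a mean difference without a significance
  model; no permutation p-values are computed for individual edges.
* The optional 4D-volume extraction path averages voxels within integer
  atlas labels on a shared grid; it does no resampling or registration.
* Hemisphere parsing assumes a `<stem>-L`/`<stem>-R` label convention;
  other conventions require relabelling.
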