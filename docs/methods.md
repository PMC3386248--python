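# Methods

`dynmod` treats a resting-state scan not as one static connectivity matrix
but as a sequence of short-lived modular configurations, and provides the
machinery to estimate, score and compare those configurations. This note
documents the models, the defaults and the reasoning behind the open design
choices.

## Sliding-window signed graphs

A subject is a volumes × regions matrix (default geometry: 68 regions, 100
volumes at TR = 3 s). A window of `L` volumes (odd, so each graph is
centered on a single volume) advances by a stride of 1 volume; within each
window the N × N Pearson correlation matrix is the graph. Windows are
0-based and half-open, `[start, start + L)`, centered at `start + (L-1)/2`;
with `T = 100` and `L = 11` this yields 90 graphs with centers at volumes
5…94. Graphs stay fully connected and signed: no thresholding, no
binarization, no discarding of negative weights. The diagonal is stored as
1 for readability but never enters any strength, modularity or z-score
computation. A region with zero variance inside a window is an error in
strict mode (the default) or gets zero weights with a logged warning in
lenient mode.

No per-window detrending or filtering is applied; preprocessing is an
upstream concern and the windowed Pearson estimate already removes the
window mean.

## Signed modularity Q*

Partition quality on signed weighted graphs is scored with the asymmetric
signed modularity

    Q* = Q+ − (v⁻ / (v⁺ + v⁻)) · Q⁻,
    Q± = (1/v±) Σ_ij (w±_ij − s±_i s±_j / v±) δ(c_i, c_j),

where positive and negative weight magnitudes are handled separately,
`v±` are the total weights of each sign and `s±_i` the node strengths.
Positive within-module weight counts at full strength; negative
within-module weight is penalized, down-weighted by the negative share of
total weight. The sum runs over all node pairs with zero weight on the
diagonal; keeping the diagonal's expected-weight terms `−s_i²/v` makes the
all-in-one partition of an all-positive graph score exactly 0 (the
convention of the standard brain-connectivity implementation). The
alternative strict `i ≠ j` sum differs only by a partition-independent
constant, so optimal partitions are identical under either convention.

Because Q* is linear in the community indicator, it can be written as
`Σ_ij B_ij δ(c_i,c_j)` for a combined modularity matrix `B`; the optimizer
works directly on `B`.

### Optimizer

Louvain-style greedy agglomeration: repeated single-node moves to the
neighboring community with the largest Q* gain (ties broken toward the
lowest community index), followed by graph aggregation, until no move
helps. The node visiting order is randomized per restart; 10 seeded
restarts by default, best partition kept, labels canonicalized so the first
node's module is 1. On all graphs small enough to enumerate every set
partition (N ≤ 8), the optimizer matches the exhaustive global optimum in
≥ 95% of random signed instances — that enumeration is the primary
correctness surface for the optimizer, not any fixed example. The inner
local-move loop is JIT-compiled with numba when available; the fallback is
the identical Python function.

### Null model

The chance baseline preserves the positive and negative weight multisets
exactly and each node's per-sign strength sequence approximately, while
destroying the community structure. On a complete graph the degree
distribution is trivially preserved, so randomization acts on the weights:

1. which node pairs carry positive versus negative weights is drawn at
   random (this is the main source of randomization);
2. within each sign, sorted weight magnitudes are matched to edge slots
   ranked by the sum of the two endpoints' original strengths, with a small
   rank jitter (0.15 sd of the score);
3. `n_passes` refinement passes (default 10, several conflict-free swap
   rounds each) greedily swap weights between edge pairs whenever that
   reduces the squared error between realized and target strengths; swaps
   sharing endpoints within a round are skipped because their gain
   estimates would interact.

On 68-node windowed graphs the resulting Spearman correlation between
original and null strength sequences is ≥ 0.9 per sign; a constant-weight
graph passes through unchanged. Note that on graphs whose strengths are
identical by symmetry (perfectly balanced equal blocks), rank preservation
is ill-posed and the Spearman statistic is uninformative — strength-rank
checks should use fixtures with heterogeneous strengths.

### Within-module degree z-score

For node i with module label c, κ_i is the summed signed weight to other
members of c, standardized within the module with the population
(divide-by-n) standard deviation. Singleton modules and zero-variance
modules get z = 0 rather than NaN. A switch (`weight_mode="positive"`)
restricts κ to positive weights for sensitivity analyses, since published
practice does not pin the convention down; signed is the default.

## Window-length selection and the instantaneous configuration

Short windows are noisy, long windows blur state switches. The selection
rule computes, for each candidate length, the standard deviation of Q*
pooled over every window of every subject, expresses it as the percentage
above the sd at the reference length `floor(T/2)`, and picks the smallest
odd length at or below a 10% excess (the published criterion; the figure
being emulated plots sd, so "variance" is operationalized as sd). If the
crossing lands on an even length the next odd length is taken. Larger
cutoffs never select larger windows.

The "instantaneous" proportion of 2-module configurations is estimated by
ordinary least squares on log10(proportion) versus log10(length) over the
reliable lengths (default: odd 11–49) and evaluating the line at
log10 L = 0, reported as a percentage. This operationalizes "window length
of zero" as L = 1 volume in log space — the only value the log-log line can
be read at — and recovers an exact planted power law `p = c·L^k` to 1e-9.
Zero proportions anywhere in the fit range are an error (log undefined)
rather than silently dropped.

On the simulated cohorts the selection rule tends to pick longer windows
(≈ 35–40 volumes) than the 11 volumes reported for real data: the
simulator's two-state switching keeps Q* dispersion elevated at short
lengths in a different profile than empirical scans. The recovery analyses
therefore run at the fixed 11-volume window, which is the geometry all
published counts refer to.

## Dwell time, co-assignment and meta-modules

The per-window module count gives each subject a dwell-time profile: the
percentage of windows spent in 2-, 3-, …-module configurations (always
summing to 100). Because module labels are arbitrary per window, consensus
across windows is built on the co-assignment matrix — the fraction of
pooled graphs in which two nodes share a label — which is invariant to
label renumbering. Ward agglomerative clustering of the dissimilarity
`1 − frequency` (standard Lance–Williams recursion, no coordinate
embedding) yields the meta-modules; the dendrogram is cut by replaying the
first N−k merges, which returns exactly k clusters even when merges happen
at tied or zero heights (`k = N` then gives the discrete partition). The
alternative reading — clustering raw label vectors after some alignment —
is label-permutation-sensitive and was not implemented.

The packaged node table ships the 68-node atlas metadata (names,
abbreviations, consensus-clustering assignment, and the final 5-module
assignment that additionally respects each node's network of origin, the
two differing on five nodes). The final assignment is metadata, not
recomputed, because the reassignment step was a judgment call about
networks of origin, not an algorithm.

## Sub-network dwell time and group comparison

Under the fixed final 5-module assignment (not each window's detected
partition — a config switch enables the per-window alternative), the
composite z of a 4-node DMN sub-network is the mean within-module degree
z-score of its nodes. A sub-network "strongly contributes" to a window when
its composite is strictly greater than 0; exact zeros do not count. The
percentage of such windows is the sub-network's dwell time. Because
z-scores sum to zero within a module, the four composites cannot all be
positive at once — the measure is intrinsically relative.

Two-group comparison uses the two-sided Wilcoxon rank-sum test: exact
enumeration when the combined sample is ≤ 20 without ties, otherwise the
normal approximation with tie correction and no continuity correction (so
identical samples give p = 1). Quartiles use linear interpolation — stated
because reported IQRs depend on the convention. Proportions are compared
with the 2×2 chi-squared test without continuity correction (configurable).
No multiple-comparison correction is applied across sub-networks, matching
the reporting style being emulated. Subject matching is out of scope; the
pipeline consumes pre-labelled groups.

## The switching-state simulator

The simulator provides ground truth, standing in for non-public scan data.
Its model is deliberately minimal:

* **States** are block-equicorrelated correlation matrices: `rho_in` within
  a community, `rho_out` between, checked for positive semi-definiteness at
  construction. Closed-form expectations and cheap PSD checks motivated
  this choice.
* **Switching** is a first-order Markov chain sampled per volume; dwell is
  induced by self-transition probabilities. Nothing finer is identifiable
  from the emulated data, and abrupt switching is the simplest reading of
  meta-stable brain states. Graded transitions are not supported.
* **Emission**: per volume, a zero-mean multivariate normal draw with the
  active state's correlation, plus white noise, then a symmetric
  moving-average smoother (halfwidth 1 volume) standing in for band-limited
  temporal autocorrelation. No hemodynamic response, spatial structure or
  motion artifacts are modelled.

Defaults, fixed once as the package's study conditions: 68 regions, 100
volumes, TR 3 s; `rho_in = 0.8`, `rho_out = −0.25` (strong within-network
coherence and moderate anticorrelation, as seen after global-signal-style
preprocessing); `noise_sd = 0.25` (noise variance ≈ 6% of signal);
Markov relaxation rate 0.1, giving expected state dwells of roughly 15–30
volumes — meta-stable on the scale of the 11-volume window. Weaker
contrasts (e.g. `rho_in ≈ 0.6`) make the 2- versus 3-module states
genuinely unidentifiable from 11-volume windows even without noise: the
windowed estimation error, amplified by the smoother's autocorrelation,
splits and merges blocks. The defaults are therefore the weakest contrast
at which the planted design is identifiable at all, not a tuned sweet spot.

Two preset state families cover the validation needs: a *recovery* pair (a
2-module and a 3-module super-grouping of the five atlas modules, chosen so
every pair of base modules is separated in at least one state — a
requirement for consensus clustering to recover all five), and a *contrast*
pair (posterior-strong versus anterior-strong DMN states whose planted
occupancy shift reproduces the direction of the patient-versus-control
dwell-time contrast).

What passing the synthetic checks does **not** show: robustness to
hemodynamic variability, motion, graded state transitions, non-block
correlation structure, or any particular empirical effect size. The
simulator validates the estimators' correctness and calibration, not the
neuroscience.

## Problem sizes and numerics

Validation runs use a 20-subject recovery cohort (≈ 1,800 windowed graphs),
25 replicate 8+8-subject contrast cohorts for shift detection, and 400
fast replicates (state sequences only) for type-I calibration — sizes at
which every check completes in minutes on one core. Exact-arithmetic
oracles are held to 1e-12, the power-law recovery to 1e-9, and stochastic
recovery checks to the tolerances stated alongside them (±10 percentage
points of dwell; pair-counting agreement ≥ 0.9; type-I error 0.05 ± 0.03).
All randomness flows through `numpy.random.Generator` seeded explicitly;
identical seeds give bit-identical outputs everywhere, including the
end-to-end pipeline.

## Known limitations

* Tapered windows, wavelet or instantaneous-phase connectivity are not
  implemented.
* The null model's strength matching is approximate by construction; only
  the weight multisets are preserved exactly.
* The simulator's state library is small and block-structured; empirical
  modular variability is richer.
* Cohort-scale published numbers (Q* medians, module-count splits, the
  93.6% intercept, patient-group medians) depend on non-public scan data
  and are emulated only in direction and mechanism, not magnitude.
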