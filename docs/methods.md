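# Methods

This note documents the models, statistics and numerical choices behind
`painmark`, in the spirit of a package reference manual: what each stage
assumes, which knobs matter, and what the synthetic data do and do not
establish about real recordings.

## Data model

A *connectome* is a symmetric, non-negative, zero-diagonal `n × n` matrix
over labelled nodes, each node assigned to one of two regions (S1, VPL in
the default study). A *study* (`ConnectomeSeries`) holds, per recording
step, an ensemble of connectomes sampled inside a narrow window plus one
behavioural scalar. The working assumption, inherited from the study
design, is that the within-window ensemble samples a steady state, so the
ensemble mean of any topological measure is a reliable per-step summary;
per-step standard errors are computed and reported but not propagated into
the interpolation (the mean is treated as exact, which is justified only
when the SE is small relative to between-step variation — the summaries
expose the SEs precisely so a user can check this).

Symmetry is *checked* (tolerance 1e-9), never silently enforced: an
asymmetric matrix signals an upstream bug, not a rounding issue.
Binarization (edge iff weight > threshold) defaults to threshold 0 — any
positive coherence is an edge — because all fourteen measures are defined
on the unweighted graph and no principled nonzero threshold exists without
reference to the coherence estimator; the threshold is an explicit argument
everywhere.

## Topological measures

The nine deterministic measures follow their textbook definitions (see
README for formulas). Conventions for corner cases:

- **Disconnected graphs.** CPL and closeness average over connected pairs /
  within components; efficiency counts disconnected pairs as zero
  contribution. Rationale: ensemble members can transiently disconnect and
  dropping whole matrices would bias the step mean.
- **Clustering** of nodes with degree < 2 is 0 (the formula is 0/0 there).
- **Betweenness** sums over unordered pairs with endpoints excluded and no
  normalization beyond the final 1/n (1/|E| for edges).
- **Radiality** is undefined (explicit missing value, never 0) when the
  diameter is ≤ 1 or infinite.
- **LCP-corr** is undefined with fewer than two links having CN > 1 or with
  zero variance in either array (e.g. complete graphs).

The five stochastic measures and their defaults:

- **Small-worldness σ and ω** compare clustering and path length against
  degree-preserving nulls, averaged over `n_realizations = 10` realizations
  with `swap_multiplier = 10` attempted double-edge swaps per edge. The
  random null preserves connectedness when the input is connected; accepted
  swaps are verified in adaptive windows (1→64) and any window that
  disconnects the graph is rolled back — behaviourally equivalent to
  resampling disconnecting swaps, at a fraction of the cost. The lattice
  null accepts a swap only when it strictly reduces the total *circular*
  band distance `min(|i−j|, n−|i−j|)` of the edge set from the diagonal;
  the circular metric treats the node order as a ring, so a ring lattice is
  already optimal and is left untouched.
- **Power-lawness** fits a discrete power law to the positive degree
  sequence: x_min by Kolmogorov–Smirnov minimization, α by maximum
  likelihood (Hurwitz-zeta normalization, bounded search α ∈ [1.01, 12]),
  goodness-of-fit p by semi-parametric bootstrap (default 1000 replicates;
  tail values sampled by the standard continuous approximation, head values
  resampled from the observed sub-x_min data, each replicate refitted from
  scratch). The power-law hypothesis is accepted at p ≥ 0.1. Degree-0 nodes
  are excluded (x_min ≥ 1).
- **Modularity** returns the best Q found. Graphs with ≤ 8 nodes are solved
  exactly by enumerating all partitions (restricted growth strings); larger
  graphs use seeded greedy agglomeration (merge the pair with the largest
  gain, ties broken at random) followed by single-node-move refinement.
  The exact small-n path exists because greedy agglomeration demonstrably
  misses the optimum on some 8-node graphs, and the package treats
  "best partition" as a contract on small graphs.
- **Structural consistency** removes a random 10% of edges
  (`perturb_fraction = 0.1`), eigendecomposes the remainder, applies the
  first-order eigenvalue correction `Δλ_k = x_kᵀ ΔA x_k`, and scores the
  fraction of removed edges among the top-|ΔE| reconstructed non-observed
  entries; the default averages `n_repeats = 10` perturbations. Degenerate
  eigenvalues are resolved by the decomposition's deterministic ordering.

Nulls, bootstraps and perturbation counts are configurable; the defaults
above are the package's choices where the underlying literature leaves them
open. All stochastic measures are deterministic given a seed; seeds cascade
through `numpy.random.SeedSequence` so per-measure, per-step and per-member
streams are independent.

## Time-course statistics

Recording steps are non-uniform in time. Labels map to hours as
"3 h" → 3 and "d days" → 24·d, the unique affine mapping consistent with a
grid that starts at hour 3 of day 1 and ends at hour 24 of day 16; the
hourly grid for the default schedule has 382 points. Interpolation is
monotone piecewise cubic Hermite (PCHIP): shape preserving, no overshoot,
exact at the knots, no extrapolation.

Because both curves pass through the same interpolation, correlations are
tested against interpolation-aware nulls: M random behavioural 8-tuples
(Gaussian white noise, or permutations of the observed behavioural values),
interpolated identically and correlated with the interpolated topological
curve, give the null distribution; the two-tailed p-value is
`p = 2·min(#[C_rand ≤ c]/M, #[C_rand ≥ c]/M)` with significance at 0.05.
p = 0 is reported exactly as the formula produces it; the
continuity-corrected `(k+1)/(M+1)` variant is logged alongside but never
substituted. Degenerate (zero-variance) null draws are redrawn, capped at
10·M attempts. The default M is 10,000; analyses in the test suite use
M = 1000 or less, which changes only the p-value granularity. Under a true
null the test is calibrated: the measured type-I error at α = 0.05 is
0.05 ± 0.01 over 500 simulated datasets, and the significant /
non-significant calls on the planted study are unchanged if linear
interpolation replaces PCHIP for the null reconstruction.

The summary table reports, per measure, both correlations, all four
p-values (2 correlation types × 2 null models), the absolutely larger
correlation with its sign, and — conservatively — the maximum p-value over
the two null models for that correlation. Measures whose time course is
undefined or constant are excluded with a logged reason, never silently.

## Embeddings

PCA operates on the z-scored, sign-aligned signal matrix (rows flipped to
correlate non-negatively with the behavioural reference; exact-zero
correlations left unflipped). MCE operates on the quantile-normalized
matrix (each row mapped onto the across-row mean sorted profile, ties
averaged, rank order preserved): pairwise Euclidean distances → minimum
spanning tree → all-pairs path distances over the tree (the MC-kernel,
symmetric, zero-diagonal, additive along tree paths) → SVD *without*
centering; coordinates are left singular vectors scaled by singular values.
Sign alignment precedes quantile normalization, so both embeddings see one
preprocessing chain. The optional first-component skip (conventions differ
between MCE variants) is exposed as `skip_first`, default off. MST
tie-breaking is the deterministic order of the sparse Kruskal
implementation, so embeddings are reproducible; axis signs are arbitrary
(SVD indeterminacy) and all tests compare orderings up to a global flip.

## Engram analysis

The per-step representative connectome is the ensemble member whose
LCP-corr is closest to the step's mean LCP-corr (ties to the lowest index,
logged). "Retained" links between consecutive steps are the exact edge-set
intersection of the two representatives — the minimal reading of
connectivity maintained across an interval — classified intra-S1,
intra-VPL, inter-region. Representative (not averaged) connectomes are used
throughout so the link counts and the retained sets refer to the same
objects.

## Synthetic data generator

The generator emulates the *structure* of the study — 8 steps at the
default schedule, 1000 matrices per step of which the middle 400 are kept,
31 nodes split 15 (S1) / 16 (VPL) — with planted statistical ground truth:

- **Latent trajectory** (default `[0.2, 0.9, 0.5, 0.45, 0.6, 0.65, 0.7,
  0.7]`): acute spike at step 2 (day 4), chronic rise and plateau from day
  11. These are generator parameters that mimic the qualitative shape of a
  neuropathic-pain time course, not estimates from data.
- **Behaviour**: `grams = 26·(1 − latent) + N(0, 0.5²)` — a Von-Frey-like
  threshold, monotone decreasing in latent pain (26 g is a typical maximal
  test force for rats).
- **Topology**: a community-rich template (near-cliques of 4–7 nodes inside
  each region, edge probability 0.95 within communities and 0.15
  elsewhere) has LCP-corr ≈ 0.85–0.9. Each step's base graph is rewired by
  *targeted* degree-preserving double-edge swaps — a proposal is accepted
  only if it moves LCP-corr strictly toward the target
  `0.9 − 0.55·latent` (tolerance 0.02) — chained from the previous step's
  graph. Targeted annealing is used instead of a fixed swap count because
  the LCP-corr response of a 31-node graph to blind swaps is a noisy,
  non-monotone random walk; annealing pins each step's base value to its
  target, making the planted coupling reliable. Chaining means equal
  consecutive latents leave the base graph bit-identical (the stable
  chronic phase the engram analysis detects) while the acute jump rewires
  many links.
- **Within-step variability**: each ensemble member flips every node pair
  independently with probability 0.02 (edge flips, not weight noise,
  because the downstream measures are binary).
- **Controls**: swaps preserve every node degree, so the average degree is
  constant across steps by construction — a planted negative control whose
  apparent correlation with behaviour is pure noise. LCP-corr is the
  planted positive marker.

All generation is deterministic given the config seed. What passing tests
on these data show: the pipeline recovers a planted topology–behaviour
coupling of realistic magnitude and rejects a planted null, at the study's
sample sizes. What they do not show: anything about coherence estimation
from raw electrophysiology (the generator starts at the adjacency-matrix
level), about weighted-network effects, or about biological effect sizes.

## Problem sizes and runtime choices

The stochastic measures dominate cost. The pipeline therefore evaluates
them on an evenly spaced subsample of each ensemble
(`stochastic_subsample`, default 25 of the 400 members) — justified by the
stability check: their per-ensemble standard error is small relative to the
mean — while the deterministic measures use every member. The test suite
runs reduced-but-structurally-complete configurations (smaller ensembles,
M = 100–1000, bootstrap 20–200); the acceptance script uses default-scale
studies with M = 1000.

## Known limitations

- Weighted and directed generalizations of the measures are out of scope;
  everything operates on the binarized graph.
- The affine day→hour mapping assumes recordings at a consistent hour; the
  true wall-clock times are unknowable from the schedule labels.
- The exact-p formula can return 0; consumers needing strictly positive
  p-values should use the logged continuity-corrected variant.
- MCE coordinates are unique only up to axis sign, and the kernel SVD can
  swap near-degenerate components between platforms; downstream analyses
  should treat orderings, not raw coordinates, as the stable output.
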