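# Methods

## Problem and model

Given two undirected, unweighted networks `A` and `B` on the same labelled
node set `V` (|V| = N) — e.g. co-methylation networks inferred from healthy
and diseased cohorts — we ask (i) whether the two networks are
statistically independent, and (ii) which node subset carries a
*differential* interaction pattern, i.e. on which induced subgraphs the
two networks look mutually independent while the remainder stays
dependent.

### Edge weights

Each network is mapped to a symmetric edge-weight matrix with zero
diagonal, in one of two modes:

* **adjacency** — the raw 0/1 entries `A_ij`;
* **topological overlap (TO)** — the one-step overlap

  `a_ij = (sum_{l != i,j} A_il A_lj + A_ij) / (min(d_i, d_j) + 1 - A_ij)`,

  which counts the shared neighbourhood of the pair relative to the
  smaller degree.  The denominator is always >= 1 (pairs involving an
  isolated node get weight 0) and every weight lies in [0, 1].  Two
  equivalent denominator forms circulate for this quantity; the
  `min(d_i, d_j) + 1 - A_ij` form is used because it guarantees the unit
  upper bound.  The matrix diagonal is stored as 0 throughout: every sum
  in the distance and in the permutation moments runs over distinct node
  pairs only, so a diagonal convention of 1 would never enter any result,
  and the zero convention keeps the moment sums unambiguous.

### The GHD statistic

With mean-centred weights `a'_ij = a_ij - mean` (mean over distinct
pairs), the Generalised Hamming Distance is

`GHD(A, B) = 1/(N(N-1)) * sum_{i != j} (a'_ij - b'_ij)^2`.

With adjacency weights the uncentred version is exactly `2 HD / (N(N-1))`
with HD the classical Hamming distance `tr[(A-B)^2]/2`; with TO weights
the GHD reacts to neighbourhood rearrangements that leave the raw
edge-difference count unchanged (two single-edge relocations with equal
HD generally have different GHD).

### Permutation null and closed-form moments

Independence is tested against the permutation null: relabel the nodes of
`A` uniformly at random (shuffle rows and columns of its weight matrix
jointly) while holding `B` fixed.  Writing, for a weight matrix `w`,

```
S1 = sum_{i != j} w_ij     S2 = sum_{i != j} w_ij^2
T  = sum_i (sum_{j != i} w_ij)^2
A* = S1^2    B* = T - S2    C* = A* + 2 S2 - 4 T
```

the exact permutation mean and variance of the GHD are

```
mu    = (S2_a + S2_b)/(N(N-1)) - 2 S1_a S1_b / (N(N-1))^2
sigma2 = 4/(N(N-1))^3 [ 2 S2_a S2_b + 4 B*_a B*_b/(N-2)
                        + C*_a C*_b/((N-2)(N-3)) - A*_a A*_b/(N(N-1)) ]
```

The moment sums are evaluated on **centred** weights (then `S1 = 0`
identically); the formulas are implemented in full generality.  This
convention is validated against an exhaustive-enumeration oracle: for
random pairs with N in {4, 5, 6}, in both weight modes, the closed forms
reproduce the mean and variance of the GHD over all N! permutations to a
relative error of ~1e-15.  Variance values in a tiny negative
neighbourhood of zero (relative magnitude below 1e-9), which arise from
floating-point cancellation on degenerate inputs, are clipped to 0;
anything more negative raises an internal-consistency error.

### Asymptotic normality and the p-value

The GHD is, up to a permutation-invariant constant, a generalised
correlation coefficient between the two weight matrices.  Its permutation
distribution is asymptotically normal when the weights are mean-centred
and a skewness-type ratio of centred row-sum moments,

`[sum_i r_i^3]^2 / [sum_i r_i^2]^3`,   `r_i = sum_{j != i} w'_ij`,

vanishes as N grows (in adjacency mode `r_i` is the degree of node i
minus the mean degree; for power-law degree distributions with exponent
`alpha` in (1, 2) the ratio decays like `N^(alpha-2)`).  The ratio is
reported with every test result as a diagnostic; no finite-N cutoff is
imposed since only the limit carries a guarantee.  Regular weight
matrices make both numerator and denominator zero and the ratio is
defined as 0 with a warning.

Dependence makes the networks more alike than a random relabelling, so
the observed GHD falls *below* its permutation mean and the test is
lower-tailed: `p = Phi((GHD - mu)/sigma)`.  A two-sided variant is
available behind a flag.  When `sigma2 = 0` the statistic is permutation
invariant and `p = 1` by definition.  The Monte-Carlo version uses the
add-one estimator `p = (1 + #{GHD_pi <= GHD_obs})/(1 + n_perm)`, which
cannot return 0; only the permuted cross-product term varies under
relabelling, so each draw costs a single masked sum.

## Baseline tests

MAD (`sum |a_ij - b_ij| / (N(N-1))`, lower tail) and QAP
(`sum a_ij b_ij / (N(N-1))`, upper tail) run through the same
permutation engine; for binary networks `|a-b| = a + b - 2ab`, so one
permuted cross-product drives both.  The CUG test draws pairs of uniform
random graphs conditioned on N and the exact observed edge counts and
compares the graph-covariance statistic `gcor` (upper tail).  `gcor` is
implemented as the printed covariance *sum*; a normalised correlation
variant exists behind a flag, and the CUG p-value is invariant to that
positive rescaling.  Tail directions are design choices inferred from
each statistic's direction of similarity and are exposed as flags.

## Differential subnetwork detection (dGHD / dHD)

For a node subset `V_K` the centred statistic is
`Delta_VK = GHD(A(V_K), B(V_K)) - mu_VK`, with weights recomputed on the
induced subgraphs and `mu_VK` the closed-form permutation mean.  The
influence of node i is `delta_i = Delta_{V_K \ i} - Delta_VK`.  Starting
from the full set the algorithm repeatedly removes the node with the
largest `delta_i` (ties broken by smallest label; when no `delta_i` is
positive the largest is still removed so the full trace exists, and the
step is flagged), recording the asymptotic p-value at every size down to
`n_min`.  Raw p-values are then Benjamini-Hochberg adjusted *once across
the completed trace* (the trace length is known only at the end), and the
differential subnetwork is the node set at the largest size whose
adjusted p-value exceeds `alpha`; if no size qualifies the result is
"no differential subnetwork".  Adjacency weights give the dHD variant.
Defaults: `alpha = 0.05`, `n_min = max(20, ceil(0.02 N))` (no canonical
value exists; this keeps the closed-form variance well defined and the
trace long enough for the FDR adjustment to be meaningful),
`batch = 1` (one node per step; larger batches are a recorded speed
option).

### Accelerated influence computation

Computing `delta_i` for all K candidate removals by recomputing TO
weights on each leave-one-out subgraph costs O(K^4) per step.  Because
the permutation mean absorbs both squared terms of the GHD, the centred
statistic reduces to a scaled centred cross-product of *raw* weights:

`Delta = -2/(K(K-1)) * [P - S1a S1b/(K(K-1))]`,  `P = sum w^a_ij w^b_ij`.

Removing node i changes the TO weight of a remaining pair (j, k) in
exactly two ways: the shared-neighbour count drops by `A_ij A_ik`, and
the denominator drops by 1 precisely when the smaller-degree endpoint
neighbours i (whenever a drop occurs the denominator was >= 2, so no
division blows up).  Writing these updates as indicator-weighted pair
factors, the leave-one-out corrections to `S1a`, `S1b` and `P` for *all*
candidates simultaneously become a fixed set of `diag(X M Y)`
contractions with X, Y built from the two adjacency indicators — about a
dozen dense matrix products per step instead of K weight recomputations,
for an overall O(K^3) step cost.  Transpose symmetry halves the mixed
contractions, and the shared-neighbour matrices are maintained across
steps by exact integer rank-1 downdates.  The exact-recomputation path is
retained and the two are required to agree (observed agreement is at
machine precision, asserted at atol 1e-10) on random planted instances in
both modes.

## Simulators

* **RG** — N points uniform on [0,1]^2 (no wrap-around; boundary effects
  are part of the model), edge iff Euclidean distance < d (strict; a
  measure-zero choice).  The default study conditions are N = 250,
  d = 0.3 or 0.15 for calibration studies and N = 1000, d = 0.3 for
  detection studies.
* **ER** — uniform over graphs with an exact edge count (the CUG null),
  or IID edges with probability p.
* **SF** — IID degrees from `P(d = k) ~ k^-alpha` on `m..K`
  (`K = N^{1/(alpha-1)}` for alpha > 2, else N-1), realised by an erased
  configuration model: only the degree law matters for the normality
  diagnostic, so the simplest standard realisation is used.  If the drawn
  degree sum is odd, one uniformly chosen degree is incremented.
* **shuffle_edges(gamma)** — deletes `ceil(gamma |E|)` uniformly chosen
  edges and reinserts the same number uniformly among the pairs absent
  after deletion (deleted slots may refill).  The edge count is preserved
  exactly, and gamma = 1 produces a uniform density-matched graph
  independent of the input, which is the property the noise parameter is
  meant to interpolate towards.  A consequence: the "too few absent
  pairs" failure cannot occur, since deletion itself frees enough slots.
* **plant_differential** — A is an RG draw, B = shuffle_edges(A, gamma);
  a uniform subset V* (default 200 of 1000) has its *internal* edges
  replaced in both networks by two independent RG draws of the same
  radius.  Edges between V* and the rest are left untouched: the
  replacement is read as acting on the selected subset's own edges, and
  keeping the boundary intact makes the planted signal conservative.

## What the synthetic data does and does not show

The generators reproduce the *mechanisms* the method targets — geometric
dependence, controlled noise, a planted independence signal, correlated
probe blocks — under exactly known ground truth.  They do not reproduce
features of real methylation data: beta-value distributions bounded in
[0, 1], batch effects, varying probe-wise noise, or the ~27k-probe scale
of a real array (studies here run at N <= 1000).  Passing tests
demonstrate correctness of the statistics and algorithms under the
simulated conditions, not field performance on array data.

The synthetic probe generator gives each block one latent factor with
loading `sqrt(r)`, yielding within-block pairwise correlation ~ r and
independent probes elsewhere; the co-methylation rule
`omega_ij = ((1+r_ij)/2)^b`, edge iff `omega > tau` (strict; defaults
b = 12, tau = 0.2) is equivalent to `r_ij > 2 tau^(1/b) - 1 ~= 0.7487`,
and the implementation is tested for exact agreement between the two
forms.  The absolute value sometimes written around `(1+r)/2` is
redundant for r in [-1, 1] and omitted.  Correlations are computed in
column chunks so probe counts well beyond the sample count stay in
memory.

## Numerical and design choices

* All randomness flows through `numpy.random.Generator`; every study
  derives replicate seeds as master seed + running counter, and manifests
  record all parameters.
* Weight matrices are dense float64; acceptance-scale problems run at
  N <= 1000.  The O(K^3)-per-step influence engine makes a full
  N = 1000 backward elimination run in minutes on one core.
* Degenerate inputs: empty or complete graphs give constant weight
  matrices, `sigma2 = 0`, and p = 1 (independence never rejected) —
  the permutation distribution is a point mass, so this is the only
  consistent answer.
* The condition-number-free identity `sum_{j != i} a'_ij = d_i - mean(d)`
  (adjacency mode) is used as a unit-level invariant.

## Scale of the shipped studies

The packaged test-suite and acceptance-script runs use reduced problem
sizes chosen as the package's own verification scale: null calibration at
N = 100 with 2000 replicate pairs per radius; permutation normality at
N = 250 with 10,000 permutations; power comparison at N = 250 with 200
replicates; planted-subnetwork recovery at N = 1000 (single instance
trace) and N = 300 with 5 replicates per noise level (benchmark
orderings).  The same code reproduces the full-scale studies (10,000
pairs, 100 replicates at N = 1000) by changing the config values; at
full scale a benchmark sweep is an hours-long single-core job.

## Known limitations

* Backward elimination finds one differential subnetwork per run;
  multiple disjoint differential regions are reported as their union at
  a single size, and no connectivity constraint is applied.
* The asymptotic p-value is only as good as the normality conditions;
  for very small or near-regular networks use the Monte-Carlo test (the
  closed-form variance also requires N >= 4).
* At strongly reduced problem sizes the detection benchmark distorts at
  high noise levels: when the shared background signal is too weak for
  the global test to reject at the full size, the scan accepts
  immediately and returns the full node set (specificity collapses
  toward 0).  This is a property of the scaled study conditions, not of
  the algorithm at its intended scale.
* Directed or weighted-edge networks and multi-step topological overlap
  are out of scope; weighted inputs must be thresholded upstream.
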