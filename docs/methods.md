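# Methods

This note documents the model, the algorithmic and numerical choices, the
synthetic study conditions, and the known limitations of the package.

## Model

A prior knowledge network (PKN) is a signed directed graph over proteins.
Node roles are purely structural: in-degree-0 nodes are stimuli, out-degree-0
nodes are readouts, the rest are inhibitors. Candidate mechanisms are
*clauses*: AND-conjunctions of one or two signed regulators of a target
(a literal `(v, −1)` reads "v inactive"); the arity cap of 2 keeps the
search space `2^|clauses|` exhaustively enumerable at the supported sizes.
A Boolean network is a clause subset, clauses sharing a target being OR-ed.
Self-loops are parsed but excluded from clause expansion (a node is never
its own regulator), and two edges from the same source with both signs never
form a two-literal clause.

### Logical semantics

Given a clamping of the input proteins, every other node starts at 0 and is
updated synchronously by its OR-of-ANDs rule; clamped nodes never change.
Iteration stops at a fixed point or after `|nodes| + 1` sweeps; a
non-converging run is flagged oscillatory and its readouts are scored 0 with
a warning. This is the simplest reproducible contract for the steady-state
response of the network; on acyclic PKNs (the synthetic default) it is the
unique forward propagation. A node without any selected clause stays 0, so
unmeasured intermediates default to "inactive" rather than "free" — the
main semantic commitment of the package. The implementation packs each
node's value across all experiments into one integer, so a sweep is
O(clauses) bitwise operations; tests verify bit-for-bit agreement with a
naive dictionary-based simulator.

### Experiments and clamping

Each selected CR–PR couple becomes one pseudo-perturbation experiment per
class: the clamped map covers exactly the selected protein set K (the only
set the couple is guaranteed to agree on); unselected stimuli behave like
any clause-less node and default to 0. Readout observations are the
class-side patient's normalized values.

## Preprocessing

* **Binarization.** Two-cluster k-means on the input measurements, pooled
  globally by default (a `per-protein` scope is exposed because protein
  scales can differ). One-dimensional 2-means is solved *exactly* by
  scanning the n−1 sorted split points with prefix sums — no random
  initialization, hence no seed sensitivity; the seed parameter is accepted
  for API compatibility only. A measurement's bit is the bit of its nearest
  cluster centre; a centre maps to 1 when, rescaled onto the data's min–max
  range, it is ≥ 0.5. A constant value set binarizes to all zeros with a
  warning. Transforming new data uses the fitted centre midpoint, which
  makes the mapping monotone in the raw value.
* **Normalization.** Min–max over all readout measurements (global scope by
  default, matching the single min/max of the normalization formula;
  `per-protein` is available). `max == min` is an error. Values of *new*
  data outside the fitted range are clipped into [0,1].
* Missing or non-finite values are rejected at load; imputation is out of
  scope.

## Selection

Affinity of a CR patient and a PR patient under a protein set K depends only
on their bit profiles restricted to K, so the affinity graph is a disjoint
union of complete bipartite blocks (one per profile). Consequences used by
the implementation:

* the maximum number of non-redundant couples (maximum bipartite matching)
  is `Σ_profiles min(#CR, #PR)`;
* the matching of that size maximizing the summed readout gap decomposes
  into one rectangular assignment problem per block, solved exactly with the
  Hungarian algorithm;
* an affinity pair is *redundant* (shares a patient with another pair) iff
  its block is larger than 1×1, which is what the k-sweep reports.

All `C(n_inputs, k)` subsets are scanned; every subset attaining the maximal
couple count is returned, ranked by readout gap and then lexicographically
by protein names (determinism). The gap tie-break therefore only matters
when several optima exist. The generic matching entry point uses
Hopcroft–Karp (networkx) and can enumerate all maximum matchings by
backtracking for auditing; tests cross-check the biclique shortcut against
it and against a brute-force dynamic program. The exhaustive scan is the
reference implementation; an ASP backend slot exists in the API but raises
`ImportError` because no ASP solver is among the package's dependencies.

## Learning

The family learner scores **every** clause subset (lexicographic objective:
MSE over all experiment × readout cells, then clause count) and returns all
subsets within `fit_tolerance` (default 0) of the minimal MSE and
`size_tolerance` (default 0) of the minimal size among those. MSE
co-optimality uses an absolute slack of 1e-9 to absorb floating-point
summation noise. Plain enumeration with the bit-parallel engine replaced an
initially planned branch-and-bound: at the guarded sizes (`max_clauses`
default 20, in practice ≤ 15) enumeration is already fast and trivially
exact. Behavior grouping compares readout fixpoints over all `2^n` input
clampings (guarded at n ≤ 20); clause frequencies are per-clause membership
fractions across the family, and the union network is the clause-set union
(the "thick edge" family summary).

## Classification

Per patient, each family predicts every readout as the mean fixpoint value
across member networks (an average over behavior-group representatives is
also available); the class with the lower MSE against the patient's
normalized readouts wins. Confidence is `mse_PR/(mse_CR + mse_PR)`, defined
as 0.5 when both errors vanish; it is a calibration-free score oriented so
1 means confident remission. Exact MSE ties are labelled CR under Method 1
(majority class, flagged) and `unknown` under Method 2. Method 2's
significance filter keeps a patient when readout values are outside
(low, high) = (0.25, 0.6); the default quantifier is `all` readouts
(strictest), with `any` exposed. Patients dropped by Method 2 are excluded
from accuracy denominators. Per-class accuracy is over classified patients
of that class; balanced accuracy is the unweighted mean, undefined (NaN)
when a class has no classified patient.

## Synthetic studies

The generator emulates a two-class perturbation proteomics study:

* **Topology**: layered acyclic PKN (stimuli → inhibitors → readouts),
  1–`max_parents` regulators per node with `max_parents = 2` as a hard
  in-degree cap, which bounds the clause count by `3·(n_inhibitors +
  n_readouts)` and keeps exhaustive learning fast; ~70% of edges are
  activations. Wiring prefers so-far-unused sources so every stimulus and
  inhibitor regulates something without breaching the cap. An optional
  `feedback_edges` flag adds cycles for robustness tests only.
* **Planted models**: one clause set per class sampled at `clause_density`
  (≥ 1 clause per regulated node); the PR model differs from CR in exactly
  `divergence` toggled clauses, resampled until the two differ in readout
  behavior on at least one input pattern.
* **Patients**: input bits i.i.d. Bernoulli(`input_bit_prob` = 0.5); by
  default (`informative_patients`) a patient's bits are resampled until the
  two class models disagree on their readouts — patients probing no
  divergent mechanism carry no class signal and only dilute accuracy
  estimates. Raw measurements are bit (or readout fixpoint, noise-clipped
  to [0,1]) + Gaussian(`noise_sd`), affine-mapped onto a positive
  RPPA-like scale (400 + 1800·x arbitrary units) so both preprocessing
  stages are exercised non-trivially. Everything is deterministic given the
  config seed.
* **Presets**: `tiny` (3/3/2 roles, 8+8 patients plus held-out),
  `small` (5/8/4, 30+30) and `paper-shaped` (17/62/23 roles, 96+95
  patients), the last matching the dimensionality of a realistic
  KEGG-derived signalling network study in role counts only.

What passing synthetic tests do **not** show about real data: real RPPA
measurements are not bimodal around two levels, real signalling is not
acyclic or noise-free, class mechanisms are not guaranteed to differ, and
real patients are not pre-filtered to informative input profiles. The
synthetic results are correctness and calibration checks of the machinery,
not effect-size predictions.

### Benchmark protocols and problem sizes

`benchmarks.planted_recovery` learns each family from noise-free
experiments covering *all* input clampings — under full coverage every
MSE-0 network is input–output equivalent to the planted model, so recovery
and 100% held-out balanced accuracy are structural guarantees, which is the
point of the check. `benchmarks.noise_sweep` repeats this with Gaussian
noise on both the learning observations and the held-out patient table
(3 stimuli + 2 inhibitors + 2 readouts, 10 held-out patients per class,
20 seeds per level by default). The full-pipeline study used by the
acceptance script (3/3/2 roles, 12+12 patients, k = 4, noise 0.1) selects
k = 4 of the 6 input proteins: requiring agreement on *all* inputs often
leaves no couples at realistic sample sizes, which is precisely the
phenomenon the selection stage exists to mitigate. These sizes were chosen
so the exhaustive reference algorithms remain exact.

## Known limitations

* Synchronous 0-default fixpoint is one of several defensible steady-state
  semantics; cyclic networks may legitimately oscillate and are then scored
  pessimistically.
* The exhaustive learner is exponential in the clause count by design
  (exactness over scale); large PKNs need the hypergraph reduced or an
  external ASP-based learner.
* Selection scans `C(n, k)` subsets; it is meant for tens of input
  proteins, not hundreds.
* The confidence score is a ratio of errors, not a calibrated probability.
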