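# Methods

This note documents the models, statistics and design choices behind
`netcondense`, and what the synthetic benchmark does and does not show.

## Preprocessing

Expression enters as a genes × samples table of strictly positive
linear-scale intensities; samples are labelled A (non-responders, the
reference group) or B (responders, the cases). The preprocessing order is
fixed: quantile normalization at probe level → probe → gene collapse →
group-wise means. Quantile normalization replaces each column by the
across-sample means of the rank-ordered values; tied values receive the
mean of the rank-means their span covers, which makes the operation
deterministic and row-order independent. Probes mapping to several genes
are dropped before collapsing (only the many-probes-to-one-gene direction
is well defined); a gene's value is the arithmetic mean of its probes.
Missing values are rejected rather than imputed, and zero/negative
intensities are rejected unless an explicit floor (`floor_intensities`,
ε = 1e−6 by default) is requested.

Group means are taken on the linear scale and logs are applied downstream
(inside the link score and the t-tests). Whether the original study
averaged linear or log intensities is not recoverable; linear averaging
was chosen as the default because the link score is a function of group
means and stays scale-invariant either way, and the alternative only
shifts scores by Jensen-gap terms that are constant under the generator's
shared noise model.

## Link score and condensation

For an interaction (i, j), with m_A/m_B the group means of the endpoints,

    LS(i, j) = [log2 m_B(i) + log2 m_B(j)] − [log2 m_A(i) + log2 m_A(j)].

This is the log2 fold change of the product of endpoint means; it is
antisymmetric under swapping groups and invariant to multiplying all
intensities by a constant. A difference-of-products variant
(m_B(i)·m_B(j) − m_A(i)·m_A(j)) is available behind `variant=
"diff_product"`; it weights highly expressed genes more and is not
scale-invariant, which is why the log form is the default.

Condensation keeps the k_up edges with the largest positive scores and the
k_down with the most negative; zero-score edges belong to neither
direction. Ties break on the canonical (lexicographically sorted) edge
identifier, so the selection is deterministic. When k_up + k_down exceeds
the edge count the selection clamps with a warning.

Interaction-level significance uses the per-sample activity
a_s = log2 x(i,s) + log2 x(j,s) — the sample-level analogue of the link
score — compared between groups with Welch's two-tailed t-test (the
equal-variance variant is deliberately avoided: group sizes are unbalanced
by design, 182 vs 48). Gene-level tests are Welch tests on log2 values.
Both are Benjamini–Hochberg adjusted *across the selected subnetwork's
items* (the selection is the hypothesis family of interest); a
network-wide universe is a caller choice, since the functions adjust over
whatever item set they are given. α defaults to 0.05.

## Interaction network

STRING-style links tables are filtered by confidence: an edge is kept when
the maximum over the selected evidence channels (experimental, database,
textmining) reaches the threshold, 0.85 by default. The disjunctive
reading ("any channel suffices") is the default because it is the literal
reading of a per-channel rule; a combined-score mode
(1 − ∏(1 − s_c) ≥ t) exists behind `combined=True`. Scores on the integer
0–1000 convention are auto-detected and divided by 1000. Rows are
canonicalized (unordered pairs), deduplicated keeping per-channel maxima,
and self-loops dropped. Identifier matching against expression is exact
and case-sensitive; alias resolution is out of scope. Effect annotations
(stimulation/inhibition) can be attached from an actions table but never
influence scoring.

## Indicator matrix and the K/L exception model

The per-case activity test follows the recommended recipe for
case-vs-control-population mining: intensities are log2-transformed,
each sample column is standardized to mean 0 / variance 1 (sample
variance, divisor n−1), and each responder value is z-tested two-tailed
against the gene-wise mean and standard deviation of the non-responders;
the indicator entry is 1 iff |z| ≥ Φ⁻¹(1 − α/2) (1.959964 at α = 0.05).
The log2 step is this package's choice: z-testing raw linear intensities
against a roughly log-normal control distribution inflates the upper tail
and miscalibrates per-case detection, while on the log scale the null
activation rate matches α (verified by simulation in the test suite). The
test is two-tailed and the variance divisor is n−1; neither is recoverable
from the original description, and both choices are recorded here. Genes
with zero control variance yield all-zero rows with a warning.

A *solution* of the K/L model is a connected subgraph in which every node
is active at case-exception budget L (misses the activity test in at most
L cases) except for at most K exception nodes. Solutions must contain at
least one active node: a budget of K exception nodes alone would otherwise
always form a spurious non-empty "solution", and the empty-network outcome
for small L — the phenomenon of interest in heterogeneous cohorts — could
never occur.

### Solvers

The original tool searches with an ant-colony metaheuristic; that search
strategy is out of scope here and is replaced by two solvers with the same
constraint semantics:

* **Exact** (instances ≤ 25 nodes): enumerate every subset E of inactive
  nodes with |E| ≤ K and collect the connected components of the subgraph
  induced on active ∪ E that contain an active node. Every
  inclusion-maximal feasible node set arises this way — a maximal feasible
  S with exception set E_S is, by maximality, exactly the component of
  G[active ∪ E_S] containing it — so ranking the deduplicated components
  by size yields the true optima. Solutions are ranked by size descending,
  then total active indicator entries, then lexicographically.
* **Greedy** (any size, seeded, deterministic): grow from each active seed
  node in seed-shuffled order; active neighbours are admitted first
  (they never consume budget), and when none remain an exception neighbour
  is admitted — the one unlocking the most new active genes — until the K
  budget is spent. Greedy solutions always satisfy the constraints
  (validated independently) and never exceed the exact optimum, but carry
  no optimality guarantee.

`min_L_for_size` binary-searches the smallest L admitting a solution of a
target size; correctness relies on solution size being monotone
non-decreasing in L, which holds exactly for the exact solver and
empirically for the greedy one on the benchmark scenarios.

## Over-representation analysis

Result gene sets are tested against user-supplied GMT collections with the
one-sided hypergeometric upper tail P[X ≥ overlap], term sets intersected
with the background first and BH adjustment across the collection. The
background defaults to the network gene universe in the analysis drivers,
because that is the sampling frame of both subnetwork methods. Depletion
is not tested.

## Synthetic cohort generator

The generator emulates the structure of an unbalanced two-group microarray
cohort: per-gene log2 baselines ~ Normal(8, 1.5) shared across samples,
per-entry Normal(0, σ) noise on the log2 scale, export on the linear scale
(2^value). Defaults mirror the benchmark conditions: 100 genes, a
connected Erdős–Rényi G(n, M) network with 250 interactions (channel
confidences uniform in [0.85, 1.0], so the default filter keeps all
edges), 182 non-responders vs 48 responders, 8 up- and 8 down-regulated
planted interactions with both endpoints shifted by 1.5 log2 units, σ =
0.3. The 182/48 split matches the cohort the pipeline is designed around;
σ = 0.3 gives per-gene group-mean standard errors of ≈ 0.05 log2 units,
i.e. clearly detectable but not trivial planted effects.

Two placement rules govern planted edges: endpoints are disjoint across
planted edges (each planted gene has one unambiguous direction), and no
*unplanted* network edge may join two same-direction shifted genes. The
second rule exists because such a shortcut edge would carry the identical
expected link score as a planted edge, making edge-level precision/recall
a tie-breaking coin toss rather than a property of the method. Carrier
sets — the responders in which a planted signal is present — are drawn
independently per edge with |carriers| = round(carrier_fraction · n_B);
`carrier_fraction = 0.25` reproduces the heterogeneous-cohort regime in
which no gene is active in enough cases for small case-exception budgets.
All randomness flows from one seed through named per-operation streams, so
identical seeds give bit-identical cohorts and adding operations never
perturbs existing draws.

What the generator does *not* emulate: probe-level structure and
saturation, background signal, batch effects, sample-level technical
variation, and correlated expression beyond the planted modules. Passing
the benchmark therefore shows that the statistics and solvers behave as
specified under their own model assumptions — not that the pipeline is
robust to array artefacts.

One consequence worth noting: because the generator introduces no
technical variation, quantile normalization has nothing to remove in the
benchmark, and on a 100-gene panel where a third of the genes carry
planted group effects it actively distorts them (QN assumes most features
are unchanged between samples). The recovery benchmark is therefore scored
on the generated intensities directly; `analysis/02_condense_network.py`
quantifies the distortion (recovery drops from 16/16 to 15/16 planted
interactions at the default seed). On genome-scale arrays, where
differential genes are a small minority, this caveat is negligible.

## Problem sizes and numerical choices

The benchmark analyses and the acceptance script use 100-gene / 250-edge
cohorts, 100 seeded replicates for the recovery rate, 3,000 gene-case
entries for null calibration, and ≤ 12-node instances for exact-vs-brute
force solver comparisons; these sizes give stable estimates (binomial
standard errors ≤ 0.7 percentage points on the calibration rate) while
keeping every run to seconds. Exact solver instances are capped at 25
nodes (the exception-subset enumeration is combinatorial in K); larger
instances go to the greedy solver. Floating-point equality in tests is
asserted at 1e−12 where values are algebraically exact; calibration
checks use 3 binomial standard errors.

## Known limitations

* The greedy K/L solver is a heuristic; reported subnetworks are feasible
  and deterministic under the seed but not certified maximal.
* Identifier namespaces must already agree between expression and network
  tables; no alias mapping is attempted.
* The per-case z-test treats the control distribution as normal after the
  log2 transform; heavy-tailed real intensities will inflate the per-case
  activation rate relative to α.
* Enrichment is a generic hypergeometric over-representation test; it does
  not reproduce any proprietary annotation database or its term
  vocabulary.
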