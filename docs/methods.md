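# Methods

`orsel` tests whether branches of a species phylogeny on which a
sociobiological or ecological trait changed ("transition branches") are
enriched or depleted for positive selection acting on members of a large
multigene family (the motivating case is the ant odorant-receptor
repertoire). The unit of evidence is a gene-tree branch carrying a p-value
from an upstream branch-site dN/dS test; the pipeline's job is to place
those branches on the species tree, define the transition branches, and run
a calibrated enrichment statistic. This note documents the models, the
defaults and their rationale, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Tree representation and branch identity

Trees are rooted, stored as flat arrays indexed by post-order node id
(children before parents, root last), with ids assigned deterministically
from the child order of the source Newick. The branch *leading into* a node
carries that node's id, giving one id namespace for nodes and branches;
every table in the pipeline (branch maps, test records, transition files)
uses these ids. Missing branch lengths parse as 0 and are flagged; unrooted
input is rejected rather than midpoint-rooted, because every upstream tool
in this setting produces rooted trees. Gene-tree leaves encode their species
of origin as `species|gene`, split on the first delimiter occurrence.

## Duplication–loss reconciliation

Gene trees are embedded in the species tree by LCA (duplication–loss
parsimony) mapping: each gene node maps to the most recent common ancestor
of its descendants' species; a node is a duplication exactly when it maps to
the same species node as one of its children. Losses on a gene branch
(u, v) are `depth(M(v)) − depth(M(u)) − 1`, plus one more when u is a
duplication that did not resolve on the same species branch, and zero when
`M(u) = M(v)`. LCA mapping minimizes duplications + losses over all valid
reconciliations; the test suite verifies this against exhaustive enumeration
of monotone mappings on small instances.

A gene branch that spans several species branches (implied losses) is
attributed to the single child-side species branch: a selection event on
such an edge is observable only in its surviving descendants, and the
enrichment tally needs a unique attribution. Branches whose child maps to
the species root get the synthetic id `root`; they are counted in the test's
population but can never fall in a transition draw. Precomputed
reconciliations (e.g. from probabilistic tools) can be imported from
NHX-annotated trees (`S=` species tags, `D=Y`/`Ev=D` duplication tags);
LCA invariants are re-checked and disagreements downgrade to a flag rather
than an error, since richer models may legitimately differ.

## The enrichment statistic

Long branches are more likely to harbor a detectable selection event, so raw
branch counts are biased. Each branch therefore contributes a weight equal
to its length divided by the mean branch length of its dataset (a dataset is
one species-clade × subfamily analysis); weights sum to the branch count
within a dataset. The hypergeometric test uses

- `N_w` — rounded sum of all weights (population size),
- `n_w` — rounded sum of weights on transition branches (draw size),
- `K` — number of branches with p below the call threshold α (default 0.05),
- `k` — number of those on transition branches.

Significant-branch counts stay unweighted: a selection call is an event, and
weighting events would double-count the length correction. Rounding is
half-to-even, with clamps so the tally invariants survive rounding.
`expected = n_w·K/N_w`, `fold = k/expected` (NaN and flagged when the
expectation is 0). Both one-sided tail probabilities are computed —
`P(X ≥ k)` and `P(X ≤ k)` for `X ~ Hypergeom(N_w, K, n_w)` — and the one
matching the direction of the fold is reported. Because the two one-sided
tails share the point mass at k, the reported p is not a two-sided p-value;
its null behavior is measured directly by the calibration benchmark below.

Convergent transitions (the same trait change on several species branches,
across datasets) are pooled by summing tally components before a single
test. Pooled folds can sit outside the range of member folds
(Simpson-type reversals), so the invariant enforced is exact component
additivity, not fold monotonicity. Benjamini–Hochberg step-up q-values are
computed across the family of reported tests (delegated to statsmodels).

## Trait reconstruction and transition calling

Discrete traits are fitted with Mk models — equal rates (ER, 1 parameter)
and all-rates-different (ARD, k(k−1) parameters) — by maximizing the
Felsenstein pruning likelihood over log-rates (L-BFGS-B, bounds 1e−9 to
1e4 changes per unit length, start at one expected change over the total
tree length). The root prior is uniform (configurable); AIC selects the
model class. Marginal ancestral probabilities combine downward conditional
likelihoods with an upward pass. A branch is a transition for the change
s → s′ when parent and child argmax states differ and both maxima reach a
confidence floor (default 0.7). Continuous traits are reconstructed under
Brownian motion via the GLS conditional expectation given the tips; a branch
is an increase/decrease transition when the child-parent difference exceeds
±δ (default 0.5 trait units, e.g. half a log10 unit of colony size). The
floor and δ are declared defaults, not estimates; when curated transition
branches exist, supplying them as a file bypasses reconstruction entirely
and is the preferred route.

## Ancestral gene counts and PGLS

Copy numbers are reconstructed by Sankoff parsimony over states 0..max
count, default linear cost |i − j| (one gain or loss per copy), custom cost
matrices allowed. Under linear cost the optimal root states form the
Wagner/Farris interval; tie-breaks are deterministic — root takes the
midpoint of its optimal interval (rounded down), each descendant the optimal
state closest to its parent (smaller state on ties). Per-branch deltas
(child − parent) sum in absolute value to the parsimony cost.

Count–trait association uses PGLS: covariance `V_ij` = shared root-to-LCA
path length, off-diagonals scaled by Pagel's λ (fixed, or estimated by
restricted maximum likelihood on [0, 1] by bounded scalar search, xatol
1e−8). Estimates are GLS via Cholesky whitening; the slope is tested with
n − 2 degrees of freedom. λ = 0 on an ultrametric tree reduces to OLS, as
does a star tree at any λ. Families that are mostly single copy (fraction
of species with count ≤ 1 strictly above 0.8 by default; the threshold is a
declared choice) carry no expansion signal and are filtered before fitting
to avoid spurious hits.

## Alignment masking

Per-codon alignment confidence scores in [0, 1] (per sequence × column, or
per column) drive masking before selection testing. The threshold starts at
0.8 and is lowered in steps of 0.1 until at most 20% of codons would be
masked; codons strictly below the chosen threshold become `NNN`
(configurable to gaps). Strict comparison means a threshold of 0 masks
nothing, which fixes the boundary semantics; the procedure is idempotent.
Per-residue and per-column score modes are both supported because upstream
tools emit either.

## Synthetic benchmark

The generator emulates the statistical structure of the real inputs, not
their content: an ultrametric Yule species tree (depth normalized to 1)
with 8 species per clade; 200 gene families per dataset evolved down the
species tree by per-lineage duplication and loss at 0.1 events per unit
depth (moderate turnover — a few percent of families show an event);
one randomly chosen internal species branch as the planted transition;
per-branch test lengths Exponential(mean 0.1 substitutions/site),
independent of selection status by default (a correlation knob exists to
stress the normalization).

The p-value model is calibrated by construction: a branch is "selected"
with probability p0 (f·p0 on transition branches, default p0 = 0.05);
selected branches draw p ~ Uniform(0, α) and unselected ones
p ~ Uniform(α, 1). With p0 = α the marginal p-value distribution under
f = 1 is exactly Uniform(0, 1), and "selected" coincides with "called at
α", so the planted fold is directly comparable to the estimated fold. An
alternative mode draws unselected p ~ Uniform(0, 1) (the upstream test then
contributes its own α false calls, diluting the observable fold), and a
Beta(a, 1) mode models a weaker upstream test.

Benchmark scales, chosen as the package's own study sizes: calibration uses
500 no-signal replicates (the reported-p rejection rate at α = 0.05 lands
near 0.06–0.07 — slightly above α, as expected for a min-of-two-one-sided
report, pulled back by the discreteness of the hypergeometric); power uses
50 replicates with a planted 2-fold, recovering a median fold near 1.9
(slightly below 2 because the transition branches are part of the
population the expectation is computed from) with a large majority of
rejections. Reconciliation recovers ≥ 95% of true branch attributions at
these turnover rates (empirically ≈ 100%, degrading only at several-fold
higher rates).

What passing these benchmarks does *not* show: the generator plants
selection directly as significance indicators, so it says nothing about the
power of the upstream branch-site test; gene branch lengths are exchangeable
within a dataset, so the length normalization is exercised but not
adversarially (except via the correlation knob); trees are small and clean —
no alignment error, no gene-tree estimation error, no rooting error, all of
which affect real data.

## Determinism and degenerate inputs

All randomness flows from explicit seeds through one generator per
simulation; identical configs reproduce byte-identical reports and stage
tables (reports carry the package version, seed and input digests, no
timestamps). Degenerate cases are explicit errors or flagged fallbacks:
all-zero branch lengths in a dataset (error, or unit weights in lax mode),
empty populations (error), a single observed trait state (rate driven to
the bound, flagged), zero-length cherries in Brownian reconstruction
(1e−8 regularization), saturated or empty draws in the hypergeometric
(fold NaN, p = 1).

## Known limitations

- LCA parsimony is the only built-in reconciliation; probabilistic
  reconciliations must be imported. Transfer events are out of scope.
- The Mk machinery targets the small state spaces of sociobiological traits
  (2–5 states); ARD with many states is overparameterized on small trees.
- PGLS assumes a Brownian (λ-scaled) covariance; OU or rate-shift models
  are not implemented.
- The enrichment test conditions on the branch attribution being correct;
  attribution error at high duplication/loss rates biases folds toward 1.
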