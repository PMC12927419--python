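# Methods

## Graph model

A genotype representation graph is a DAG over haploid sample leaves.  Node
ids are dense `0..n_nodes-1`; ids `0..2N-1` are the sample leaves, and the
0-based diploid individual `i` owns samples `2i` and `2i+1`.  Mutations
attach to exactly one node each; sample `j` carries mutation `m` iff a
down-path connects `m`'s node to leaf `j`.  Validity requires acyclicity, no
parallel edges (a duplicate child would double-count in the accumulation
rule), and leaf status for sample nodes.

The two dot products follow the accumulation rule: downward, a node's value
is the sum of its attached entries of `u` plus its parents' values, giving
`G u` at the leaves; upward, every internal node sums its children, giving
`G^T v` at the mutation nodes.  These identities assume each leaf is
reachable from any given node along at most one path — a property that holds
for every graph this package constructs (flat carrier-set builds, greedy
pair factoring, and trees) because edges are only ever re-routed, never
duplicated.  A graph hand-built with genuinely redundant paths would count
path multiplicity; the decoder (direct reachability, path-count agnostic)
exists precisely to cross-check this in tests.

Implementation: traversals are scheduled by longest-path level and executed
as one cached `scipy.sparse` CSR mat-vec per level, rather than per-node
Python recursion.  The recursive per-node rule is kept in the test suite as
an independent oracle.  Topological order breaks ties among incomparable
nodes by ascending node id (heap-based Kahn), so every ordering, and hence
every floating-point summation order, is deterministic.

## Builder

The construction algorithm is deliberately simple and lossless rather than
maximally compressing.  Stage 1 creates one internal node per *distinct
carrier set* (mutations sharing a carrier set share a node) with direct
edges to the sample leaves.  Stage 2 (`compress=True`) greedily extracts the
most frequent child pair shared by at least two parents into a new internal
node, repeating until no pair is shared; ties break toward the smallest pair
of node ids.  Each extraction strictly reduces the edge count, so the pass
terminates; reachability is invariant throughout.  Compression ratio is
best-effort — correctness (`decode(build(G)) == G`, enforced for both
modes) is the contract.

## Standardized genotype scale

For alt-allele frequency `f_i` (carrier count over 2N, computed by one
upward product with the all-ones vector), the per-site scale is
`sigma_i = sqrt(2 f_i (1 - f_i))` — the Hardy–Weinberg standard deviation
of a diploid genotype.  The standardized product is computed as
`X (Sigma beta) - sum_i 2 f_i beta_i / sigma_i`: one downward product with
the scaled effect vector, a pair-sum over haploid leaves, and one scalar
subtraction per trait (the centering term is constant across individuals).
Monomorphic causal sites are rejected (`sigma_i = 0`), and monomorphic
sites are excluded from causal sampling in both raw and standardized modes
for consistency.  Standardized genetic values have mean exactly zero over
individuals up to float round-off.

## Pipeline and calibration

1. **Causal sampling** — uniform without replacement among polymorphic
   sites; sorted ascending.  With several graphs the sample is drawn from
   the pooled eligible sites across graphs, so a panel split by chromosome
   simulates like the merged panel.
2. **Effect sizes** — built-in families: normal (optionally multivariate
   across traits with a user covariance), exponential, fixed, gamma, and
   location–scale Student-t.  Exponential/gamma draws are positive as
   drawn; a `negative_sign_prob` knob (default 0) optionally flips signs.
   `df <= 2` in the t family is allowed but warned (infinite variance).  In
   standardized mode without an explicit distribution,
   `beta ~ N(0, h^2 / M_causal)`.
3. **Genetic values** — one downward product per trait; individual value =
   sum of its two haploid values (minus the centering scalar in
   standardized mode).  Multi-graph values are summed per individual before
   noise.
4. **Noise and assembly** — `eps ~ N(0, V (1/h^2 - 1))` with `V` the
   *sample* variance (denominator N−1) of the simulated individual genetic
   values of that trait; `h^2 = 1` gives exactly zero noise; degenerate
   (zero-variance) genetic values are an error when `h^2 < 1`.  Noise is
   drawn per trait independently; cross-trait environmental correlation is
   out of scope.  `phenotype = genetic_value + noise`, exactly.
5. **Normalization** — `standard` rescales in place ((x − mean)/sd, ddof 1);
   `quantile` is the rank-based inverse-normal transform
   `Phi^{-1}((r - 0.5)/N)` with average ranks for ties, appended as
   `normalized_phenotype` so the raw column survives.  Normalization runs
   *after* the noise variance was computed from the unnormalized values, so
   the h² calibration refers to the pre-normalization scale.
6. **Binary traits** — standard-normalize the phenotype, then case iff the
   liability exceeds the *theoretical* Gaussian quantile `Phi^{-1}(1 - K)`.
   The theoretical (not empirical) quantile is used because the prevalence
   parameter targets the population, not the realized sample; the realized
   case fraction therefore fluctuates around `K` across replicates.  Binary
   simulation requires standardized mode, and re-binarizing an
   already-binary table is rejected.

### Random streams

One root seed; every stage and trait uses an independent substream derived
from `SeedSequence([seed, stage_code, trait_id])`.  Adding a trait or
re-running a later stage never perturbs earlier draws, and the end-to-end
wrapper is reproducible bit-for-bit from `(graphs, config)`.

### Schema note

The trait index is emitted under the column name `causal_mutation_id` in
every stage table, matching the established output schema of graph-based
phenotype simulators; read it as "trait id" grouping rows of a multi-trait
run.

## Synthetic data

`generate_matrix` draws, per mutation, a carrier count from a frequency
model — `uniform(a, b)` (frequency uniform in the band, count =
`round(f * 2N)`) or the neutral site-frequency spectrum (`P(k)
proportional to 1/k`, the infinite-sites expectation) — then assigns that
many carriers uniformly without replacement.  Columns are therefore
exchangeable and **unlinked**: no LD, no demography, no recombination map,
and positions are synthetic.  `generate_tree_grg` produces a random binary
coalescent-topology tree with mutations on uniform internal nodes,
emulating the hierarchical sharing of ancestry-derived graphs and
exercising multi-level accumulation.  Every generator is a pure function of
its spec, seed included.

A green calibration test establishes that the pipeline's algebra and
variance bookkeeping are correct on exchangeable unlinked genotypes; it
does not establish realism under LD, population structure, or
frequency-dependent architectures (the alpha model is a non-goal).

## Numerical choices

* Dense-oracle agreement is asserted at relative tolerance 1e-10;
  standardized-mode centering at 1e-9 absolute.
* Chromosome additivity is asserted *exactly* using integer effect sizes
  (all intermediates are integers, hence exact in floats); with real-valued
  effects, split-vs-merged agreement holds to summation-order round-off
  (~1e-15 relative), which the float-valued tests cover at 1e-12.
* The Monte-Carlo calibration checks (heritability, prevalence) use a
  3-standard-error band around the replicate mean with fixed seeds, so they
  are deterministic.
* Frequencies are integer carrier counts divided by 2N, hence exact.
* `.par`/`.phen`/GRG-lite writers print floats with `repr` (shortest
  round-trip form); the `.par` reader parses with round-trip precision, so
  write→read is lossless.

## Design choices on open points

* The per-site scale uses the square root, `sigma_i = sqrt(2 f_i (1 -
  f_i))`: the scaling matrix is the inverse *standard deviation*, and only
  with the root do standardized columns have unit variance and the
  `N(0, h^2/M_causal)` prior yield genetic variance `h^2`.
* The noise formula is applied identically in raw and standardized modes
  (variance always measured on the genetic values actually simulated).
* Mutation nodes that reach zero samples are permitted (frequency 0) but
  never eligible as causal sites.
* Missing or unphased VCF genotypes are rejected, not imputed: the graph
  encodes hard calls and no imputation policy is defined.
* `.phen` defaults to the headerless two-column GCTA dialect; a
  `fid_iid` dialect (family id duplicated) and an optional header are
  offered.
* `sim_phenotypes` defaults to standardized mode with all polymorphic sites
  causal when only a heritability is supplied — the one setting in which
  `heritability` alone fully specifies the effect-size model.

## Limitations

* The builder optimizes correctness, not size: on unlinked random matrices
  the flat graph has as many edges as the matrix has carriers, and the
  greedy pair factoring is quadratic-ish — practical at desk scale, not for
  biobank panels.  The runtime advantage of the graph route shows on
  hierarchical (tree-like) graphs, where shared ancestry collapses edges.
* Dosages, genotype likelihoods, missing data, dominance/epistasis,
  gene–environment interaction and case ascertainment are out of scope.
* VCF input requires phased diploid hard calls; BGEN/PLINK BED are not
  read.
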