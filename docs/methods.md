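# Methods

## Model

A Boolean network over genes `x_1 … x_n` assigns each gene a binary
activity and a transition function `f_i : B^n -> B`. We use the synchronous
update scheme throughout: `x_i(t+1) = f_i(x(t))` for all genes
simultaneously, so the dynamics are a deterministic map on the `2^n`
states and every trajectory ends in an attractor — a recurrent cycle of
states (a fixed point when the cycle has length 1). Truth tables are
addressed with the first listed input as the most significant bit; this
convention is fixed so serialized tables are portable. Attractors are
stored in canonical rotation (lexicographically smallest state first),
which makes attractors found from different start states comparable and
deduplicable. Exhaustive attractor search enumerates the full successor
map (vectorized over all states) and is refused above a configurable cap
(default 25 genes, i.e. 2^25 states); beyond that, sampled search follows
trajectories from uniform random start states with per-trajectory cycle
detection. Sampled search may under-count attractors with small basins —
that is an explicit part of its contract, and the analysis layer records
how many networks contributed no attractor. A SAT-based backend would be a
natural extension point but is not required by any analysis here.

## Binarization

Each gene's expression vector (log-normalized counts, any positive affine
scale) is converted to binary calls by a step-function fit in the family
of the BASC algorithms:

1. Sort the values and compute, by dynamic programming on quadratic
   segment costs, the optimal step function with `d` discontinuities for
   every `d` up to `min(n-2, 50)`.
2. In each step function, locate the *strongest* discontinuity: the one
   maximizing jump height divided by the two-segment (binarization) error
   at that position. Height alone is not enough — for large `d` the
   biggest raw jump is often a single-point outlier gap in a tail, while
   dividing by the split error anchors the score at the true boundary.
3. Place the threshold at the midpoint of the value gap at the *median*
   strongest-discontinuity location; calls are `value > threshold`
   (equality resolves to 0, fixed for reproducibility).

The cap of 50 discontinuities keeps the dynamic program at `O(50 n^2)`
per vector; the strongest jumps of higher-order step functions stabilize,
so the median location is insensitive to the cap for realistic cell
counts (tens to hundreds).

Significance of the step structure is assessed by a bootstrap test: the
observed statistic (mean normalized jump height of the strongest
discontinuities, after min–max normalization to [0, 1]) is compared to
the same statistic on `n_boot` (default 999) samples of equal size drawn
from the uniform distribution on [0, 1]; `p = (1 + #{null >= observed}) /
(n_boot + 1)`. The null depends only on the sample size, so it is cached
and a whole matrix pays the bootstrap cost once per cell count. Across
genes, p-values are Benjamini–Hochberg adjusted and genes with
`q >= alpha` (default 0.05) are dropped. A constant vector is
non-binarizable by definition (`p = 1`).

**Known limitation.** The uniform reference null is well calibrated for
noise without step structure on a bounded range; heavier-tailed unimodal
data (e.g. Gaussian) can over-reject, because its extreme gaps look
step-like relative to a uniform sample. The significance filter is
therefore a screen against structureless genes, not a general test of
bimodality. A cheap alternative strategy (`kmeans2`: optimal 1-D
two-cluster split, threshold at the midpoint of the cluster means) is
available behind the same interface and significance machinery.

## Pseudo-time tuples

Cells of one individual are treated as interchangeable snapshots of a
population that moves between activity states; any cell may act as the
predecessor or successor of any other. With `s` cells there are
`C(s, 2) = s(s-1)/2` couples and, with both orders allowed, `s(s-1)`
ordered tuples (for `s = 94`: 4371 couples, 8742 tuples). A
reconstruction run draws `n_pairs` (default 1000) ordered tuples
uniformly, by default without replacement within a replicate (1000 of
8742 in the reference setting); a with-replacement flag exists. The draw
is repeated over `n_replicates` (default 20) independent replicates with
seeds `master_seed + r` for replicate `r` — an explicit, documented
derivation, never global RNG state. Self-pairs are excluded, which is
what makes the tuple count `s(s-1)`.

The package deliberately performs no trajectory inference; the point of
the tuple construction is to avoid assuming a pseudotemporal ordering.
For data that *are* ordered (simulated series, trajectory-structured
fixtures) the pipeline offers a `consecutive` pairing mode that forms
transition pairs from successive measurements within a trajectory,
subsampling `n_pairs` of them per replicate. Cell identifiers ending in
`_s<step>` with a shared prefix mark trajectory membership; otherwise
column order is used.

## Filtered best-fit reconstruction

For each target gene independently:

1. **Input pre-filter.** Pearson correlation `r` between each candidate
   input's predecessor values and the target's successor values across
   all transition pairs. Inputs with `|r| >= threshold` (default 0.03)
   survive; the absolute value keeps monotone-decreasing (inhibitory)
   regulation, which is exactly as informative as activation under the
   monotonicity rationale of correlation screening. Zero-variance inputs
   have undefined `r` and are excluded. Survivors are sorted by `|r|`
   (ties broken by gene order) and truncated to `max_candidates`
   (default 16, chosen so that the subset enumeration below stays within
   `C(16,5) ≈ 4.4·10^3` subsets per gene).

2. **Best-Fit Extension.** Every subset `X'` of the surviving inputs with
   `|X'| <= k_max` (default 5), including the empty subset, is scored
   through its partially defined Boolean function: each pair contributes
   its input pattern to the true set T (successor bit 1) or false set F
   (successor bit 0), and the error is
   `epsilon = sum_patterns min(count_T, count_F)` — the minimal number of
   misclassified observations achievable by any Boolean completion. This
   weighted multiset reading is what "least error" minimizes over
   completions; an unweighted variant counting distinct conflicting
   patterns is available (`error_mode="distinct"`) for comparison.

3. **Truth-table fill.** For every subset achieving the global minimum
   `epsilon`: patterns observed only in T become 1, only in F become 0,
   conflicting patterns resolve to the majority output with ties to 0
   (minimizing realized error deterministically), and unobserved patterns
   are expanded over every completion while the completion count stays
   within `cap` (default 1024) — beyond that a single majority-filled
   table is kept and the candidate set is flagged `capped`. Candidates
   from all minimal subsets are pooled without minimality pruning and
   deduplicated; the pooled list is itself truncated at `cap`. Because
   the empty subset (a constant function) always competes, every gene has
   at least one candidate; genes whose pre-filter retains nothing become
   constants at the majority successor value and populate the fixed-gene
   metric. Self-inputs are allowed as candidates.

At threshold 0 the pre-filter passes every non-constant input, so the
filtered search coincides with the plain Best-Fit Extension — this filter
soundness, and the equality of the minimal `epsilon` with a brute-force
search over all subsets and all truth tables, are enforced by tests.

## Ensembles

A concrete network is sampled from the candidate sets by drawing, per
gene, one candidate uniformly at random; `n_networks` (default 100)
networks per replicate and `n_replicates` (default 20) replicates yield
2000 networks per individual in the default configuration. Draws are with
replacement across networks (candidate spaces can be smaller than the
ensemble) and unweighted (all candidates share the minimal error by
construction). Sampling seeds derive from the master seed by the same
`master_seed + replicate` scheme; a JSON manifest of per-network choices
allows exact replay.

## Analysis

* **Fixed genes**: constant-function genes per network, averaged over the
  ensemble. **Isolated genes**: zero in-degree *and* zero out-degree in
  the network's interaction graph; a constant gene that still regulates
  others is fixed but not isolated. **Mean input**: mean in-degree over
  genes and networks. **Mean functions**: mean candidate-list size over
  genes.
* **Adjacency**: entry `(i, j)` is 1 iff gene `i` appears in the
  regulatory function of gene `j`; union matrices take the union over
  candidate functions and over replicates (monotone in replicates).
* **Motifs**: feed-forward loops (ordered distinct triples A→B, A→C,
  B→C) and bi-fans (unordered regulator pair × unordered target pair,
  all four distinct, all four edges present), self-loops ignored; counts
  are computed from the adjacency algebraically and verified against a
  brute-force subgraph enumerator.
* **Attractor statistics**: mean attractor count per network and the
  per-network mean attractor length, each averaged over networks and
  replicates; networks where sampled search found nothing are excluded
  and counted.
* **Activity probabilities**: per network, all attractor states are
  pooled and the fraction of states with the gene active is taken; the
  result is averaged over networks, then over replicates. The pooled
  reading (rather than averaging per attractor first) weights each
  attractor by its length; it follows directly from normalizing summed
  binary states by the total number of attractor states.
* **Group comparison**: rank-based two-sample tests per metric with
  optional Bonferroni correction. The independent-samples rank-sum test
  is the default because individuals in different age groups are not
  paired; the paired signed-rank test is available (`paired=True`) for
  designs that do induce pairing. SciPy supplies exact p-values for
  small tie-free samples and a normal approximation otherwise. All-tied
  metrics yield `p = 1` with a warning.
* **Reference match**: reconstructed edges are validated against an
  offline undirected interaction table (a STRING-like export, optionally
  score-filtered). A network edge matches (+1) when the reference
  connects the genes directly or through exactly one intermediary;
  otherwise it is a mismatch (−1); non-edges are 0. The match fraction is
  `#(+1) / #(±1)`. Genes absent from the reference contribute no
  reference edges and are reported.

## Benchmark harness

Ground-truth networks are random Boolean networks with in-degrees drawn
from a truncated power law `P(k) ∝ k^(-gamma)` on `1..k_max` (defaults
`gamma = 2.5`, `k_max = 3`), inputs chosen uniformly without replacement,
and truth tables uniform over tables in which *every listed input is
essential* — a fictitious input would make the declared topology
meaningless for edge-recovery scoring. Synchronous series of 20 or
`n + 10` time points are simulated from random starts; observation noise
is modeled as independent bit flips on the observed series (rate < 0.5)
applied after simulation, so a corrupted state appears consistently in
both pairs it participates in. Edge recovery of the candidate-union
adjacency is scored as sensitivity and specificity over all `n^2` ordered
pairs (self-loops included by default; a flag excludes them). Plain
best-fit is the threshold-0 configuration with no candidate truncation,
so the filtered and plain arms differ only in the pre-filter. Runtime is
reported per method but is hardware-dependent and not a correctness
contract.

## Synthetic data generator

The fixture generator emulates exactly the two data properties the
pipeline relies on: (a) bimodal per-gene expression — binary activities
mapped through two Gaussians `N(0, sd)` / `N(sep, sd)` with default
separation 6 sd, comfortably recoverable by the step fit; and (b) cells
that are states of a known Boolean network, collected along synchronous
trajectories from uniform random starts (default 8–12 states per
trajectory), with identifiers recording trajectory membership. Optional
exactly-constant genes exercise the significance filter (mirroring a
101-gene panel of which 96 binarize).

What it does *not* emulate: sequencing dropout and zero inflation,
depth/library-size variation, asymmetric or heavy-tailed noise, doublets,
batch effects, or continuous intermediate expression states. Passing
recovery tests therefore demonstrates the correctness of the inference
machinery on data satisfying the model's assumptions, not the fidelity of
any particular biological reconstruction.

One structural point deserves emphasis: ordered pairs of *independently*
drawn cells carry no transition signal in this generator — the successor
cell is statistically independent of the predecessor, so correlations
between predecessor inputs and successor targets vanish by construction.
Recovery tests therefore run the pipeline in `consecutive` pairing mode
on trajectory-structured fixtures, where pairs are genuine synchronous
transitions. The `random` pseudo-time mode is the intended mode for real
single-cell snapshots, whose biological premise (cells transiting between
observed states) is precisely what the generator's independence
assumption does not model.

## Problem sizes in tests and acceptance

The test suite and the acceptance script run scaled-down configurations
chosen for coverage per unit time: oracle equivalence on up to 8 genes /
64 pairs / `k_max` 3 (where the brute-force table enumeration is exact
and fast), noise-free recovery on 10-gene networks with all `2^10` input
patterns observed, attractor completeness on up to 10 genes, and the
end-to-end fixture on a 15-gene truth network with 480 cells in 40
trajectories, 3 replicate draws of 440 consecutive pairs, 10 networks
per replicate, and a 199-resample bootstrap. Library defaults remain at
the full-scale reference configuration (1000 tuples, 20 replicates, 100
networks, 999 bootstrap resamples, threshold 0.03, `k_max` 5).

## Numerical choices and degenerate inputs

Ties at the binarization threshold resolve to 0; conflict ties in the
truth-table fill resolve to 0; candidate input order is `|r|` descending
with gene order breaking ties; attractor cycles rotate the smallest state
first; all stochastic stages take explicit integer seeds and replicate
seeds are `master_seed + replicate`. Degenerate inputs have defined
behavior: constant expression vectors are non-binarizable (`p = 1`), an
all-dropped gene set is an error, a zero-variance target successor
yields a constant function, an empty pair list yields a constant-0
fallback at error 0, and `n_pairs` exceeding the ordered-pair total
without replacement is an error.

## Limitations

Sampled attractor search under-counts small basins; the binarization
significance test is calibrated against a uniform null only; pooling all
minimal-error subsets (no minimality pruning) deliberately inflates the
union adjacency with supersets of informative inputs, trading specificity
for candidate completeness — union-adjacency specificity is therefore low
when data are abundant and many subsets tie at the minimum; and the
Wilcoxon comparison of unpaired groups defaults to the rank-sum form,
which is a deliberate deviation from naming conventions that apply the
signed-rank test to unpaired data.
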