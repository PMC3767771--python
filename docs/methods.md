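# Methods

## Model and assumptions

The input is a regulator × target matrix of normalized z-scores, assumed to
be centred and scaled so that a standard-normal tail is a meaningful reference
for a single entry (that assumption is only used by the convenience mapping
between a threshold `t_B` and a two-sided p-value; the method itself never
relies on normality). Thresholding at `t_B` produces a bipartite graph with
UP (`z ≥ t_B`) and DOWN (`z ≤ −t_B`) edges. Comparisons are inclusive; at
`t_B = 0` an exact zero is classified UP by the `≥` rule, and a warning is
emitted because that boundary is rarely intended. Missing matrix entries
produce no edge. A (regulator, target) pair has one z-score, hence at most
one edge — this single-edge constraint shapes the null model below.

The quantity of interest is the co-occurrence of two same-side nodes: the
number of opposite-side neighbours they share, split into three patterns
(co-up, co-down, and the directed antagonistic pattern whose source is the
down-linked member). The null hypothesis is that an observed co-occurrence is
explained entirely by the per-node counts of up- and down-regulations. The
null distribution is the uniform distribution over simple bipartite graphs
with the observed per-type degree signature at every node.

## Null sampling and empirical p-values

Null graphs are sampled by a Markov chain of same-type edge swaps. One
attempt: draw an edge type with probability proportional to its edge count
(per-type counts are invariant under swaps, so these probabilities are fixed
along the chain), draw two distinct edges `(a,b)`, `(c,d)` of that type
uniformly, and accept the swap to `(a,d)`, `(c,b)` only if neither target
slot carries an edge of either type. Rejected attempts are self-loops of the
lazy chain; because the proposal is symmetric, the stationary distribution is
uniform over the chain's reachable state space. One continuing chain starts
at the observed graph; a state is recorded every `swaps_per_sample` attempts
(default `10 × |E|`; burn-in equals one inter-sample gap). For every pair and
pattern, `p_emp = (# samples with count ≥ observed) / N`, computed exactly —
counts are integers, so no tolerance is involved. Pairs with zero observed
co-occurrence receive `p_emp = 1` identically. An optional add-one-smoothed
estimator `(x+1)/(N+1)` is *not* applied here (the plain ratio is reported);
downstream corrections are the user's choice, and no multiple-testing
correction is applied.

Counting is vectorized: with biadjacency indicators `U` and `D`, the
target-side count matrices are `UᵀU`, `DᵀD` and `DᵀU` (regulator-side:
`UUᵀ`, `DDᵀ`, `DUᵀ`), and the exceedance accumulators are whole-matrix
comparisons per sample. The swap engine keeps per-type endpoint lists plus a
flat occupancy byte array, and consumes three pre-drawn uniforms per attempt,
which makes sample sequences bit-reproducible for a fixed seed.

**Known limitation (reducibility).** With a single edge type, the swap chain
connects the full space of degree-compatible bipartite graphs. With two edge
types and the cross-type conflict rule this is not guaranteed: there are
small instances whose swap graph splits into several communicating classes,
and the sampler is then uniform only on the class containing the observed
graph. The test suite verifies uniformity against exhaustive enumeration of
the reachable class (computed by an independent breadth-first search over
swap moves) on small instances, and verifies that for the single-type
demonstration instance the class is the full 5-graph space. On large, dense
biological graphs the practical effect is expected to be minor, but p-values
should be read as "relative to degree- and swap-reachable graphs".

## Projection, threshold scan

The co-regulation graph retains pairs with `observed ≥ 1` and
`p_emp ≤ τ_P` (inclusive retention). Rather than fixing `τ_P` by rule of
thumb, a scan over a τ grid reports four topology metrics of the pattern's
projection (antagonistic direction ignored): edge count normalized to the
grid maximum; number of connected components with ≥ 2 nodes (isolated nodes
are not components); mean per-component density (component edges divided by
`C(size, 2)`), reported raw and normalized to its own grid maximum — the
normalization of this curve is genuinely ambiguous in the underlying
description, so both forms are emitted; and the average local clustering
coefficient, with degree < 2 nodes contributing 0. A grid point is flagged
when clustering *and* normalized component density each show a local maximum
or a forward difference at or above a configurable quantile (default 0.75) of
that metric's differences, while the component count stays at or above a
configurable floor (default 5). "Strong increase" has no canonical
quantitative definition, hence the quantile is configuration, not a constant.
Suggestions are advisory; the full scan table is always written.

## Artificial benchmark

The generator plants five modules, each with 8 up-regulated and 8
down-regulated targets and 58 regulators with a strongly skewed degree
histogram — per module 10 hubs of degree 16, 8 regulators of degree 4, 40 of
degree 2 (all overridable). Each regulator's edges split half UP into the
module's up-group and half DOWN into its down-group (odd degrees alternate
the extra edge's type deterministically), with endpoints drawn uniformly
without replacement within the group. Target degrees are emergent and
approximately Poisson (binomial draws, slightly under-dispersed because
endpoints are drawn without replacement). The gold standard follows from the
construction alone and is independent of the seed: all within-group up pairs
are co-up positives (5·C(8,2) = 140 of C(80,2) = 3160 unordered pairs),
likewise co-down; all ordered (down-member, up-member) within-module pairs
are antagonistic positives (5·64 = 320 of 80·79 = 6320) — a ≈ 20:1
negative:positive imbalance for every pattern.

The hub count deserves a note, as it is the one structural choice that the
detection guarantee hinges on. Every planted pair is covered by all of its
module's hubs, so its minimum co-occurrence equals the hub count H. Under
the degree-preserving null, a configuration-model calculation gives the
expected co-occurrence of a planted pair as roughly
`d_a · d_b · Σ_r d_r(d_r−1) / m²` ≈ 1–2 with these sizes; detection at
`τ_P = 0.01` therefore requires the Poisson tail `P(count ≥ H)` at that mean
to sit well below 0.01. With H = 10 the tail is ≲ 10⁻⁴ even for
above-average target degrees, so the planted structure is recoverable
perfectly in the absence of noise; with 2 hubs (minimum count 2) the tail is
0.06–0.13 and perfect recovery is mathematically impossible at that
threshold. The histogram remains strongly skewed: 40 of 58 regulators per
module have degree 2.

Noise: `delete_edges` removes `round(p/100 · |E|)` uniformly chosen edges
(false negatives); `add_edges` inserts `round(p/100 · |E|)` edges into
uniformly chosen vacant slots, typed UP with probability 0.5 by default
(real screens skew towards down-regulation; the bias is a knob). Rounding is
round-half-to-even. Both return copies — the pristine graph and gold
standard are retained for scoring.

What the benchmark does *not* emulate: correlated noise (antibody batch
effects hit whole rows/columns, not uniform random entries), cross-module
regulation, hub targets on the protein side, and any dependence between edge
sign and magnitude. Passing the benchmark shows the statistic and the null
model behave as designed under degree-preserving randomness, not that every
real screen satisfies those assumptions.

## Evaluation

Predictions at a threshold are scored by the F-score (harmonic mean of
precision and recall; defined as 0 when tp = 0). PPV_n ranks all candidate
pairs by `p_emp` ascending, breaking ties by observed count descending and
then by a fixed pseudorandom key (CRC32 of the pair label). The key — rather
than a lexicographic comparison of node labels — matters in the fully tied
regime (e.g. an empty graph): module-structured labels sort same-module pairs
together, which would bias PPV_n away from the prevalence baseline that a
random ranking attains in expectation; a fixed hash order is reproducible and
exchangeable with respect to any label structure. With `n = |gold
positives|`, PPV_n equals the sensitivity of the induced top-n prediction —
an identity the tests assert on randomized tables. The antagonistic candidate
universe is ordered pairs; reversed arrows count as one false positive plus
one false negative.

The robustness experiment regenerates the benchmark, perturbs it per noise
type and level, runs the full pipeline (default 1000 null samples,
`τ_P = 0.01` — 0.01 is the default significance rule of thumb for the
F-score cut and is configurable), and records F-score and PPV_n per pattern
with all derived seeds logged.

## Enrichment

The seed of a mature miRNA is the 6-mer at 1-based positions 2–7; T is
auto-converted to U with a warning. Distances are unit-cost Levenshtein
(computed by edlib; tests cross-check a full dynamic-programming oracle).
Group similarity is the mean pairwise distance. The permutation test draws
`n_perm` (default 10 000) uniform same-size subsets of the eligible universe
and reports the add-one-smoothed p-value `(1 + #{null ≤ observed})/(n_perm + 1)`
— smoothing keeps finite-permutation p-values strictly positive — plus the
null median and 95% band. Groups of equal size share one null sample, so a
smaller observed similarity never receives a larger p-value. Family
over-representation uses the upper-tail hypergeometric probability
`P(X ≥ k)`; the population is the caller's choice (miRNAs in the analysed
projection by default, all miRNAs passing the z-score threshold as the
documented alternative — the right urn is context-dependent and deliberately
not hard-coded).

## Numerical and reproducibility choices

All stochastic operations take an explicit seed or `numpy` generator; chain
seeds derived inside compound experiments come from `SeedSequence` spawning
and are logged. Problem sizes used by the shipped tests and the acceptance
script: 10 000 null samples on the enumerable demonstration instances, 1000
samples for benchmark recovery and robustness, 5 generator seeds across
deletion levels {0, 25, 50, 75, 100}%. Matrix counting uses float32 matmuls,
exact for counts below 2²⁴. CLI exit codes: 0 success, 2 usage error,
1 runtime error; logs go to stderr, data to files.
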