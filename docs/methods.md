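# Methods

## The signal-to-network mapping

`conect` treats a finite, uniformly sampled amplitude series
x₀ … x_{n−1} as the node set of a directed graph on the time indices.
The chord angle between samples a < b is

    θ_ab = arctan( (x_b − x_a) / (b − a) ),

with time measured in sample-index units. An edge i → j (j > i) exists
iff θ_ik < θ_ij **strictly** for every intermediate k; the condition is
vacuous for j = i + 1, so consecutive samples always connect and the
graph contains the time-ordered chain. Because arctan is monotone, the
rule is equivalent to requiring every intermediate sample to lie strictly
below the straight chord from (i, x_i) to (j, x_j) — the left-to-right
natural-visibility criterion. That equivalence is exploited twice: as an
independent test oracle, and in the O(n²) construction, which for each
source i scans targets left to right keeping the running maximum of the
chord slopes and connects exactly at the record values. A literal O(n³)
transcription of the quantified condition is kept in the public API
(`arc_edges_bruteforce`) purely as a cross-check; the two are asserted
equal on randomized batteries in the test suite.

Ties (exactly collinear triples) do **not** connect; this makes the
constant series produce a clean chain. Topology is invariant to adding a
constant to all amplitudes and to rescaling all amplitudes by a positive
factor (both sides of the chord inequality scale together); it is *not*
invariant to changing the amplitude scale relative to the sample step in
any way that alters ties, and edge weights (below) are scale-covariant.
In floating point, translation invariance holds only when the shift does
not absorb sub-epsilon amplitude differences; the property test uses
integer amplitudes, where the arithmetic is exact.

### Edge weights

Each edge carries

    w_ij = α·|x_j − x_i| + β·1/(j − i) + γ·|θ_ij|,

defaults α = 0.5, β = 0.3, γ = 0.2. The absolute values are a design
choice: the formula is used downstream as a nonnegative
strength/cost, and Gini, efficiency and strength semantics assume
w ≥ 0. A `signed_weights` flag exposes the signed variant for
sensitivity work. With β > 0 every weight is strictly positive. The
documented exploration grid (α ∈ {0.3…0.7}, β ∈ {0.1…0.4},
γ ∈ {0.1…0.3}) is exported as `arc_network.PARAM_GRID`.

## The 15-feature vector

Features 1–13 are classical descriptors, 14–15 the geometric indices.
Indices (1-based) and conventions:

| # | feature | convention |
|---|---------|-----------|
| 1 | edge count | |E| |
| 2 | edge-weight kurtosis | population moments, excess (−3), 0 if σ = 0 |
| 3 | edge-weight mean | |
| 4 | edge-weight skewness | population moments, 0 if σ = 0 |
| 5 | edge-weight variance | population (1/|E|) |
| 6 | Gini index | Σ|w_i − w_j| / (2·|E|²·μ); 0 for equal weights |
| 7 | global efficiency | Σ_{i≠j} d_ij⁻¹ / (N(N−1)); unreachable pairs add 0 |
| 8 | modularity | greedy (CNM) partition, weighted objective |
| 9 | weighted average degree | 2·Σw / N (undirected strength mean) |
| 10 | average degree | 2|E| / N |
| 11 | average betweenness | weighted, endpoints excluded, ÷ (N−1)(N−2)/2 |
| 12 | average node strength | identical to 9 by definition; both emitted for table fidelity |
| 13 | average path length | mean d_ij over reachable ordered pairs |
| 14 | WAII | mean over nodes of population std/mean of *outgoing* weights; 0 if out-degree ≤ 1 |
| 15 | CBEFI | mean over edges of κ_ij = \|x_j − 2x_k + x_i\| / (j−i)², k = ⌊(i+j)/2⌋ |

Path-based quantities and community detection run on the **undirected**
view with edge length = raw weight. The directed graph is a DAG, so every
right-to-left distance would be infinite, which would cap efficiency at
0.5 and leave the mean path length ill-defined; the pair sums in the
definitions above clearly intend reachable symmetric distances. WAII is
the one feature that keeps direction. An `inverse` weight→length mode is
not enabled by default; weight-as-cost is the documented convention.

The condition "|S_i| > 1" in WAII is read as out-degree greater than one
(a standard deviation of a single value is degenerate); the alternative
reading mean(S_i) > 1 would make the index depend on amplitude units.
κ's denominator uses sample units, consistent with the chord angles; a
global 1/fs² rescaling would shift all CBEFI values equally and cannot
change class contrasts. For adjacent edges the floor midpoint gives
k = i, so κ degenerates to |Δx|; CBEFI therefore blends first- and
second-difference magnitudes, dominated by the latter on longer edges.

Shortest paths, betweenness and the greedy modularity partition are
computed with igraph (C core); the tests verify agreement with networkx
to 1e-9 on randomized ARC networks, with the modularity objective
evaluated on the identical partition by both libraries. The greedy
agglomeration is deterministic, so no seed is involved in feature
extraction.

## Synthetic cohorts

`generate_segment` sums cosine components, AR(1) Gaussian noise (the
`noise_sd` parameter is the innovation sd, so stationary variance is
sd²/(1−φ²)), and Poisson-placed transients: symmetric triangular spikes,
a second wide-bump family, and asymmetric sawtooths (linear rise r
samples, linear decay d samples). Cohort seeding is counter-based
(master seed, class index, subject index, channel index via
`SeedSequence`), so any subset of a cohort regenerates identically in
isolation.

### The easy cohort

Three classes at 500 Hz emulating the qualitative contrasts of dementia
EEG subtypes: HC = 10 Hz + 0.3·20 Hz, AR 0.5, sd 0.2; AD = 6 Hz slowed
oscillation with smooth AR 0.9 noise; FTD = 10 Hz with sharp triangular
transients (2/s, amplitude 3, half-width 5). Default shipped shape:
10 subjects/class × 2 channels × 2,000 samples. These profiles make the
three classes separable by many features at once — the cohort validates
the plumbing (a Random Forest on all 15 features reaches ≥ 0.8 multiclass
accuracy over grouped splits), not the uniqueness of any index.

### The geometry cohort

This cohort is constructed so that each geometric index carries class
signal that the classical features cannot express, which is what makes a
selection-frequency analysis informative rather than an artifact of
fitness ties:

* **steep_rise** vs **steep_fall** differ only by time reversal of their
  sawtooth transients (12/s, amplitude 5, rise/decay 6/20 vs 20/6
  samples). Every classical feature is computed from the undirected graph
  view and absolute amplitude differences and is therefore blind to time
  reversal up to sampling noise (verified: a Random Forest on features
  1–13 sits at chance on this pair). WAII, which aggregates *outgoing*
  edge weights, separates the pair cleanly.
* **sharp** repeats steep_rise and adds narrow spikes (6/s, amplitude 3,
  half-width 1). Their curvature is what CBEFI measures; the classical
  moment features that would otherwise detect them (weight skewness,
  kurtosis, Gini) are scrambled by per-subject nuisance draws shared by
  all classes — oscillation frequency U(7, 13) Hz, AR coefficient
  U(0.45, 0.65), and wide low-curvature bumps (width 25, rate U(1, 5)/s,
  amplitude U(3, 10)) whose heavy amplitude tails dominate the weight
  distribution without contributing curvature.

Default shape: 8 subjects/class × 1 channel × 2,000 samples. On this
cohort, removing WAII or CBEFI from the feature pool measurably drops the
attainable cross-validated accuracy, so the ant-colony wrapper retains
both indices in every run — the mechanism behind the 100% selection
frequencies the test suite asserts.

Neither cohort attempts realistic EEG spectra, amplitude ranges,
artifacts, or clinical effect sizes. Passing tests on them demonstrates
that the pipeline detects the geometric properties it claims to measure
under controlled conditions, not that those properties separate clinical
populations.

## Ant-colony feature selection

The wrapper keeps one pheromone level τ_f per feature (τ init = 1). Each
ant draws a subset size uniformly in [4, 8] and samples that many
distinct features with probability ∝ τ. Every sampled subset is scored by
stratified, subject-grouped k-fold cross-validation of a seeded Random
Forest restricted to those columns (fitness values are memoized per
subset within a run). After each iteration τ ← (1−ρ)·τ with ρ = 0.1, and
the iteration-best subset's features receive τ_f += Q·fitness with
Q = 1. The returned subset is the best ever observed; the best-so-far
trace is nondecreasing by construction, and ties keep the earliest
subset found. No heuristic-desirability term is used by default
(`use_heuristic` enables an ANOVA-F term). Defaults are 30 ants and 50
iterations; the end-to-end tests and the acceptance script use smaller
colonies (6–8 ants, 6–10 iterations, 3-fold fitness, 50–100-tree fitness
forests) — sizes chosen so the full-pipeline checks run at desk scale —
while the planted-optimum recovery test runs the full 30 × 50
configuration against an exhaustively enumerated optimum.

The selection-frequency analysis (`selection_frequency`) repeats the
colony with independently derived sampling seeds but evaluates fitness
with the *master* seed throughout, so every run searches one
deterministic fitness landscape and the reported frequencies measure
search variability, not cross-validation resampling noise; this also
lets fitness values be memoized across runs. Injecting a custom fitness
function bypasses the classifier entirely (used by the planted-optimum
tests).

## Evaluation harness

Two split modes: `stratified_record` (row-level, class proportions
preserved) and `grouped_subject` (default; whole subjects on one side,
per-class subject allocation, bounded redraws if a class would end up
one-sided). Feature selection, when enabled, runs on the training side
only. Metrics follow the confusion-table definitions exactly; multiclass
reports are one-vs-rest macro averages, and zero-denominator ratios
report 0 with a logged flag instead of NaN. Of the five classifiers,
k-NN and RBF-SVM see z-scored features (scaler fit on the training
side); tree ensembles see raw features. AdaBoost uses depth-1 stumps and
bagging uses unpruned trees — conventional defaults, stated rather than
inferred. The ablation table reuses one train/test split per task across
all five feature configurations so its rows are paired comparisons; the
CV grid evaluates a seeded Random Forest over trees × folds with
grouped, stratified folds.

## Numerical notes and limitations

* Strict inequality in the edge rule means amplitude quantization
  (e.g., integer µV storage) can create ties and withhold edges that
  infinitesimal noise would admit; this matches the printed rule and is
  deliberate.
* The Gini implementation returns exactly 0 for an all-equal weight
  multiset, avoiding ~1e-17 float residue from the sorted-rank formula.
* Degenerate weight distributions (σ = 0) define skewness and kurtosis
  as 0, keeping feature vectors finite on constant segments.
* Feature extraction cost is dominated by all-pairs Dijkstra and
  weighted betweenness, ~2–3 s per 2,000-sample segment on one core;
  the ARC construction itself is ~50 ms.
* Group-aware CV with very few subjects per class is noisy; fitness
  plateaus produce ties the wrapper resolves by first discovery, which
  is why selection-frequency claims are only meaningful on cohorts where
  the geometric indices carry unique signal (see above).
* EDF/EEGLAB readers pass amplitudes through in µV as declared by the
  file; plain-text input has no unit declaration and is used as-is with
  a logged warning. ARC topology is scale-invariant but edge weights are
  not, so mixed-unit cohorts must be harmonized upstream.
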