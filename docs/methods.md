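# Methods

This note documents the models and procedures implemented in `beadcomp`,
the parameter defaults and why they are what they are, the numerical
choices, and the limits of what the synthetic benchmarks establish.

## Compositional annotation by unbalanced optimal transport

**Model.** Beads and reference categories are treated as two mass
distributions: bead *i* carries its read mass *a_i*, category *c* its
prior frequency *b_c* (the category's cell frequency in the reference).
Annotation is the entropic, semi-relaxed transport plan

    min_P ⟨C, P⟩ + ε KL(P | a⊗b) + ρ KL(Pᵀ1 | b)   s.t.  P1 = a,

with cost `C(i,c) = 1 − cosine(bead profile i, category profile c)`.
The bead marginal is exact — every read is assigned — while the category
marginal is only penalized: tissue composition may drift from the
reference frequencies ("unbalanced"), at a price set by ρ. Larger ρ pulls
aggregate inferred frequencies toward the priors (verified monotonically
in the tests); ρ → 0 removes the prior entirely and each bead is assigned
independently by soft cost minimization.

**Solver.** Log-domain Sinkhorn iterations on the dual potentials, with
the relaxed-side update damped by the exponent ρ/(ρ+ε); a final exact row
scaling enforces `P1 = a` to machine precision. Log-domain arithmetic is
required: at ε = 0.005 the kernel `exp(−C/ε)` underflows for most cost
entries. Convergence tolerance 1e-9 on the potentials, 500 iterations
maximum; the problems solved here (≤ a few thousand beads × ≤ tens of
categories) converge in well under that.

**Cost function.** The cosine cost is a deliberate choice: it is
scale-free (bead depth and profile normalization drop out) and standard
for expression matching. Any cost bounded on [0, 2] with the same minimum
structure behaves equivalently under the bisectioning scheme.

**Bisectioning.** A single transport step under-calls minor
contributions: with near-orthogonal profiles, the per-bead cost landscape
is steep and the plan concentrates on the dominant category. Bisectioning
(default 4 rounds, divisor 3) therefore commits only (divisor−1)/divisor
of each bead's transported mass per round, subtracts the committed
reconstruction (committed mass × category profile) from the bead profile,
clips at zero, and re-annotates the residual; the final round commits
everything. The residual after subtracting the dominant category is
enriched for the remaining contributions, so later rounds see them at
full contrast. With divisor → ∞ and one round this reduces to plain OT;
mass bookkeeping guarantees termination. The same scheme (4 ÷ 3) is used
for program annotation at ε = 0.01: without it, fractional program
activity collapses to hard assignments (mean L1 error vs planted truth
≈ 0.6 instead of ≈ 0.05 at depth 500).

**Platform normalization.** Bead platforms and scRNA-seq capture genes
with different efficiencies. Before computing costs, reference profiles
are rescaled per gene by (target pseudo-bulk gene fraction)/(reference
pseudo-bulk gene fraction), clipped at 100; genes absent from the target
get factor 0 (ignored), genes absent from the reference keep factor 1.
The reference is rescaled rather than the query, so bead counts stay
integer for downstream splitting.

**Count splitting.** Gene *g* of bead *i* is apportioned across
categories proportional to `composition(i,c) × profile(c,g)`, falling
back to the composition alone when every weighted profile is zero for
that gene. Largest-remainder integer rounding makes conservation exact:
the per-category matrices sum to the input counts identically, which the
tests assert on random fixtures. Compartment aggregation keeps only beads
with ≥ 50 counts assigned to the compartment — below that, a bead's
compartment profile is mostly shot noise.

## Expression programs (integrative NMF)

Per-batch matrices are decomposed as `X_d ≈ H_d (W + V_d)` with
non-negative shared loadings `W` (the programs), batch-specific loadings
`V_d`, and usages `H_d`, minimizing
`Σ_d ‖X_d − H_d(W+V_d)‖²_F + λ Σ_d ‖H_d V_d‖²_F`. λ prices
batch-specific expression: as λ grows, ‖V_d‖ → 0 (asserted over
λ ∈ {1, 5, 25}). Defaults k = 20, λ = 5. The input is count-like
(library-size normalized, **no** log transform): programs are additive
expression profiles whose weighted sum approximates the cells.

The optimizer is block-coordinate HALS — exact non-negative minimization
of each factor row/column given the rest — so the objective is
non-increasing by construction, which the tests assert on every run.
Initialization is uniform random scaled to the data magnitude; restarts
are seeded and the best objective kept (recovery benchmarks use 5
restarts). Convergence: relative objective change ≤ 1e-5 (tunable), with
a warning carrying the final relative change on non-convergence. The
count-like corrected matrix is `H_d · W` with the batch term dropped; it
is non-negative, preserves all-zero genes, and is invariant to batch
relabelling.

## Spatial statistics

**Neighborship z-scores.** For categories (a, b), the observed statistic
is Σ over unordered within-puck bead pairs within `max_distance` (default
20 µm) of `f_a(i)f_b(j) + f_b(i)f_a(j)` — computed as `Fᵀ A F` with the
symmetric pair adjacency. The null permutes whole composition rows across
beads within each puck (coordinates fixed), preserving per-puck
composition margins and the spatial geometry; z = (obs − mean)/sd over
permutations (sample sd). Entries with zero permutation sd are reported
missing, never as 0. Pairs never cross pucks; the statistic is invariant
to bead order and rigid motions of the coordinates. An exhaustive mode
enumerates all row permutations for small inputs and is tested against an
independently coded oracle.

The analysis default of 10 permutations follows the original parameter
set and suffices for signs and large |z|; the *calibration* benchmark
uses 100 permutations, because with n permutations the z statistic is
t-like (heavier-tailed than normal at n = 10, ~9% beyond ±1.96) and only
approaches its nominal 5% tail rate as n grows. Sign stability of |z| > 3
entries across n ∈ {5, 10, 50} is asserted separately.

**Co-occurrence.** `cooc(a,b,d) = [Σ f_a(i)f_b(j) / Σ f_b(j)] / mean(f_a)`
over ordered pairs in half-open distance bins `[kΔ, (k+1)Δ)` (defaults
Δ = 20 µm up to 1000 µm); ≈ 1 everywhere under spatial uniformity.

**Annotation distance.** Per bead, the smallest binned radius at which
cumulative target-annotation mass reaches `critical_neighbourhood_size`
(default 4.0; bins of 10 µm up to 100 µm); never-reaching beads are
censored at `max_distance` and kept by the downstream ≥ 75 µm restriction
(censored = far from the target).

## Region discovery

Spatial k-NN graphs are built per puck, an expression k-NN graph across
all pucks on √program-weights — Euclidean distance on the square-rooted
simplex ranks neighbours by the Bhattacharyya coefficient Σ√(p_i q_i) —
both as binary adjacencies symmetrized by union (k = 15 each). Leiden
(modularity with resolution 1.3, fixed seed) runs on
`w·A_space + (1−w)·A_expr`, default w = 0.7. Cross-puck region identity
comes entirely from expression edges. With w = 0 the labels equal Leiden
on the expression graph alone (asserted exactly); with w = 1 regions
respect spatial components. Unlabelled beads inherit the label of the
Euclidean-nearest labelled bead on their puck, distance ties resolved to
the smallest bead id.

The recovery benchmark plants 8 horizontal layers (6 grid rows of 30 µm
each, 10 columns, 2–3 pucks, adjacent-program 0.7/0.3 mixtures, Dirichlet
concentration 30, depth 600) and requires ARI ≥ 0.8 at the default
parameters; in this regime recovery is exact across seeds. The geometry
matters: modularity at resolution 1.3 has a natural cluster granularity,
and very thin layers get over-split while very small pucks cluster by
puck — a genuine property of resolution-based community detection on k-NN
graphs, not an implementation artifact, and the reason the benchmark
tissue uses thick layers.

## Compositional statistics and spatial patches

**Log-ratio transforms.** CLR: `log(x_i/g(x))` after closure, rows sum to
0 (1e-10); ALR: `log(x_i/x_ref)` against a designated reference category.
Zeros are replaced before closure by half the smallest positive value of
the row (a constant-pseudocount alternative is available); the choice only
matters for rare categories and is recorded with the results.

**Enrichment.** Two-sided Welch's t per category on CLR-transformed
sample-level compositions, BH FDR across categories. Under exchangeable
Dirichlet nulls the per-category type-I error at α = 0.05 is within the
binomial CI over 1000 replicates (the closure dependence between
categories is mild at the tested dimensions).

**Patches.** Beads within a puck are spatially correlated; treating them
as independent observations collapses p-values. Each puck (then each
patch, for `n_iterations = 2`) is split at the median projection onto the
first principal axis of its bead coordinates; beads strictly within
±200 µm of the split are permanently discarded (400 µm boundary band ≈
twice the distance over which bead-bead correlations decay in the
motivating data); patches under 100 beads are flagged unusable. Median
split balances patch sizes; boundary-equal beads are kept. Patch-level
testing takes the mean of a per-bead field over each usable patch and
compares groups with a two-sided Mann-Whitney U across patches, BH across
fields. The calibration benchmark draws independent Gaussian random
fields (squared-exponential covariance, length scale 200 µm, exact
Cholesky sampling) on four 2800×560 µm pucks: the bead-level test rejects
the true null in > 80% of replicates, the patch-level test stays within
the binomial CI of 5%.

**Bootstrap method comparison.** Means and SEMs of CLR compositions over
100 bootstrap resamples of samples; the SE of between-condition
differences comes from the 100×100 pairwise-difference set; cross-method
agreement is the Pearson correlation of mean vectors.

## Cross-species analysis

Ortholog mapping is case-normalized with synonym fallback (synonyms
consulted only when the primary symbol misses); source genes sharing a
target are summed, so counts over mapped genes are conserved exactly.
The on-disk format is the tab-separated MGI HOM-report dialect (class
key, organism, symbol, synonyms), with a pair-table in memory.

Program similarity: programs and per-species background pseudo-bulks are
normalized to 10,000 counts; the program vector is
`log((program + 1)/(background + 1))` on that scale (δ = 1, the
log1p-compatible offset); Pearson across shared genes for every
cross-species pair. The background ratio cancels species- and
platform-specific gene scaling, which the tests verify by planting a
shared program under multiplicative distortion.

Region DEGs: genes binarized as expressed (count ≥ 1, configurable) per
bead; one-sided Fisher (hypergeometric tail) of in-region vs out-region
expressing beads; ranked by p, ties by descending in-region fraction then
gene name; top 200 kept. Region scores: mean CLR pseudo-bulk expression
over the gene set, standardized to zero mean/unit population variance per
species (an in-set/out-of-set correction — the DEGs come from one
species); PCA across samples summarizes the region-score matrix, PC1
oriented so a designated reference set loads positive (the sign is pure
convention). Outcome stratification cuts scores at the empirical
25th/75th percentiles (linear interpolation, Q1 = score < q25,
Q4 = score ≥ q75) and compares the extreme quartiles with the logrank
test, BH across score sets.

Signature scoring normalizes beads to 10,000 counts, log1p-transforms and
scales per gene, then subtracts a size-matched, expression-bin-matched
random control set (25 bins, seeded) from the signature mean — so a
signature equal to the whole vocabulary scores ≈ 0. Genes expressed on
fewer than 3 beads are dropped first.

## Marker-panel optimization

Candidates are partitioned into redundancy sets with per-set quotas. The
objective thins the candidate count matrix once (seeded binomial thinning
to a target mean panel depth — the expected sparsity of the targeted
in situ assay; thinning once, over all candidates, makes the objective a
deterministic function of the selection) and averages grouped 4-fold CV
scores: multinomial logistic accuracy per classification task, ridge R²
per regression task, unweighted across tasks (relative task weights are a
declared convention). Folds are grouped by sample id to avoid leakage.
The optimizer sweeps sets in fixed order, exhaustively evaluating every
feasible within-set choice with the rest held fixed, accepting strict
improvements only (ties keep the incumbent) — so the trace is
non-decreasing and termination is guaranteed on the finite state space.
The classifier/regressor hyperparameters are fixed (unit L2): the
objective ranks selections, it is not an accuracy claim.

## QC and doublet labelling

Cell filters: counts in [1000, 50000] and genes in [500, 7000]
(inclusive — "between"), mitochondrial fraction < 0.20 and hemoglobin
fraction < 0.10 (strict — "less than"); every failed rule is reported per
cell. Bead filter: ≥ 100 total reads. Both are idempotent.

Doublets in a partition are the union of three rules applied once, in
order: (1) any foreign-compartment marker count strictly above that
marker's 95th percentile within the partition (linear interpolation on
integer counts; if ≥ 95% of cells have 0 counts the percentile is 0 and
only positive cells can be flagged, so > 95% of cells are always kept);
(2) disagreement between cell-wise and cluster-wise reference labels
after coarse mapping; (3) one-sided Fisher enrichment of already-flagged
cells among a cell's k expression neighbours against the rest of the
partition (focal neighbourhood excluded from the background to avoid
double counting), BH FDR ≤ 0.05. On 10% planted immune×epithelial
doublets the union achieves sensitivity ≥ 0.5 (typically ≈ 1.0 with
well-separated marker blocks) at specificity ≥ 0.95.

## Synthetic data: what it does and does not establish

The generator emulates: layered multi-puck tissue with per-bead mixtures
of type profiles, Poisson counts at controlled depth (gamma mixing
available for overdispersion, default off), per-gene batch scaling,
spatially autocorrelated Gaussian fields, species pairs with a known
ortholog table and synonym lists, and doublets (sum of two cells' counts,
halved and re-Poissonized, preserving the depth distribution). Beads sit
on a square grid (jitter available, default off) so distance-based
statistics have exact expected neighbour counts. All generators are
bit-reproducible under a fixed seed; one top-level seed is split into
per-stage streams.

It does **not** emulate: real gene-level count statistics (zero inflation
beyond Poisson, gene-gene correlation within a type), lateral transcript
diffusion between beads, bead barcode errors, segmentation artifacts, or
optics. Passing benchmarks therefore establish correctness of the
algorithms under their stated models and calibration of the statistics
under exchangeable or Gaussian nulls — not performance claims on real
tissue, where profile distinctness, depth and spatial texture differ.

## Problem sizes

The bundled benchmarks are desk-scale by design: ~2000 beads for
annotation recovery, 1470 beads across 3 pucks for region recovery, four
1050-bead pucks × 100 replicates for patch calibration, 200 replicate
grids for neighborship calibration, 1000 replicates for Welch
calibration. The full test suite runs in about a minute on one CPU; the
acceptance script in about half a minute.
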