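# Methods

## The model

`pdrwh` prioritizes the mutated genes of one tumor sample ("the target
patient") by how strongly they sit upstream of abnormal transcription — not
only in the patient's own profile but across the cohort samples that resemble
it. The reasoning is that a driver mutation perturbs its interaction partners'
expression, and patients sharing a driver tend to share the downstream
perturbation, while passenger mutations do neither.

The per-patient computation has three stages.

**1. Personalized weighted hypergraph.** Vertices `V` are the union of the
target's mutated genes and its abnormally expressed genes. Each sample sharing
at least one mutated gene with the target contributes one hyperedge incident
with its own mutated/abnormal genes inside `V`; the target's own hyperedge
`e0` covers all of `V`. Two weight families encode the biology:

- *hyperedge weights* `w_e = exp(-(1-ρ)² / (2δ²))`, a Gaussian kernel of the
  Pearson correlation `ρ` between that sample's and the target's expression
  profiles (bandwidth `δ = 0.1`; `w_{e0} = 1`). Transcriptionally similar
  patients dominate the walk.
- *vertex weights* `w(v,e)`: the degree of gene `v` in the interaction
  subnetwork induced by hyperedge `e`'s genes. A gene adjacent to many
  co-occurring abnormal genes gets proportionally more of the walk's mass.
  Genes with no partner in the set (or absent from the network) get a floor of
  `0.01` so every membership keeps positive weight.

Vertex and hyperedge degrees are `d(v) = Σ_e h(v,e)·w_e` and
`δ(e) = Σ_v w(v,e)`.

**2. Transition matrix.** One walk step picks a hyperedge containing the
current gene with probability ∝ `h(u,e)·w_e`, then a gene inside it with
probability ∝ `w(v,e)`. Collapsed, `P = D_v⁻¹ H W_e D_ve⁻¹ W_vᵀ`, which is
row-stochastic by construction (asserted to 1e-12 at every build).

**3. Restart walk and scoring.** `v_{t+1} = α Pᵀ v_t + (1-α) v_0` with damping
`α = 0.85` and `v_0` uniform over the target's mutated genes. Iteration stops
when the L1 difference of successive iterates falls below `ε = 1e-6` (cap
1000, converged flag otherwise). The stationary probabilities of the mutated
genes, renormalized to sum to 1 (L1; a max-normalization switch exists), are
the driver scores; ties sort by gene symbol for determinism.

## Pre-processing

Expression is z-scored per gene with the sample (n−1) standard deviation;
quantiles use linear interpolation — both pinned so thresholds are
reproducible. A gene is *abnormal* in a sample when `|z|` strictly exceeds
`θ = min(|q05|, |q95|)` of that gene's z row, i.e. the smaller tail magnitude;
this needs no matched normal tissue. Zero-variance genes are kept (their z
rows are 0, never abnormal) so gene universes stay aligned across modules.
Samples with fewer than 3 mutated genes are dropped before normalization, so
all cohort statistics describe exactly the analyzed cohort. On a symmetric
continuous expression row this flags ~10% of samples per gene; the `min()` of
two noisy quantile estimates biases `θ` slightly low, so single genes can land
a little above that (the tests assert the band on the mean across genes).

Correlations `ρ` for hyperedge weights are computed on the z-scored matrix by
default, so they reflect shared deviation patterns rather than shared absolute
expression level; `correlation="raw"` restores the literal raw-matrix reading.
An undefined correlation (zero-variance profile) is treated as `ρ = 0`, whose
kernel weight is negligible.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `bandwidth` (δ) | 0.1 | decay of a neighbor sample's influence with 1−ρ; at δ=0.1, ρ=0.9 already gives weight e^(−0.5) and ρ=0.5 is negligible |
| `alpha` (α) | 0.85 | probability of walking on vs restarting at the mutated genes |
| `epsilon` (ε) | 1e−6 | L1 convergence tolerance of the walk |
| `isolated_weight` | 0.01 | vertex-weight floor for genes without interaction partners in the hyperedge |
| `min_mutations` | 3 | sample-filtering cutoff (strict: exactly 3 is kept) |

Because `e0` carries weight 1 and covers `V` while distant neighbors' kernel
weights are tiny, `P` is close to a rank-one matrix and the walk typically
converges in a handful of iterations (median 2 on the synthetic cohorts; the
original claim of convergence within ~10 iterations is checked, not assumed).

## Evaluation statistics

- Precision/recall/F1 of the top-k predictions against a reference driver
  list, with the cohort cutoff `n = 2 × median` per-patient count of reference
  genes among mutated genes (rounded half-up, floored at 1).
- Per-patient hypergeometric enrichment `P(X ≥ m)` of the top-n predictions.
  The draw universe is the patient's mutated gene set and `M` the reference
  genes within it — the literal "all genes / full list" reading can make
  `M > N` and is available via `universe="genes"`. With the synthetic cohorts'
  ~7 mutated genes per patient this test is deliberately underpowered (a
  universe that small cannot reach p < 0.05 unless nearly all draws hit), so
  low enrichment rates there reflect the scaled-down problem size, not the
  statistic.
- Cohort-level ranking by summing each gene's normalized per-patient scores
  (Borda-like; the aggregation is pluggable since more elaborate rank-fusion
  schemes exist), scored by rank-based ROC/AUC with ties counting ½.
- Common/rare split of predicted drivers at cohort mutation frequency ≥ 2%.
- Baselines over the target's mutated genes: cohort mutation frequency, and
  degree in the subnetwork induced by the target's mutated genes.

## Synthetic cohorts

The generator plants exactly the structure the method exploits and nothing
else: a preferential-attachment network (heavy-tailed degrees), drivers drawn
from the top-degree decile, samples partitioned into 4 groups that share
driver assignments, a `+3σ` expression shift on a carried driver's direct
network neighbors in carrier samples, and network-independent Bernoulli
passenger mutations (rate 0.01/gene; samples are topped up to the
3-mutation floor). Defaults: 500 genes, 60 samples, 5 drivers.

Drivers are *partitioned* across groups (shuffled round-robin) rather than
drawn independently per group: abnormality is defined against the cohort
distribution, so a driver carried by most samples would have its neighbors'
shift absorbed into the baseline and lose the very signal being planted.
Within-group samples share shifted genes, which makes the correlation-based
hyperedge weights informative (within-group ρ exceeds between-group ρ).

The null control for recovery removes both planted signals: `effect_size=0`
silences the expression link, and `driver_hub_quantile=1.0` removes the
degree association. The latter matters — with hub placement alone (effect 0)
top-1 precision stays near 0.6 against a 0.22 chance level, because the
induced-degree vertex weights legitimately reward hubs; that is the method
working as designed, not residual leakage.

What the generator does **not** emulate: mutational signatures, copy-number
and fusion events, expression compositionality/library-size effects, batch
structure, or realistic gene-gene correlation beyond the planted shifts.
Passing recovery tests therefore show the algorithm finds the structure it
assumes when present — they do not certify performance on real tumors.

## Numerical choices

- Walk iterates and the transition build accumulate in float64; the dense
  matrix path is used throughout (|V| is at most a few thousand; a factored
  sparse product `(D_v⁻¹ H W_e)(D_ve⁻¹ W_vᵀ)` is the natural extension for
  larger vertex sets).
- Convergence is measured in L1; every iterate conserves probability mass to
  ~1e-12 because `Pᵀ` preserves column sums.
- Tie-breaks everywhere are lexicographic by gene symbol; output files are
  sorted (sample, rank), so reruns are byte-identical.
- Degenerate inputs fail loudly: empty vertex sets, zero degrees,
  non-stochastic restart vectors, infeasible hypergeometric setups and
  sample-id mismatches are hard errors, while non-convergence is a flagged
  warning.

## Problem sizes used in the checks

The verification suite runs 100 random hypergraphs (|V| ≤ 50) against a
scalar-loop transition oracle and a dense linear solve, one 10⁶-step
Monte-Carlo simulation of the literal two-stage walk (batch-means standard
errors, since the chain is autocorrelated), exhaustive hypergeometric
enumeration to N = 12, and 20 seeded default-condition cohorts for recovery
(plus 10 null cohorts). These sizes keep a full run in well under a minute
per component while leaving the tolerances at the values stated above.

## Known limitations

- The interaction network is global, not patient-specific; false positives
  from context-irrelevant edges are possible.
- Single-gene scores; co-driving gene sets are out of scope.
- Point mutations and small indels only — no copy number, rearrangements or
  epigenetic silencing.
- The cohort-level aggregation is a deliberate simple score-sum; published
  rank-fusion strategies (e.g. election-style schemes) are not reimplemented.
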