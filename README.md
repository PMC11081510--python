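# pdrwh

Personalized cancer driver gene prioritization via random walks with restart
on patient-specific weighted hypergraphs.

Most driver-gene methods output one gene list per cohort, but tumors are
heterogeneous: the mutations driving one patient's cancer are often absent or
irrelevant in another's. `pdrwh` ranks **each patient's own mutated genes** by
integrating three inputs over the whole cohort:

1. binary somatic mutation calls (gene × sample),
2. a gene expression matrix (gene × sample),
3. an undirected gene interaction network (e.g. a STRING edge list).

For a target patient, every cohort sample sharing a mutated gene becomes a
hyperedge connecting its mutated and abnormally expressed genes; hyperedges
are weighted by expression-profile correlation with the target
(`w_e = exp(-(1-ρ)²/2δ²)`), and genes within a hyperedge by their degree in
the interaction subnetwork it induces. A random walk with restart on this
hypergraph,

```
v(t+1) = α Pᵀ v(t) + (1-α) v₀,    P = D_v⁻¹ H W_e D_ve⁻¹ W_vᵀ,
```

restarting at the patient's mutated genes (α = 0.85), yields stationary
probabilities whose restriction to the mutated genes — renormalized — is the
driver score. A mutated gene ranks high when it is adjacent to many genes
that are abnormally expressed both in the patient and in transcriptionally
similar patients. See `docs/methods.md` for the full model, assumptions and
parameter discussion.

The package also ships the benchmarking statistics (precision/recall/F1 at a
cohort-derived top-n cutoff, hypergeometric enrichment, cohort-level score
aggregation with ROC/AUC, common/rare splitting at 2% mutation frequency,
frequency and degree baselines) and a seedable synthetic-cohort simulator
with planted hub drivers for end-to-end validation without external data.

## Worked example

```python
from pdrwh import (SyntheticCohortSpec, generate_synthetic_cohort,
                   prepare_cohort, rank_cohort, RunConfig)

X, M, net, truth = generate_synthetic_cohort(SyntheticCohortSpec(seed=42))
cohort = prepare_cohort(X, M, net, RunConfig())
rankings = rank_cohort(cohort)
for r in rankings[:3]:
    print(r.sample_id, r.entries[:3])
```

prints (see `examples/01_rank_synthetic_cohort.py` for the annotated version):

```
S0000 [('G00017', 0.306), ('G00087', 0.306), ('G00487', 0.130)]
S0001 [('G00049', 0.480), ('G00396', 0.200), ('G00231', 0.160)]
S0002 [('G00078', 0.295), ('G00222', 0.219), ('G00031', 0.143)]
```

Each line is one patient's mutated genes sorted by driver score (scores sum
to 1 per patient). Here the top-ranked genes are exactly the drivers planted
for those patients' groups; over the whole 60-sample cohort 52/60 patients
(86.7%) have a planted driver ranked first. The other examples dissect one
patient's hypergraph (`02_hypergraph_anatomy.py`) and run the benchmark
statistics and naive baselines (`03_benchmark_and_baselines.py`).

The same pipeline is available from the shell:

```sh
pdrwh simulate --seed 42 --outdir data/
pdrwh rank --expression data/expression.tsv --mutations data/mutations.tsv \
           --network data/network.tsv --outdir run/
pdrwh evaluate --rankings run/rankings.tsv --mutations data/mutations.tsv \
               --reference data/drivers.txt --outdir eval/
```

`rank` writes one deterministic TSV block per patient plus the effective
config; `evaluate` writes per-patient metrics, the enrichment table, the
aggregated cohort ranking and a JSON summary.

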