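"""Benchmark the ranking against the planted truth and naive baselines.

Evaluates per-patient precision/recall/F1 at the cohort top-n cutoff,
per-patient hypergeometric enrichment, and the aggregated cohort AUC,
and compares top-1 precision with the mutation-frequency and induced-
degree baselines.
"""

import logging

import numpy as np

from pdrwh import (
    ReferenceSet,
    RunConfig,
    SyntheticCohortSpec,
    baseline_rankings,
    evaluate_rankings,
    generate_synthetic_cohort,
    prepare_cohort,
    rank_cohort,
)

logging.disable(logging.INFO)

X, M, net, truth = generate_synthetic_cohort(SyntheticCohortSpec(seed=42))
cohort = prepare_cohort(X, M, net, RunConfig())
rankings = rank_cohort(cohort)
ref = ReferenceSet("planted", frozenset(truth.drivers))

report = evaluate_rankings(rankings, ref, cohort.mutations)
print(f"top-n cutoff (2 x median reference mutations/patient): {report.top_n}")
print("\nmean metrics by cutoff:")
print(report.averages.round(3).to_string(index=False))
print(f"\nenrichment: {report.enrichment_rate:.1%} of patients have "
      f"top-{report.top_n} predictions enriched (p < 0.05) in the "
      "planted-driver list given their own mutated-gene universe.")
print(f"cohort-level AUC against planted drivers: {report.auc:.3f}")

def top1_precision(make):
    hits = [make(s).entries[0][0] in truth.carried[s]
            for s in cohort.mutations.sample_ids]
    return np.mean(hits)

walk = {r.sample_id: r for r in rankings}
print("\ntop-1 precision, hypergraph walk vs naive baselines:")
print(f"  hypergraph walk     {top1_precision(lambda s: walk[s]):.3f}")
for method in ("frequency", "degree"):
    p = top1_precision(
        lambda s: baseline_rankings(s, cohort.mutations, net, method)
    )
    print(f"  {method:18}  {p:.3f}")
print("\nOn this simulated cohort the frequency baseline is very strong "
      "by construction (each planted driver is mutated across a whole "
      "sample group), yet the walk comes close without ever reading "
      "recurrence directly, and clearly beats the network-only degree "
      "baseline.  On real tumors, where rare drivers have near-zero "
      "recurrence, the walk's expression-and-network signal is the part "
      "frequency cannot see.")
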