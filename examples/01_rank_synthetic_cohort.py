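"""Rank personalized driver genes on a simulated cohort.

Generates a 500-gene, 60-sample cohort with 5 planted hub drivers,
runs the full pipeline (normalization, abnormal calling, per-patient
hypergraph, restart walk) and prints each of the first few patients'
top-ranked mutated genes next to the ground truth.
"""

import logging

from pdrwh import (
    RunConfig,
    SyntheticCohortSpec,
    generate_synthetic_cohort,
    prepare_cohort,
    rank_cohort,
)

logging.disable(logging.INFO)

spec = SyntheticCohortSpec(seed=42)
X, M, net, truth = generate_synthetic_cohort(spec)
cohort = prepare_cohort(X, M, net, RunConfig())
rankings = rank_cohort(cohort)

print(f"cohort: {len(X.gene_ids)} genes, {len(rankings)} samples, "
      f"planted drivers: {', '.join(sorted(truth.drivers))}\n")
print(f"{'sample':8} {'top-3 ranked mutated genes (score)':52} carried drivers")
for r in rankings[:8]:
    top3 = ", ".join(f"{g} ({s:.3f})" for g, s in r.entries[:3])
    carried = ",".join(sorted(truth.carried[r.sample_id]))
    mark = "*" if r.entries[0][0] in truth.carried[r.sample_id] else " "
    print(f"{r.sample_id:8} {top3:52} {carried} {mark}")

hits = sum(r.entries[0][0] in truth.carried[r.sample_id] for r in rankings)
print(f"\ntop-1 recovery: {hits}/{len(rankings)} patients "
      f"({hits / len(rankings):.1%}) have a planted driver ranked first.")
print("Scores are stationary walk probabilities renormalized over each "
      "patient's mutated genes; a high score means the gene sits next to "
      "many abnormally expressed genes across transcriptionally similar "
      "patients.")
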