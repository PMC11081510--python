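"""Benchmarking statistics for driver rankings.

Per-patient precision/recall/F1 against a reference driver list, the
top-n cutoff rule (twice the cohort median count of reference genes
among each patient's mutations), hypergeometric enrichment of predicted
drivers, score-sum aggregation of patient rankings into a cohort list
with rank-based ROC/AUC, the common/rare mutation-frequency split, and
two naive per-patient baselines (cohort mutation frequency and induced
subnetwork degree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import roc_auc_score

from .cohort_io import MutationProfile, ReferenceSet
from .preprocess import AbnormalCalls
from .randomwalk import DriverRanking

__all__ = [
    "EnrichmentResult",
    "EvalReport",
    "precision_recall_f1",
    "compute_top_n",
    "enrichment_pvalue",
    "enrich_patient",
    "aggregate_cohort_ranking",
    "roc_auc",
    "baseline_rankings",
    "classify_mutation_frequency",
    "evaluate_rankings",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one patient's predicted drivers.

    N is the candidate universe size, M the reference genes inside it,
    n the predicted drivers tested, m their overlap with the reference;
    p_value is the upper tail P(X >= m).
    """

    sample_id: str
    N: int
    M: int
    n: int
    m: int
    p_value: float
    significant: bool


@dataclass
class EvalReport:
    """Cohort evaluation summary."""

    top_n: int
    per_patient: pd.DataFrame          # sample_id, cutoff, precision, recall, f1
    averages: pd.DataFrame             # cutoff, precision, recall, f1
    enrichment: list[EnrichmentResult]
    enrichment_rate: float             # fraction of patients significant
    cohort_ranking: list[tuple[str, float]]
    auc: float | None
    frequency_class: dict[str, str]    # gene -> "common" | "rare"


def precision_recall_f1(
    predicted: list[str], reference: ReferenceSet, k: int
) -> tuple[float, float, float]:
    """Precision, recall and F1 of the top-k predictions against a reference.

    F1 is defined as 0 when precision and recall are both 0.
    """
    if k < 1:
        raise ValueError("cutoff k must be >= 1")
    if not predicted:
        raise ValueError("no predictions")
    if len(reference) == 0:
        raise ValueError("empty reference set")
    top = set(predicted[:k])
    hits = len(top & reference.genes)
    precision = hits / len(top)
    recall = hits / len(reference)
    if precision + recall == 0:
        return 0.0, 0.0, 0.0
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def compute_top_n(
    reference: ReferenceSet, mutations: MutationProfile, samples=None
) -> int:
    """Cohort cutoff: twice the median per-patient count of reference genes
    among that patient's mutated genes, rounded half-up, floored at 1."""
    samples = list(samples) if samples is not None else list(mutations.sample_ids)
    if not samples:
        raise ValueError("no samples")
    counts = [
        len(mutations.mutated_genes(s) & reference.genes) for s in samples
    ]
    n = 2.0 * median(counts)
    return max(1, int(np.floor(n + 0.5)))


def enrichment_pvalue(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    X counts reference genes in a size-n draw without replacement from a
    universe of N genes of which M are reference.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(f"infeasible hypergeometric setup N={N} M={M} n={n} m={m}")
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich_patient(
    ranking: DriverRanking,
    reference: ReferenceSet,
    mutations: MutationProfile,
    top_n: int,
    alpha: float = 0.05,
    universe: str = "mutated",
) -> EnrichmentResult:
    """Test whether a patient's top-n predictions are enriched for reference genes.

    With ``universe='mutated'`` (default) the draw universe is the
    patient's mutated gene set and M the reference genes inside it,
    which keeps the distribution well-defined; ``universe='genes'`` uses
    the literal full gene universe and full reference size.
    """
    mutated = mutations.mutated_genes(ranking.sample_id)
    predicted = ranking.top(top_n)
    n = len(predicted)
    m = len(set(predicted) & reference.genes)
    if universe == "mutated":
        N = len(mutated)
        M = len(mutated & reference.genes)
    elif universe == "genes":
        N = len(mutations.gene_ids)
        M = len(reference)
        m = min(m, M)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    p = enrichment_pvalue(N, M, n, m)
    return EnrichmentResult(
        sample_id=ranking.sample_id, N=N, M=M, n=n, m=m,
        p_value=p, significant=p < alpha,
    )


def aggregate_cohort_ranking(
    rankings: list[DriverRanking],
) -> list[tuple[str, float]]:
    """Sum each gene's normalized per-patient scores into a cohort ranking.

    A Borda-like aggregation: genes are ordered by the total score they
    accumulate across patients, descending, ties by gene symbol.
    """
    if not rankings:
        raise ValueError("no rankings to aggregate")
    totals: dict[str, float] = {}
    for r in rankings:
        for gene, score in r.entries:
            totals[gene] = totals.get(gene, 0.0) + score
    return sorted(totals.items(), key=lambda gv: (-gv[1], gv[0]))


def roc_auc(
    cohort_ranking: list[tuple[str, float]], reference: ReferenceSet
) -> float:
    """Rank-based AUC: probability a reference gene outscores a non-reference
    gene in the aggregated cohort ranking, ties counting one half."""
    labels = np.array([1 if g in reference else 0 for g, _ in cohort_ranking])
    scores = np.array([s for _, s in cohort_ranking])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("ROC needs both reference and non-reference genes")
    return float(roc_auc_score(labels, scores))


def baseline_rankings(
    target: str,
    M: MutationProfile,
    network: nx.Graph,
    method: str,
) -> DriverRanking:
    """Naive per-patient baselines over the target's mutated genes.

    ``frequency`` orders by cohort mutation frequency; ``degree`` by
    degree in the network subgraph induced by the target's mutated
    genes.  Ties break by ascending gene symbol, as in the main method.
    """
    mutated = sorted(M.mutated_genes(target))
    if method == "frequency":
        n_samples = len(M.sample_ids)
        freq = M.calls.loc[mutated].sum(axis=1) / n_samples
        scored = [(g, float(freq[g])) for g in mutated]
    elif method == "degree":
        members = set(mutated)
        scored = []
        for g in mutated:
            deg = (
                sum(1 for nb in network.adj[g] if nb in members)
                if g in network
                else 0
            )
            scored.append((g, float(deg)))
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    entries = sorted(scored, key=lambda gv: (-gv[1], gv[0]))
    return DriverRanking(sample_id=target, entries=entries)


def classify_mutation_frequency(
    gene: str, M: MutationProfile, threshold: float = 0.02
) -> str:
    """'common' if the gene's cohort mutation frequency is >= threshold."""
    if gene not in M.calls.index:
        raise KeyError(f"gene {gene!r} not in mutation profile")
    freq = float(M.calls.loc[gene].sum()) / len(M.sample_ids)
    return "common" if freq >= threshold else "rare"


def evaluate_rankings(
    rankings: list[DriverRanking],
    reference: ReferenceSet,
    mutations: MutationProfile,
    top_n: int | None = None,
    alpha: float = 0.05,
    universe: str = "mutated",
) -> EvalReport:
    """Full cohort evaluation against one reference set."""
    if not rankings:
        raise ValueError("no rankings to evaluate")
    samples = [r.sample_id for r in rankings]
    if top_n is None:
        top_n = compute_top_n(reference, mutations, samples)

    rows = []
    for r in rankings:
        for k in range(1, top_n + 1):
            if k > len(r.entries):
                break
            p, rec, f1 = precision_recall_f1(r.genes, reference, k)
            rows.append((r.sample_id, k, p, rec, f1))
    per_patient = pd.DataFrame(
        rows, columns=["sample_id", "cutoff", "precision", "recall", "f1"]
    )
    averages = (
        per_patient.groupby("cutoff")[["precision", "recall", "f1"]]
        .mean()
        .reset_index()
    )

    enrichment = [
        enrich_patient(r, reference, mutations, top_n, alpha, universe)
        for r in rankings
    ]
    rate = sum(e.significant for e in enrichment) / len(enrichment)

    cohort = aggregate_cohort_ranking(rankings)
    labels = {1 if g in reference else 0 for g, _ in cohort}
    auc = roc_auc(cohort, reference) if labels == {0, 1} else None

    freq_class = {
        g: classify_mutation_frequency(g, mutations)
        for g, _ in cohort
        if g in mutations.calls.index
    }
    return EvalReport(
        top_n=top_n,
        per_patient=per_patient,
        averages=averages,
        enrichment=enrichment,
        enrichment_rate=rate,
        cohort_ranking=cohort,
        auc=auc,
        frequency_class=freq_class,
    )
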