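"""Expression normalization, abnormal-expression calling, sample filtering.

Each gene's expression is z-scored across the cohort.  A gene is called
abnormally expressed in a sample when the magnitude of its z-score
exceeds a per-gene threshold theta, defined as the smaller of the
magnitudes of the 5% and 95% cohort quantiles of that gene's z-scores.
This flags the extreme tail on both sides without needing matched
normal tissue or a healthy background cohort.

Samples with too few mutated genes carry almost no signal for the walk
and are removed up front (default: fewer than 3 mutated genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, MutationProfile

__all__ = [
    "NormalizedExpression",
    "AbnormalCalls",
    "normalize_expression",
    "call_abnormal",
    "filter_samples",
]


@dataclass
class NormalizedExpression:
    """Per-gene z-scored expression with abnormality thresholds.

    ``z`` holds x' = (x - mu) / sigma per gene row (sample sd, n-1
    denominator).  Genes with zero variance are recorded in
    ``degenerate_genes``; their z rows are 0 and they are never called
    abnormal.  ``theta`` is min(|q05|, |q95|) of each z row.
    """

    z: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    theta: pd.Series
    degenerate_genes: frozenset[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class AbnormalCalls:
    """Boolean gene x sample matrix of abnormal-expression calls."""

    flags: pd.DataFrame

    def genes_for(self, sample: str) -> set[str]:
        """The abnormally expressed gene set A_j of one sample."""
        col = self.flags[sample]
        return set(col.index[col])


def normalize_expression(X: ExpressionMatrix) -> NormalizedExpression:
    """Z-score each gene row and derive its abnormality threshold.

    Quantiles use linear interpolation between order statistics.  Needs
    at least 2 samples for the quantiles to mean anything.
    """
    if X.values.shape[1] < 2:
        raise ValueError("normalization needs at least 2 samples")
    vals = X.values
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=1)
    degenerate = frozenset(sigma.index[sigma == 0.0])
    safe_sigma = sigma.replace(0.0, 1.0)
    z = vals.sub(mu, axis=0).div(safe_sigma, axis=0)
    z.loc[list(degenerate)] = 0.0
    q05 = z.quantile(0.05, axis=1, interpolation="linear")
    q95 = z.quantile(0.95, axis=1, interpolation="linear")
    theta = pd.concat([q05.abs(), q95.abs()], axis=1).min(axis=1)
    return NormalizedExpression(z=z, mu=mu, sigma=sigma, theta=theta,
                                degenerate_genes=degenerate)


def call_abnormal(N: NormalizedExpression) -> AbnormalCalls:
    """Flag gene/sample pairs with |z| strictly above the gene's theta."""
    flags = N.z.abs().gt(N.theta, axis=0)
    if N.degenerate_genes:
        flags.loc[list(N.degenerate_genes)] = False
    return AbnormalCalls(flags)


def filter_samples(M: MutationProfile, min_mutations: int = 3) -> MutationProfile:
    """Drop samples carrying fewer than ``min_mutations`` mutated genes.

    The bound is strict: a sample with exactly ``min_mutations`` is kept.
    """
    counts = M.calls.sum(axis=0)
    keep = counts.index[counts >= min_mutations]
    if len(keep) == 0:
        raise ValueError(
            f"all samples have fewer than {min_mutations} mutated genes"
        )
    return MutationProfile(M.calls[list(keep)])


def write_gene_stats(N: NormalizedExpression, path) -> None:
    """Audit cache: per-gene mu, sigma, theta as TSV."""
    pd.DataFrame({"mu": N.mu, "sigma": N.sigma, "theta": N.theta}).rename_axis(
        "gene"
    ).to_csv(path, sep="\t")
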