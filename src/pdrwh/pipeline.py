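"""Cohort-level orchestration: preprocess once, rank every patient."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .cohort_io import ExpressionMatrix, MutationProfile
from .preprocess import (
    AbnormalCalls,
    NormalizedExpression,
    call_abnormal,
    filter_samples,
    normalize_expression,
)
from .randomwalk import DriverRanking, WalkConfig, rank_patient

logger = logging.getLogger("pdrwh")

__all__ = ["RunConfig", "PreparedCohort", "prepare_cohort", "rank_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters with the method's published defaults."""

    bandwidth: float = 0.1
    alpha: float = 0.85
    epsilon: float = 1e-6
    max_iter: int = 1000
    isolated_weight: float = 0.01
    min_mutations: int = 3
    correlation: str = "zscore"   # or "raw"
    normalization: str = "l1"     # or "max"
    max_neighbors: int | None = None

    def walk_config(self) -> WalkConfig:
        return WalkConfig(alpha=self.alpha, epsilon=self.epsilon,
                          max_iter=self.max_iter)


@dataclass
class PreparedCohort:
    """Filtered, normalized cohort ready for per-patient ranking."""

    expression: ExpressionMatrix
    mutations: MutationProfile
    normalized: NormalizedExpression
    abnormal: AbnormalCalls
    network: nx.Graph
    config: RunConfig


def prepare_cohort(
    expression: ExpressionMatrix,
    mutations: MutationProfile,
    network: nx.Graph,
    config: RunConfig = RunConfig(),
) -> PreparedCohort:
    """Align samples, filter low-mutation samples, normalize expression.

    Samples must agree between the expression and mutation matrices;
    mismatches are reported by id rather than silently intersected.
    """
    expr_samples = set(expression.sample_ids)
    mut_samples = set(mutations.sample_ids)
    if expr_samples != mut_samples:
        missing = sorted((expr_samples ^ mut_samples))
        raise ValueError(
            f"sample ids differ between expression and mutations: {missing}"
        )
    mutations = filter_samples(mutations, config.min_mutations)
    kept = mutations.sample_ids
    expression = ExpressionMatrix(expression.values[kept])
    normalized = normalize_expression(expression)
    abnormal = call_abnormal(normalized)
    return PreparedCohort(
        expression=expression,
        mutations=mutations,
        normalized=normalized,
        abnormal=abnormal,
        network=network,
        config=config,
    )


def rank_cohort(
    cohort: PreparedCohort, targets: list[str] | None = None
) -> list[DriverRanking]:
    """Rank the mutated genes of every requested sample.

    Patients are independent, so results do not depend on the order in
    which samples are processed.  Non-converged walks are flagged on
    the returned rankings and logged, never dropped.
    """
    cfg = cohort.config
    wcfg = cfg.walk_config()
    all_samples = cohort.mutations.sample_ids
    if targets is None:
        targets = all_samples
    else:
        unknown = [t for t in targets if t not in set(all_samples)]
        if unknown:
            raise KeyError(f"unknown sample id(s): {unknown}")
    rankings = []
    for s in targets:
        r = rank_patient(
            s,
            cohort.mutations,
            cohort.abnormal,
            cohort.normalized,
            cohort.network,
            bandwidth=cfg.bandwidth,
            isolated_weight=cfg.isolated_weight,
            cfg=wcfg,
            correlation_values=(
                cohort.expression.values if cfg.correlation == "raw" else None
            ),
            max_neighbors=cfg.max_neighbors,
            normalization=cfg.normalization,
        )
        logger.info(
            "sample=%s genes=%d iterations=%d converged=%s",
            s, len(r.entries), r.iterations_used, r.converged,
        )
        if not r.converged:
            logger.warning("sample %s did not converge", s)
        rankings.append(r)
    return rankings
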