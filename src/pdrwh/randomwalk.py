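"""Transition matrix and restart random walk on the personalized hypergraph.

One walk step has two stages: from the current gene, pick a hyperedge
(a sample containing it) with probability proportional to h(u,e)*w_e,
then move to a gene in that hyperedge with probability proportional to
its per-hyperedge vertex weight w(v,e).  Collapsing the two stages
gives the vertex-to-vertex transition matrix

    P = D_v^{-1} H W_e D_ve^{-1} W_v^T

which is row-stochastic by construction.  The restart walk

    v_{t+1} = alpha P^T v_t + (1 - alpha) v_0

starts from the uniform distribution over the target's mutated genes
and converges geometrically for alpha < 1; the stationary mass on each
mutated gene, renormalized over the mutated genes, is the driver score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import MutationProfile
from .hypergraph import PersonalizedHypergraph, build_personalized_hypergraph
from .preprocess import AbnormalCalls, NormalizedExpression

__all__ = [
    "TransitionMatrix",
    "WalkConfig",
    "DriverRanking",
    "transition_matrix",
    "random_walk_with_restart",
    "solve_stationary_direct",
    "score_and_rank",
    "rank_patient",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic vertex-to-vertex transition probabilities."""

    vertex_order: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.P < 0):
            raise ValueError("negative transition probability")
        rowsums = self.P.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("transition matrix rows do not sum to 1")


@dataclass(frozen=True)
class WalkConfig:
    """Restart-walk parameters.

    alpha is the damping factor (probability of walking on rather than
    restarting); epsilon the L1 convergence tolerance between successive
    iterates; max_iter a safeguard cap.
    """

    alpha: float = 0.85
    epsilon: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class DriverRanking:
    """Ordered (gene, score) pairs over one patient's mutated genes.

    Scores are the stationary walk probabilities restricted to the
    mutated genes and renormalized to sum to 1; ties sort by gene symbol.
    """

    sample_id: str
    entries: list[tuple[str, float]]
    iterations_used: int = 0
    converged: bool = True

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


def transition_matrix(hg: PersonalizedHypergraph) -> TransitionMatrix:
    """Collapse the two-stage hyperedge walk into a dense vertex matrix.

    p(u,v) = sum_e [h(u,e) w_e / d(u)] * [w(v,e) / delta(e)].
    """
    if np.any(hg.d_v <= 0) or np.any(hg.delta_e <= 0):
        raise ValueError("hypergraph has a zero vertex or hyperedge degree")
    edge_pick = (hg.H * hg.w_e[None, :]) / hg.d_v[:, None]
    vertex_pick = hg.Wv / hg.delta_e[None, :]
    P = edge_pick @ vertex_pick.T
    return TransitionMatrix(vertex_order=list(hg.vertices), P=P)


def random_walk_with_restart(
    T: TransitionMatrix, v0: np.ndarray, cfg: WalkConfig = WalkConfig()
) -> tuple[np.ndarray, int, bool]:
    """Iterate v <- alpha P^T v + (1-alpha) v0 to stationarity.

    Returns (stationary vector, iterations used, converged flag).  The
    iteration stops when the L1 difference between successive iterates
    drops below cfg.epsilon, or warns and returns the last iterate when
    max_iter is hit.
    """
    v0 = np.asarray(v0, dtype=float)
    if np.any(v0 < 0) or not np.isclose(v0.sum(), 1.0, atol=1e-9):
        raise ValueError("v0 must be a probability vector")
    PT = T.P.T
    a = cfg.alpha
    restart = (1.0 - a) * v0
    v = v0.copy()
    for it in range(1, cfg.max_iter + 1):
        v_next = a * (PT @ v) + restart
        delta = np.abs(v_next - v).sum()
        v = v_next
        if delta < cfg.epsilon:
            return v, it, True
    warnings.warn(
        f"restart walk did not converge in {cfg.max_iter} iterations "
        f"(last L1 delta {delta:.3g})",
        RuntimeWarning,
    )
    return v, cfg.max_iter, False


def solve_stationary_direct(
    T: TransitionMatrix, v0: np.ndarray, alpha: float = 0.85
) -> np.ndarray:
    """Closed-form fixed point (I - alpha P^T) v = (1-alpha) v0.

    Exact dense solve; used as an independent check on the iteration.
    """
    v0 = np.asarray(v0, dtype=float)
    n = T.P.shape[0]
    A = np.eye(n) - alpha * T.P.T
    return np.linalg.solve(A, (1.0 - alpha) * v0)


def score_and_rank(
    stationary: np.ndarray,
    vertex_order: list[str],
    target_mutated: set[str],
    sample_id: str,
    iterations_used: int = 0,
    converged: bool = True,
    normalization: str = "l1",
) -> DriverRanking:
    """Restrict the stationary vector to mutated genes and rank them.

    Scores are L1-normalized over the mutated genes by default
    (``normalization='max'`` divides by the largest instead).  Sorting
    is by descending score with ties broken by ascending gene symbol.
    """
    idx = {g: i for i, g in enumerate(vertex_order)}
    missing = target_mutated - idx.keys()
    if missing:
        raise ValueError(f"mutated genes missing from vertex order: {sorted(missing)}")
    raw = {g: float(stationary[idx[g]]) for g in target_mutated}
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("all mutated genes have zero stationary probability")
    denom = total if normalization == "l1" else max(raw.values())
    if normalization not in {"l1", "max"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    entries = sorted(
        ((g, v / denom) for g, v in raw.items()), key=lambda gv: (-gv[1], gv[0])
    )
    return DriverRanking(
        sample_id=sample_id,
        entries=entries,
        iterations_used=iterations_used,
        converged=converged,
    )


def restart_vector(
    vertex_order: list[str], target_mutated: set[str]
) -> np.ndarray:
    """Uniform probability 1/n over the target's mutated genes, 0 elsewhere."""
    if not target_mutated:
        raise ValueError("target has no mutated genes")
    v0 = np.zeros(len(vertex_order))
    idx = {g: i for i, g in enumerate(vertex_order)}
    for g in target_mutated:
        v0[idx[g]] = 1.0
    return v0 / v0.sum()


def rank_patient(
    target: str,
    M: MutationProfile,
    A: AbnormalCalls,
    N: NormalizedExpression,
    network,
    bandwidth: float = 0.1,
    isolated_weight: float = 0.01,
    cfg: WalkConfig = WalkConfig(),
    correlation_values=None,
    max_neighbors: int | None = None,
    normalization: str = "l1",
) -> DriverRanking:
    """Full per-patient pipeline: hypergraph -> walk -> driver ranking."""
    hg = build_personalized_hypergraph(
        target,
        M,
        A,
        N,
        network,
        bandwidth=bandwidth,
        isolated_weight=isolated_weight,
        correlation_values=correlation_values,
        max_neighbors=max_neighbors,
    )
    T = transition_matrix(hg)
    mutated = M.mutated_genes(target)
    v0 = restart_vector(T.vertex_order, mutated)
    stationary, iters, converged = random_walk_with_restart(T, v0, cfg)
    return score_and_rank(
        stationary,
        T.vertex_order,
        mutated,
        sample_id=target,
        iterations_used=iters,
        converged=converged,
        normalization=normalization,
    )
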