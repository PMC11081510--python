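"""Patient-specific weighted hypergraph construction.

For a target sample s0, the hypergraph's vertices are the union of the
target's mutated genes and its abnormally expressed genes.  Each sample
contributes one hyperedge: e0 is the target itself (incident with every
vertex), and every cohort sample sharing at least one mutated gene with
the target contributes a neighbor hyperedge incident with its own
mutated and abnormal genes restricted to the vertex set.

Hyperedge weights follow a Gaussian kernel of (1 - Pearson correlation)
between the neighbor's and the target's expression profiles, so
transcriptionally similar patients dominate.  Within each hyperedge a
vertex is weighted by its degree in the interaction subnetwork induced
by that hyperedge's genes — the count of its interaction partners among
that sample's mutated/abnormal genes — with a small positive floor for
isolated vertices so every membership keeps nonzero weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import MutationProfile
from .preprocess import AbnormalCalls, NormalizedExpression

__all__ = [
    "PersonalizedHypergraph",
    "find_neighbor_samples",
    "hyperedge_weight",
    "induced_degree_weights",
    "build_personalized_hypergraph",
]


@dataclass
class PersonalizedHypergraph:
    """Weighted hypergraph for one target sample.

    Attributes
    ----------
    target_sample:
        Sample id of the patient being ranked.
    vertices:
        Ordered gene symbols: mutated(target) | abnormal(target).
    hyperedges:
        Ordered sample ids; the target comes first.
    H:
        Binary |V| x |E| incidence matrix.
    rho:
        Pearson correlation of each hyperedge's expression profile with
        the target's (1.0 for the target hyperedge itself).
    w_e:
        Hyperedge weights, Gaussian kernel of (1 - rho).
    Wv:
        |V| x |E| per-hyperedge vertex weights (induced-subnetwork
        degrees with an isolated-vertex floor; 0 off-membership).
    d_v:
        Vertex degrees, d(v) = sum_e h(v,e) * w_e.
    delta_e:
        Hyperedge degrees, delta(e) = sum_v w(v,e).
    """

    target_sample: str
    vertices: list[str]
    hyperedges: list[str]
    H: np.ndarray
    rho: np.ndarray
    w_e: np.ndarray
    Wv: np.ndarray
    d_v: np.ndarray
    delta_e: np.ndarray
    bandwidth: float

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)


def find_neighbor_samples(target: str, M: MutationProfile) -> list[str]:
    """Samples sharing at least one mutated gene with ``target``, input order."""
    if target not in M.calls.columns:
        raise KeyError(f"target sample {target!r} not in mutation profile")
    tcol = M.calls[target].to_numpy()
    shared = (M.calls.to_numpy() * tcol[:, None]).sum(axis=0)
    return [
        s for s, n in zip(M.calls.columns, shared) if s != target and n >= 1
    ]


def hyperedge_weight(rho: float, bandwidth: float) -> float:
    """Gaussian kernel weight exp(-(1-rho)^2 / (2*bandwidth^2))."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation {rho} outside [-1, 1]")
    return math.exp(-((1.0 - rho) ** 2) / (2.0 * bandwidth**2))


def induced_degree_weights(
    genes_in_hyperedge: Iterable[str],
    network: nx.Graph,
    isolated_weight: float = 0.01,
) -> dict[str, float]:
    """Weight each gene by its degree in the induced interaction subnetwork.

    The subnetwork is induced by ``genes_in_hyperedge``; a gene with no
    interaction partner in the set (including genes absent from the
    network entirely) receives ``isolated_weight`` instead of 0.
    """
    members = set(genes_in_hyperedge)
    if not members:
        raise ValueError("hyperedge has no genes")
    weights: dict[str, float] = {}
    for g in members:
        if g in network:
            deg = sum(1 for nb in network.adj[g] if nb in members)
        else:
            deg = 0
        weights[g] = float(deg) if deg > 0 else isolated_weight
    return weights


def _pearson_to_target(
    values: pd.DataFrame, target: str, samples: list[str]
) -> np.ndarray:
    """Pearson correlation of each sample column with the target column.

    A zero-variance column has undefined correlation; it is treated as 0
    so the corresponding hyperedge weight is effectively negligible.
    """
    t = values[target].to_numpy(dtype=float)
    t = t - t.mean()
    tn = np.linalg.norm(t)
    out = np.empty(len(samples))
    for i, s in enumerate(samples):
        c = values[s].to_numpy(dtype=float)
        c = c - c.mean()
        cn = np.linalg.norm(c)
        if tn == 0.0 or cn == 0.0:
            out[i] = 0.0
        else:
            out[i] = float(np.clip(np.dot(t, c) / (tn * cn), -1.0, 1.0))
    return out


def build_personalized_hypergraph(
    target: str,
    M: MutationProfile,
    A: AbnormalCalls,
    N: NormalizedExpression,
    network: nx.Graph,
    bandwidth: float = 0.1,
    isolated_weight: float = 0.01,
    correlation_values: pd.DataFrame | None = None,
    max_neighbors: int | None = None,
) -> PersonalizedHypergraph:
    """Assemble the weighted hypergraph for one target sample.

    Correlations are computed on the z-scored matrix by default so that
    hyperedge weights reflect shared deviation patterns rather than
    absolute expression magnitude; pass ``correlation_values`` (e.g. the
    raw expression matrix) to override.  ``max_neighbors`` optionally
    caps the hyperedge count at the most co-mutated neighbors for very
    large cohorts; by default all neighbors are used.
    """
    mutated = M.mutated_genes(target)
    abnormal = A.genes_for(target)
    vertex_set = mutated | abnormal
    if not vertex_set:
        raise ValueError(f"sample {target!r} has no mutated or abnormal genes")
    vertices = sorted(vertex_set)
    v_index = {g: i for i, g in enumerate(vertices)}

    neighbors = find_neighbor_samples(target, M)
    if max_neighbors is not None and len(neighbors) > max_neighbors:
        tcol = M.calls[target]
        shared = {
            s: int((M.calls[s] * tcol).sum()) for s in neighbors
        }
        neighbors = sorted(neighbors, key=lambda s: (-shared[s], s))[:max_neighbors]
    hyperedges = [target] + neighbors
    nV, nE = len(vertices), len(hyperedges)

    H = np.zeros((nV, nE))
    H[:, 0] = 1.0  # target hyperedge covers all of V
    member_sets: list[set[str]] = [vertex_set]
    for j, s in enumerate(neighbors, start=1):
        members = (M.mutated_genes(s) | A.genes_for(s)) & vertex_set
        member_sets.append(members)
        for g in members:
            H[v_index[g], j] = 1.0

    corr_source = correlation_values if correlation_values is not None else N.z
    rho = np.ones(nE)
    if neighbors:
        rho[1:] = _pearson_to_target(corr_source, target, neighbors)
    w_e = np.array([hyperedge_weight(r, bandwidth) for r in rho])
    w_e[0] = 1.0  # target correlates perfectly with itself

    Wv = np.zeros((nV, nE))
    for j, members in enumerate(member_sets):
        if not members:
            continue
        for g, w in induced_degree_weights(members, network, isolated_weight).items():
            Wv[v_index[g], j] = w

    d_v = H @ w_e
    delta_e = Wv.sum(axis=0)
    if np.any(d_v <= 0):
        raise ValueError("vertex with zero degree; hypergraph invalid")
    # all-empty neighbor columns cannot occur (a neighbor shares >=1 mutated
    # gene with the target, which is a vertex), but guard anyway
    if np.any(delta_e <= 0):
        raise ValueError("hyperedge with zero degree; hypergraph invalid")

    return PersonalizedHypergraph(
        target_sample=target,
        vertices=vertices,
        hyperedges=hyperedges,
        H=H,
        rho=rho,
        w_e=w_e,
        Wv=Wv,
        d_v=d_v,
        delta_e=delta_e,
        bandwidth=bandwidth,
    )
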