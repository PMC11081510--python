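"""Seedable synthetic cohorts with planted driver genes.

The generator emulates the statistical structure the ranking method
exploits: planted drivers are network hubs, and in samples carrying a
driver the expression of that driver's direct network neighbors is
shifted, so the carriers show dysregulated neighborhoods.  Samples are
partitioned into groups that share driver assignments, which induces
higher within-group expression correlation — the signal the
correlation-based hyperedge weights read.  Passenger mutations are
network-independent Bernoulli noise, giving a clean null class.

All randomness flows through ``numpy.random.default_rng`` (PCG64) plus
the seeded preferential-attachment generator in networkx, so a spec
with a fixed seed reproduces its cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, MutationProfile

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruth",
    "generate_network",
    "generate_synthetic_cohort",
    "random_hypergraph",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    Defaults give a small but structured cohort: 500 genes on a
    preferential-attachment network, 60 samples in 4 driver-sharing
    groups, 5 planted hub drivers, a 3-sigma expression shift on a
    carried driver's neighbors, and ~1% background passenger mutation
    probability per gene.
    """

    n_genes: int = 500
    n_samples: int = 60
    n_drivers: int = 5
    driver_hub_quantile: float = 0.10
    drivers_per_sample: tuple[int, int] = (1, 2)
    passenger_rate: float = 0.01
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_sample_groups: int = 4
    attachment_edges: int = 2
    min_mutations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_samples, self.n_drivers,
               self.n_sample_groups) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 < self.passenger_rate < 1.0:
            raise ValueError("passenger_rate must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        lo, hi = self.drivers_per_sample
        if not 1 <= lo <= hi <= self.n_drivers:
            raise ValueError("invalid drivers_per_sample range")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    drivers: frozenset[str]
    carried: dict[str, frozenset[str]]     # sample -> drivers it carries
    passengers: dict[str, frozenset[str]]  # sample -> non-driver mutations
    groups: dict[str, int] = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(
    n_genes: int, attachment_edges: int = 2, seed: int = 0
) -> nx.Graph:
    """Connected preferential-attachment gene network.

    Barabási–Albert growth with ``attachment_edges`` edges per new node
    gives the heavy-tailed degree distribution needed for hub drivers;
    the edge count is exactly attachment_edges * (n_genes -
    attachment_edges).  Deterministic for a fixed seed.
    """
    if n_genes < attachment_edges + 1:
        raise ValueError("n_genes must exceed attachment_edges")
    g = nx.barabasi_albert_graph(n_genes, attachment_edges, seed=seed)
    return nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes})


def generate_synthetic_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[ExpressionMatrix, MutationProfile, nx.Graph, GroundTruth]:
    """Draw one cohort: network, mutations, expression and ground truth."""
    rng = np.random.default_rng(spec.seed)
    network = generate_network(spec.n_genes, spec.attachment_edges, spec.seed)
    genes = sorted(network.nodes)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    # drivers come from the top-degree fraction of the network
    by_degree = sorted(genes, key=lambda g: (-network.degree[g], g))
    pool_size = max(1, int(np.ceil(spec.driver_hub_quantile * spec.n_genes)))
    hub_pool = by_degree[:pool_size]
    if len(hub_pool) < spec.n_drivers:
        raise ValueError(
            f"hub pool of {len(hub_pool)} genes cannot host {spec.n_drivers} drivers"
        )
    drivers = sorted(rng.choice(hub_pool, size=spec.n_drivers, replace=False))

    # partition drivers across groups (shuffled round-robin) so every
    # driver is carried by exactly one group: dysregulation is defined
    # relative to the cohort, so a driver carried by most samples would
    # have its neighbors' shift absorbed into the cohort baseline and
    # lose the abnormality signal the generator is meant to plant
    lo, hi = spec.drivers_per_sample
    shuffled = list(rng.permutation(drivers))
    group_drivers: list[list[str]] = [
        sorted(shuffled[g::spec.n_sample_groups])
        for g in range(spec.n_sample_groups)
    ]
    sizes = {len(gd) for gd in group_drivers}
    if not all(lo <= k <= hi for k in sizes):
        raise ValueError(
            f"partitioning {spec.n_drivers} drivers over "
            f"{spec.n_sample_groups} groups gives per-sample driver counts "
            f"{sorted(sizes)}, outside the requested range {lo}..{hi}"
        )

    gene_index = {g: i for i, g in enumerate(genes)}
    calls = np.zeros((len(genes), len(samples)), dtype=np.int8)
    expr = rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))

    carried: dict[str, frozenset[str]] = {}
    passengers: dict[str, frozenset[str]] = {}
    groups: dict[str, int] = {}
    for j, s in enumerate(samples):
        grp = j % spec.n_sample_groups
        groups[s] = grp
        mine = set(group_drivers[grp])
        pass_mask = rng.random(len(genes)) < spec.passenger_rate
        pset = {g for g, hit in zip(genes, pass_mask) if hit} - mine
        # top up so no sample falls below the mutation filter
        while len(mine) + len(pset) < spec.min_mutations:
            extra = genes[int(rng.integers(len(genes)))]
            if extra not in mine:
                pset.add(extra)
        carried[s] = frozenset(mine)
        passengers[s] = frozenset(pset)
        for g in mine | pset:
            calls[gene_index[g], j] = 1
        # carried drivers dysregulate their direct network neighbors
        for d in mine:
            for nb in network.adj[d]:
                expr[gene_index[nb], j] += spec.effect_size

    X = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    M = MutationProfile(pd.DataFrame(calls, index=genes, columns=samples))
    truth = GroundTruth(
        drivers=frozenset(drivers), carried=carried,
        passengers=passengers, groups=groups,
    )
    return X, M, network, truth


def random_hypergraph(
    n_vertices: int,
    n_hyperedges: int,
    rng: np.random.Generator,
    bandwidth: float = 0.1,
    membership_prob: float = 0.4,
):
    """Random but structurally valid personalized hypergraph.

    Used for stress-testing the transition matrix and walk on arbitrary
    shapes: the first hyperedge covers every vertex with weight 1 (the
    target sample), neighbor hyperedges get random non-empty memberships
    and Gaussian-kernel weights from random correlations, and member
    vertex weights are random small integer degrees with the isolated
    floor of 0.01 mixed in.
    """
    from .hypergraph import PersonalizedHypergraph, hyperedge_weight

    vertices = [_gene_name(i) for i in range(n_vertices)]
    H = np.zeros((n_vertices, n_hyperedges))
    H[:, 0] = 1.0
    for j in range(1, n_hyperedges):
        col = rng.random(n_vertices) < membership_prob
        if not col.any():
            col[rng.integers(n_vertices)] = True
        H[col, j] = 1.0
    rho = np.ones(n_hyperedges)
    if n_hyperedges > 1:
        rho[1:] = rng.uniform(0.6, 1.0, size=n_hyperedges - 1)
    w_e = np.array([hyperedge_weight(r, bandwidth) for r in rho])
    w_e[0] = 1.0
    Wv = np.zeros_like(H)
    member = H > 0
    weights = rng.integers(0, 6, size=H.shape).astype(float)
    weights[weights == 0] = 0.01
    Wv[member] = weights[member]
    return PersonalizedHypergraph(
        target_sample="S0",
        vertices=vertices,
        hyperedges=[f"S{j}" for j in range(n_hyperedges)],
        H=H,
        rho=rho,
        w_e=w_e,
        Wv=Wv,
        d_v=H @ w_e,
        delta_e=Wv.sum(axis=0),
        bandwidth=bandwidth,
    )


def write_cohort(
    spec: SyntheticCohortSpec, outdir
) -> tuple[ExpressionMatrix, MutationProfile, nx.Graph, GroundTruth]:
    """Generate a cohort and write it in the package's input formats.

    Produces expression.tsv (matrix), mutations.tsv (long table),
    network.tsv (edge list) and truth.tsv (sample, carried drivers,
    passengers) under ``outdir``.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X, M, network, truth = generate_synthetic_cohort(spec)

    X.values.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t")
    rows = [
        (s, g)
        for s in M.sample_ids
        for g in sorted(M.mutated_genes(s))
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene"]).to_csv(
        outdir / "mutations.tsv", sep="\t", index=False
    )
    with open(outdir / "network.tsv", "wt", encoding="utf-8") as fh:
        for a, b in sorted(map(sorted, network.edges)):
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "truth.tsv", "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tcarried_drivers\tpassengers\n")
        for s in M.sample_ids:
            fh.write(
                f"{s}\t{truth.groups[s]}\t"
                f"{','.join(sorted(truth.carried[s]))}\t"
                f"{','.join(sorted(truth.passengers[s]))}\n"
            )
    with open(outdir / "drivers.txt", "wt", encoding="utf-8") as fh:
        for d in sorted(truth.drivers):
            fh.write(d + "\n")
    return X, M, network, truth
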