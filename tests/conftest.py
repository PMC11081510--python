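import logging

import numpy as np
import pandas as pd
import pytest

from pdrwh import (
    ExpressionMatrix,
    MutationProfile,
    RunConfig,
    SyntheticCohortSpec,
    call_abnormal,
    generate_synthetic_cohort,
    normalize_expression,
    prepare_cohort,
)

logging.disable(logging.INFO)


def brute_force_transition(hg):
    """Scalar-loop evaluation of the two-stage transition probability.

    Independent of the matrix-product implementation: triple loop over
    (u, e, v) summing [h(u,e) w_e / d(u)] * [w(v,e) / delta(e)].
    """
    nV, nE = hg.H.shape
    P = np.zeros((nV, nV))
    for u in range(nV):
        du = sum(hg.H[u, e] * hg.w_e[e] for e in range(nE))
        for e in range(nE):
            if hg.H[u, e] == 0:
                continue
            pick_e = hg.H[u, e] * hg.w_e[e] / du
            delta = sum(hg.Wv[v, e] for v in range(nV))
            for v in range(nV):
                P[u, v] += pick_e * hg.Wv[v, e] / delta
    return P


@pytest.fixture
def toy_cohort():
    """Hand-built 5-gene, 4-sample cohort with a hand-checkable network.

    Network: A-B, B-C, A-C (triangle) plus C-D; gene E isolated.
    """
    import networkx as nx

    genes = ["A", "B", "C", "D", "E"]
    samples = ["S1", "S2", "S3", "S4"]
    rng = np.random.default_rng(42)
    expr = pd.DataFrame(rng.normal(size=(5, 4)), index=genes, columns=samples)
    calls = pd.DataFrame(
        [
            [1, 1, 0, 0],  # A
            [1, 0, 1, 0],  # B
            [1, 1, 1, 1],  # C
            [0, 1, 0, 1],  # D
            [0, 0, 0, 1],  # E
        ],
        index=genes,
        columns=samples,
    )
    net = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
    return ExpressionMatrix(expr), MutationProfile(calls), net


@pytest.fixture(scope="session")
def small_synthetic():
    """One small seeded cohort shared across tests (100 genes, 20 samples)."""
    spec = SyntheticCohortSpec(n_genes=100, n_samples=20, n_drivers=3,
                               n_sample_groups=3, seed=7)
    return spec, generate_synthetic_cohort(spec)


@pytest.fixture(scope="session")
def small_prepared(small_synthetic):
    _, (X, M, net, truth) = small_synthetic
    cohort = prepare_cohort(X, M, net, RunConfig(min_mutations=1))
    return cohort, truth


def simulate_two_stage_walk(hg, v0, alpha, steps, rng, n_batches=50):
    """Monte-Carlo occupancy of the two-stage hyperedge walk.

    Independent of the transition-matrix code: per step, restart with
    probability 1-alpha, otherwise sample a hyperedge proportional to
    h(u,e)*w_e and then a vertex proportional to w(v,e).  Returns the
    occupancy frequencies and a batch-means standard error per
    coordinate (the chain is autocorrelated, so the naive binomial SE
    would be too small).
    """
    nV, nE = hg.H.shape
    edge_cdfs = []
    edge_ids = []
    for u in range(nV):
        w = hg.H[u] * hg.w_e
        ids = np.nonzero(w)[0]
        edge_ids.append(ids)
        edge_cdfs.append(np.cumsum(w[ids]) / w[ids].sum())
    vert_cdfs = []
    vert_ids = []
    for e in range(nE):
        w = hg.Wv[:, e]
        ids = np.nonzero(w)[0]
        vert_ids.append(ids)
        vert_cdfs.append(np.cumsum(w[ids]) / w[ids].sum())
    v0_ids = np.nonzero(v0)[0]
    v0_cdf = np.cumsum(v0[v0_ids]) / v0[v0_ids].sum()

    u = int(v0_ids[np.searchsorted(v0_cdf, rng.random())])
    counts = np.zeros((n_batches, nV))
    per_batch = steps // n_batches
    us = rng.random(size=(steps, 3))
    step = 0
    for b in range(n_batches):
        for _ in range(per_batch):
            r1, r2, r3 = us[step]
            step += 1
            if r1 >= alpha:  # restart
                u = int(v0_ids[np.searchsorted(v0_cdf, r2)])
            else:
                e = int(edge_ids[u][np.searchsorted(edge_cdfs[u], r2)])
                u = int(vert_ids[e][np.searchsorted(vert_cdfs[e], r3)])
            counts[b, u] += 1
    freqs = counts / per_batch
    emp = freqs.mean(axis=0)
    se = freqs.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return emp, se
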