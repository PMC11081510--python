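"""Readers and writers for cohort inputs and ranking outputs.

Three input kinds are supported, all plain TSV:

* expression matrix — genes in rows, samples in columns, real values;
* somatic mutation calls — either a binary gene x sample matrix, or a
  two-column long table with one (sample, gene) mutation event per line;
* gene interaction network — an undirected edge list with an optional
  confidence score column (e.g. a STRING export).

Gene symbols are uppercased at read time so that cohort matrices and
network node labels from different sources can be joined reliably.
Genes present in the cohort but absent from the network are kept; they
become isolated vertices downstream and receive a small floor weight
there rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MutationProfile",
    "ReferenceSet",
    "read_expression",
    "read_mutations",
    "read_network",
    "read_reference",
    "read_rankings",
    "write_rankings",
]


class CohortIOError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class ExpressionMatrix:
    """Cohort expression profiles, genes x samples.

    ``values`` is a DataFrame indexed by uppercased gene symbol with one
    column per sample.  Any expression unit or monotone transform is
    accepted; downstream normalization is per gene.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not self.values.map(lambda v: math.isfinite(v)).all().all():
            raise CohortIOError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MutationProfile:
    """Binary somatic mutation calls, genes x samples.

    A 1 means the gene carries a non-synonymous point mutation or indel
    in that sample.  Variant-class filtering happens before this point;
    the profile is already binarized.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.calls.index, "gene")
        _check_unique(self.calls.columns, "sample")
        bad = ~self.calls.isin([0, 1])
        if bad.any().any():
            gene = bad.any(axis=1).idxmax()
            raise CohortIOError(f"mutation matrix entry not in {{0,1}} (gene {gene})")
        self.calls = self.calls.astype("int8")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def mutated_genes(self, sample: str) -> set[str]:
        """Set of genes called mutated in ``sample``."""
        col = self.calls[sample]
        return set(col.index[col == 1])


@dataclass(frozen=True)
class ReferenceSet:
    """A named set of reference driver gene symbols."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.genes:
            raise CohortIOError(f"reference set {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def _check_unique(labels: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise CohortIOError(f"duplicate {kind} identifier: {lab}")
        seen.add(lab)


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples expression TSV.

    The first column holds gene symbols and the header row sample ids.
    Duplicate gene or sample ids and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise CohortIOError(f"{path}: no genes (empty body)")
    df.index = df.index.astype(str).str.upper()
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    try:
        body = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise CohortIOError(
                        f"{path}: non-numeric expression value {cell!r} "
                        f"at gene {gene}, sample {sample}"
                    ) from None
        raise
    return ExpressionMatrix(body)


def read_mutations(path, dialect: str = "long_tsv") -> MutationProfile:
    """Read somatic mutation calls.

    ``dialect='long_tsv'`` expects a headered two-column table
    (sample_id, gene); repeated events collapse to a single call.
    ``dialect='matrix_tsv'`` expects a binary gene x sample matrix laid
    out like the expression TSV.
    """
    if dialect == "matrix_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).str.upper()
        return MutationProfile(df)
    if dialect == "long_tsv":
        long = pd.read_csv(path, sep="\t", dtype=str)
        if long.shape[1] < 2:
            raise CohortIOError(f"{path}: long mutation table needs 2 columns")
        long = long.iloc[:, :2]
        long.columns = ["sample_id", "gene"]
        long["gene"] = long["gene"].str.upper()
        calls = (
            pd.crosstab(long["gene"], long["sample_id"])
            .clip(upper=1)
            .rename_axis(index=None, columns=None)
        )
        return MutationProfile(calls)
    raise CohortIOError(f"unknown mutation dialect: {dialect!r}")


def read_network(path, min_score: float | None = None) -> nx.Graph:
    """Read an undirected gene interaction network from an edge list TSV.

    Each line holds ``geneA<TAB>geneB[<TAB>score]``.  A header line whose
    third field is non-numeric is skipped.  Self-loops are dropped,
    duplicate edges are stored once, and if ``min_score`` is given,
    edges scoring below it are discarded.
    """
    graph = nx.Graph()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise CohortIOError(f"{path}:{lineno}: malformed network line {line!r}")
            a, b = parts[0].strip().upper(), parts[1].strip().upper()
            score = None
            if len(parts) >= 3 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError:
                    if lineno == 1:  # header row
                        continue
                    raise CohortIOError(
                        f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                    ) from None
            if a == b:
                continue
            if min_score is not None and score is not None and score < min_score:
                continue
            if score is None:
                graph.add_edge(a, b)
            else:
                graph.add_edge(a, b, score=score)
    return graph


def read_reference(path, name: str | None = None) -> ReferenceSet:
    """Read a one-symbol-per-line driver gene list; ``#`` starts a comment."""
    genes: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            sym = raw.split("#", 1)[0].strip()
            if sym:
                genes.add(sym.upper())
    return ReferenceSet(name or str(path), frozenset(genes))


def write_rankings(rankings: Sequence, path) -> None:
    """Write per-patient driver rankings as a single TSV.

    Columns are (sample_id, rank, gene, score); ranks start at 1 and rows
    are ordered by sample id then rank, so output is deterministic.
    """
    if not rankings:
        raise CohortIOError("no rankings to write")
    rows = []
    for ranking in sorted(rankings, key=lambda r: r.sample_id):
        for rank, (gene, score) in enumerate(ranking.entries, start=1):
            rows.append((ranking.sample_id, rank, gene, f"{score:.8g}"))
    out = pd.DataFrame(rows, columns=["sample_id", "rank", "gene", "score"])
    out.to_csv(path, sep="\t", index=False)


def read_rankings(path) -> dict[str, list[tuple[str, float]]]:
    """Read a rankings TSV back as {sample_id: [(gene, score), ...]} in rank order."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    out: dict[str, list[tuple[str, float]]] = {}
    for sample, block in df.groupby("sample_id", sort=True):
        block = block.sort_values("rank")
        out[str(sample)] = list(zip(block["gene"], block["score"].astype(float)))
    return out
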