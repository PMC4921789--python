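"""Overlapping module detection by k-clique percolation (CPM).

A module (community) is the union of all k-cliques that can be reached
from one another through a chain of k-cliques sharing k-1 nodes.  CPM
communities may overlap, which suits co-expression networks where one
gene can belong to several functional contexts.  Edges are unweighted:
the MR/tier filters upstream decide which pairs enter the graph.

The implementation enumerates the k-cliques of each maximal clique
(Bron-Kerbosch via :func:`networkx.find_cliques`) and unions them with a
disjoint-set structure keyed by their (k-1)-node subsets, which is
exactly the percolation adjacency relation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_K = 5
MAX_MODULE_SIZE = 500


@dataclass
class ModuleSet:
    """Communities found at one k, as sorted node tuples."""

    communities: list[tuple[str, ...]]
    k: int

    def __post_init__(self) -> None:
        self.communities = sorted(
            (tuple(sorted(c)) for c in self.communities), key=lambda c: (-len(c), c)
        )

    def __len__(self) -> int:
        return len(self.communities)

    def __iter__(self):
        return iter(self.communities)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities]

    @property
    def covered_genes(self) -> set[str]:
        return set().union(*map(set, self.communities)) if self.communities else set()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "module_id": [f"M{i + 1:04d}" for i in range(len(self.communities))],
            "k": self.k,
            "size": self.sizes,
            "genes": [",".join(c) for c in self.communities],
        })

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class _DisjointSet:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def add(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def k_clique_communities(g: nx.Graph, k: int = DEFAULT_K) -> ModuleSet:
    """All CPM communities of *g* at clique size *k* (k >= 3)."""
    if k < 3:
        raise ValueError("k must be >= 3 for clique percolation")
    kcliques: set[frozenset] = set()
    for maximal in nx.find_cliques(g):
        if len(maximal) >= k:
            for comb in itertools.combinations(sorted(maximal), k):
                kcliques.add(frozenset(comb))
    cliques = sorted(kcliques, key=sorted)
    ds = _DisjointSet()
    owner: dict[frozenset, int] = {}
    for idx, cq in enumerate(cliques):
        ds.add(idx)
        for node in cq:
            sub = cq - {node}
            if sub in owner:
                ds.union(owner[sub], idx)
            else:
                owner[sub] = idx
    groups: dict[int, set[str]] = {}
    for idx, cq in enumerate(cliques):
        groups.setdefault(ds.find(idx), set()).update(cq)
    return ModuleSet(communities=[tuple(sorted(c)) for c in groups.values()], k=k)


def filter_modules(ms: ModuleSet, max_size: int = MAX_MODULE_SIZE) -> ModuleSet:
    """Drop communities with more than *max_size* nodes (bound exclusive)."""
    if max_size < ms.k:
        raise ValueError("max_size must be >= k")
    kept = [c for c in ms.communities if len(c) <= max_size]
    removed = len(ms.communities) - len(kept)
    if removed:
        log.info("filter_modules removed %d communities larger than %d nodes",
                 removed, max_size)
    return ModuleSet(communities=kept, k=ms.k)


def k_selection_summary(g: nx.Graph, k_range=range(3, 9)) -> pd.DataFrame:
    """Diagnostics for choosing k: community count, gene coverage, mean
    pairwise Jaccard overlap of communities sharing at least one node,
    and the largest community size, per candidate k.

    A good k balances coverage (favouring small k) against module
    distinctness (overlap rate; favouring larger k).
    """
    ks = list(k_range)
    if any(k < 3 or k > 10 for k in ks):
        raise ValueError("k_range must lie within [3, 10]")
    rows = []
    for k in ks:
        ms = k_clique_communities(g, k)
        comms = [set(c) for c in ms.communities]
        overlaps = [
            len(a & b) / len(a | b)
            for a, b in itertools.combinations(comms, 2)
            if a & b
        ]
        rows.append({
            "k": k,
            "n_communities": len(comms),
            "coverage": len(ms.covered_genes),
            "mean_overlap": sum(overlaps) / len(overlaps) if overlaps else 0.0,
            "max_size": max(ms.sizes) if comms else 0,
        })
    return pd.DataFrame(rows).set_index("k")


def graph_from_edges(edges: pd.DataFrame, signs=("positive",),
                     tiers=(1, 2, 3)) -> nx.Graph:
    """Build the CPM input graph from a tier-classified edge table.

    Defaults to the union of positive tiers 1-3.
    """
    sel = edges[edges["sign"].isin(signs) & edges["tier"].isin(list(tiers))]
    g = nx.Graph()
    g.add_edges_from(zip(sel["gene_a"], sel["gene_b"]))
    return g
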