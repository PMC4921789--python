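"""Interolog PPI projection and the merged multi-type network.

Protein-protein interactions measured in reference species are
transferred to the target species through orthologous gene pairs
(*interologs*): a reference interaction (A, B) projects onto every
target pair (a, b) with a an ortholog of A and b of B, both at or above
a confidence threshold (default 0.6, i.e. 60%).  The projected PPIs,
the signed co-expression edges and precomputed miRNA-target pairs are
merged into one heterogeneous network with typed edges, exportable to
Cytoscape-readable SIF/GraphML and to an edge-attribute TSV.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

EDGE_TYPES = ("coexp_pos", "coexp_neg", "ppi_pred", "mirna_target")
SIF_TOKENS = {"coexp_pos": "pp", "coexp_neg": "nn", "ppi_pred": "pd",
              "mirna_target": "mt"}
DEFAULT_MIN_CONFIDENCE = 0.6


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# interolog projection
# ---------------------------------------------------------------------------

def project_interologs(ppis: pd.DataFrame, orthologs: pd.DataFrame,
                       min_conf: float = DEFAULT_MIN_CONFIDENCE) -> pd.DataFrame:
    """Map reference-species PPIs onto the target species via orthologs.

    *ppis* needs columns ``gene_a, gene_b`` (reference ids) and
    optionally ``source``; *orthologs* needs
    ``ref_gene, target_gene, confidence``.  Exact duplicate projected
    pairs are collapsed with merged evidence; self-pairs (a == b) are
    kept but flagged ``self_interaction``.
    """
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError("min_conf must lie in [0, 1]")
    conf = orthologs["confidence"].astype(float)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("ortholog confidences must lie in [0, 1]")
    usable = orthologs[conf >= min_conf]
    targets: dict[str, list[str]] = {}
    for row in usable.itertuples(index=False):
        targets.setdefault(str(row.ref_gene), []).append(str(row.target_gene))
    merged: dict[tuple[str, str], set[str]] = {}
    has_source = "source" in ppis.columns
    for row in ppis.itertuples(index=False):
        evidence = str(row.source) if has_source else "interolog"
        for a in targets.get(str(row.gene_a), ()):
            for b in targets.get(str(row.gene_b), ()):
                merged.setdefault(_canonical(a, b), set()).add(evidence)
    rows = [(a, b, ",".join(sorted(ev)), a == b)
            for (a, b), ev in sorted(merged.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evidence",
                                       "self_interaction"])


# ---------------------------------------------------------------------------
# the multi-type network
# ---------------------------------------------------------------------------

class MultiNet:
    """Heterogeneous network of typed gene/miRNA edges.

    Backed by a :class:`networkx.MultiGraph` whose edge key is the edge
    type, so one gene pair can carry several relationships (e.g. both a
    positive co-expression edge and a predicted PPI) but never two
    edges of the same type.  Node type defaults to ``mirna`` for ids
    containing ``miR`` (the sbi-miR naming convention), ``gene``
    otherwise; an override table can force either.
    """

    def __init__(self, node_types: dict[str, str] | None = None) -> None:
        self.graph = nx.MultiGraph()
        self._overrides = dict(node_types or {})

    def node_type(self, node: str) -> str:
        if node in self._overrides:
            return self._overrides[node]
        return "mirna" if "miR" in node else "gene"

    def add_edge(self, a: str, b: str, edge_type: str, **attrs) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type: {edge_type}")
        a, b = str(a), str(b)
        for node in (a, b):
            self.graph.add_node(node, node_type=self.node_type(node))
        u, v = _canonical(a, b)
        self.graph.add_edge(u, v, key=edge_type, edge_type=edge_type, **attrs)

    # -- queries ---------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self, edge_types=None) -> list[tuple[str, str, str]]:
        wanted = set(edge_types) if edge_types is not None else set(EDGE_TYPES)
        return sorted((u, v, k) for u, v, k in self.graph.edges(keys=True)
                      if k in wanted)

    def summary(self, genome_size: int | None = None) -> dict:
        by_type = {t: 0 for t in EDGE_TYPES}
        for _, _, k in self.graph.edges(keys=True):
            by_type[k] += 1
        out = {
            "n_nodes": self.graph.number_of_nodes(),
            "n_genes": sum(1 for n in self.graph
                           if self.graph.nodes[n]["node_type"] == "gene"),
            "n_mirnas": sum(1 for n in self.graph
                            if self.graph.nodes[n]["node_type"] == "mirna"),
            "n_edges": self.graph.number_of_edges(),
            "edges_by_type": {t: c for t, c in by_type.items() if c},
        }
        if genome_size:
            out["genome_size"] = int(genome_size)
            out["coverage_pct"] = round(100.0 * out["n_genes"] / genome_size, 1)
        return out

    def neighborhood(self, seed: str, edge_types=None, depth: int = 1) -> "MultiNet":
        """Induced sub-network within *depth* hops of *seed* via the
        selected edge types, including all qualifying edges among the
        reached nodes.  depth 0 or an empty type set yields the seed alone.
        """
        if seed not in self.graph:
            raise KeyError(f"unknown seed node: {seed}")
        wanted = set(edge_types) if edge_types is not None else set(EDGE_TYPES)
        frontier, reached = {seed}, {seed}
        for _ in range(depth):
            nxt = set()
            for node in frontier:
                for _, nbr, k in self.graph.edges(node, keys=True):
                    if k in wanted and nbr not in reached:
                        nxt.add(nbr)
            reached |= nxt
            frontier = nxt
            if not frontier:
                break
        sub = MultiNet(node_types=self._overrides)
        for node in reached:
            sub.graph.add_node(node, **self.graph.nodes[node])
        for u, v, k, data in self.graph.edges(keys=True, data=True):
            if k in wanted and u in reached and v in reached:
                sub.graph.add_edge(u, v, key=k, **data)
        return sub

    # -- exports ---------------------------------------------------------

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, k in self.edges():
                fh.write(f"{u}\t{SIF_TOKENS[k]}\t{v}\n")

    def to_graphml(self, path) -> None:
        g = nx.MultiGraph()
        g.add_nodes_from(sorted(self.graph.nodes(data=True)))
        for u, v, k in self.edges():
            data = {kk: vv for kk, vv in self.graph[u][v][k].items()
                    if vv is not None}
            g.add_edge(u, v, key=k, **data)
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path) -> "MultiNet":
        g = nx.read_graphml(path, force_multigraph=True)
        net = cls()
        for node, data in g.nodes(data=True):
            net.graph.add_node(node, **data)
        for u, v, k, data in g.edges(keys=True, data=True):
            uu, vv = _canonical(u, v)
            net.graph.add_edge(uu, vv, key=data.get("edge_type", k), **data)
        return net

    def to_tsv(self, path) -> None:
        attr_keys = sorted({kk for _, _, d in self.graph.edges(data=True)
                            for kk in d if kk != "edge_type"})
        rows = []
        for u, v, k in self.edges():
            data = self.graph[u][v][k]
            rows.append([u, v, k] + [data.get(a, "") for a in attr_keys])
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "edge_type"] + attr_keys
                     ).to_csv(path, sep="\t", index=False)


def merge_networks(coexp_edges: pd.DataFrame | None = None,
                   ppi_edges: pd.DataFrame | None = None,
                   mirna_pairs: pd.DataFrame | None = None,
                   node_types: dict[str, str] | None = None) -> MultiNet:
    """Union of typed edge sets into one :class:`MultiNet`.

    *coexp_edges* is a tier-classified table (``sign`` decides
    coexp_pos/coexp_neg and pcc/mr/tier ride along); *ppi_edges* is a
    projected-PPI table (``evidence`` kept); *mirna_pairs* needs columns
    ``mirna, target`` with an optional ``score``.
    """
    net = MultiNet(node_types=node_types)
    if coexp_edges is not None:
        for row in coexp_edges.itertuples(index=False):
            etype = "coexp_pos" if row.sign == "positive" else "coexp_neg"
            net.add_edge(row.gene_a, row.gene_b, etype, pcc=float(row.pcc),
                         mr=float(row.mr), tier=int(getattr(row, "tier", 0)))
    if ppi_edges is not None:
        for row in ppi_edges.itertuples(index=False):
            net.add_edge(row.gene_a, row.gene_b, "ppi_pred",
                         evidence=str(getattr(row, "evidence", "")))
    if mirna_pairs is not None:
        for row in mirna_pairs.itertuples(index=False):
            attrs = {}
            if hasattr(row, "score") and pd.notna(row.score):
                attrs["score"] = float(row.score)
            net.add_edge(row.mirna, row.target, "mirna_target", **attrs)
    return net
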