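"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately written in the most literal way possible
(full sorted lists, exact rational arithmetic, sliding windows) and
shares no code with the package paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import networkx as nx
import pandas as pd

# ---------------------------------------------------------------------------
# tiered-edge classification: materialize full sorted PCC lists
# ---------------------------------------------------------------------------

def brute_force_edges(ct: pd.DataFrame, top_n: int = 3, mr_level2: float = 5.0,
                      mr_level3: float = 30.0) -> dict:
    """{(gene_a, gene_b): (mr, sign, tier)} with gene_a < gene_b."""
    genes = sorted(ct.index)

    def ranks(gene: str, sign: str) -> dict:
        row = ct.loc[gene]
        items = [(p, row[p]) for p in genes if p != gene and pd.notna(row[p])]
        if sign == "+":
            items = sorted(((p, v) for p, v in items if v > 0),
                           key=lambda t: (-t[1], t[0]))
        else:
            items = sorted(((p, v) for p, v in items if v < 0),
                           key=lambda t: (t[1], t[0]))
        return {p: i + 1 for i, (p, _) in enumerate(items)}

    rank = {(g, s): ranks(g, s) for g in genes for s in "+-"}
    edges = {}
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            v = ct.loc[gi, gj]
            if pd.isna(v) or v == 0:
                continue
            s = "+" if v > 0 else "-"
            a, b = rank[(gi, s)][gj], rank[(gj, s)][gi]
            mr = math.sqrt(a * b)
            if a <= top_n or b <= top_n:
                tier = 1
            elif mr <= mr_level2:
                tier = 2
            elif mr <= mr_level3:
                tier = 3
            else:
                continue
            edges[(gi, gj)] = (mr, "positive" if s == "+" else "negative", tier)
    return edges


# ---------------------------------------------------------------------------
# clique percolation: exhaustive definition via networkx
# ---------------------------------------------------------------------------

def cpm_reference(g: nx.Graph, k: int) -> set[frozenset]:
    return {frozenset(c) for c in nx.community.k_clique_communities(g, k)}


# ---------------------------------------------------------------------------
# hypergeometric: exact rational arithmetic
# ---------------------------------------------------------------------------

def exact_hypergeom_pmf(N: int, n: int, K: int, k: int) -> Fraction:
    return Fraction(math.comb(n, k) * math.comb(N - n, K - k), math.comb(N, K))


def exact_hypergeom_tail(N: int, n: int, K: int, k: int) -> Fraction:
    return sum((exact_hypergeom_pmf(N, n, K, j)
                for j in range(k, min(n, K) + 1)), Fraction(0))


# ---------------------------------------------------------------------------
# IUPAC motif scan: regex-free sliding window
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def _window_matches(seq: str, consensus: str, pos: int) -> bool:
    return all(base in _IUPAC[c]
               for base, c in zip(seq[pos:pos + len(consensus)], consensus))


def sliding_window_scan(seq: str, consensus: str) -> list[tuple[int, int, str]]:
    seq, consensus = seq.upper(), consensus.upper()
    rc = "".join(_COMP[c] for c in reversed(consensus))
    w = len(consensus)
    hits = []
    for pos in range(len(seq) - w + 1):
        fwd = _window_matches(seq, consensus, pos)
        rev = _window_matches(seq, rc, pos)
        if fwd:
            hits.append((pos, pos + w, "+"))
        elif rev:
            hits.append((pos, pos + w, "-"))
    return hits
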