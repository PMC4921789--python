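"""Signed PCC / mutual-rank co-expression networks with tiered edges.

The network is built from the Pearson correlation (PCC) of every gene
pair.  Because absolute PCC values are hard to threshold consistently
across genes, edges are scored by *mutual rank* (MR): each gene ranks
its partners by PCC, and for a pair whose reciprocal rank positions are
``a`` and ``b`` (1-based), ``MR = sqrt(a * b)`` -- the geometric mean of
the two ranks.  Low MR means both genes place each other near the top
of their lists.

Edges are then assigned to three confidence tiers:

* tier 1 -- either endpoint holds the other within its top ``top_n``
  partners by PCC (default 3);
* tier 2 -- remaining pairs with ``MR <= 5``;
* tier 3 -- remaining pairs with ``5 < MR <= 30``.

Positive (PCC > 0) and negative (PCC < 0) networks are ranked and
tiered independently: in the positive network rank 1 is the highest
PCC, in the negative network rank 1 is the most negative PCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

EDGE_COLUMNS = ("gene_a", "gene_b", "pcc", "mr", "sign", "tier")


class InsufficientDataError(ValueError):
    """Fewer than three pairwise-complete observations."""


class ConstantVectorError(ValueError):
    """A vector is constant over the complete pairs; PCC is undefined."""


@dataclass(frozen=True)
class TierConfig:
    """Edge-tier thresholds.

    top_n:      tier-1 rank bound (top PCC partners, either direction).
    mr_level2:  MR bound for tier 2.
    mr_level3:  MR bound for tier 3 (edges above it are dropped).
    min_abs_pcc: optional |PCC| floor applied before ranking-based tiers;
                 0 by default (the tiers themselves do the filtering).
    """

    top_n: int = 3
    mr_level2: float = 5.0
    mr_level3: float = 30.0
    min_abs_pcc: float = 0.0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0 < self.mr_level2 < self.mr_level3):
            raise ValueError("require 0 < mr_level2 < mr_level3")
        if not (0.0 <= self.min_abs_pcc < 1.0):
            raise ValueError("min_abs_pcc must be in [0, 1)")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_cc(x: Iterable[float], y: Iterable[float]) -> float:
    """Sample Pearson correlation over pairwise-complete observations.

    Raises :class:`InsufficientDataError` with fewer than three complete
    pairs and :class:`ConstantVectorError` when either vector is constant
    over them (zero variance makes the coefficient undefined).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"only {int(ok.sum())} pairwise-complete observations (need >= 3)"
        )
    xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    denom = math.sqrt(float(xs @ xs) * float(ys @ ys))
    if denom == 0.0:
        raise ConstantVectorError("constant vector over complete pairs")
    return float(np.clip((xs @ ys) / denom, -1.0, 1.0))


def correlation_table(m: pd.DataFrame) -> pd.DataFrame:
    """All-pairs PCC table (pairwise-complete, min 3 shared samples).

    The diagonal and pairs with undefined correlation (constant gene or
    fewer than three shared samples) are ``NaN``.
    """
    if m.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    ct = m.T.corr(method="pearson", min_periods=3)
    np.fill_diagonal(ct.values, np.nan)
    return ct


# ---------------------------------------------------------------------------
# mutual rank
# ---------------------------------------------------------------------------

def mutual_rank(a: int, b: int) -> float:
    """Geometric mean sqrt(a*b) of the two reciprocal rank positions."""
    if int(a) != a or int(b) != b or a < 1 or b < 1:
        raise ValueError("ranks must be integers >= 1")
    return math.sqrt(a * b)


def rank_partners(ct: pd.DataFrame, gene: str, sign: str) -> pd.Series:
    """Rank a gene's partners for one sign of the network.

    sign ``"+"``: partners with PCC > 0 ranked by descending PCC;
    sign ``"-"``: partners with PCC < 0 ranked by ascending PCC (most
    negative first).  Ranks start at 1 with step 1; ties are broken by
    partner id ascending.  Returns a Series partner_id -> rank.
    """
    if gene not in ct.index:
        raise KeyError(f"gene not in correlation table: {gene}")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    row = ct.loc[gene].drop(labels=[gene], errors="ignore").dropna()
    sel = row[row > 0] if sign == "+" else row[row < 0]
    frame = sel.rename("pcc").reset_index().rename(columns={"index": "partner"})
    frame.columns = ["partner", "pcc"]
    ascending = sign == "-"
    frame = frame.sort_values(["pcc", "partner"], ascending=[ascending, True],
                              kind="mergesort")
    return pd.Series(np.arange(1, len(frame) + 1), index=frame["partner"].to_numpy(),
                     name="rank")


def _rank_matrix(P: np.ndarray, positive: bool) -> np.ndarray:
    """Dense per-row rank positions for one sign; 0 where not a candidate.

    Assumes the gene axis is lexicographically sorted so that the
    tie-break (equal PCC -> smaller id first) is the column order.
    """
    n = P.shape[0]
    ranks = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        row = P[i]
        cand = np.where(np.isfinite(row) & ((row > 0) if positive else (row < 0)))[0]
        if cand.size == 0:
            continue
        key = -row[cand] if positive else row[cand]
        # stable sort on PCC keeps id-ascending order within ties
        order = cand[np.argsort(key, kind="stable")]
        ranks[i, order] = np.arange(1, order.size + 1)
    return ranks


def classify_edges(ct: pd.DataFrame, cfg: TierConfig = TierConfig()) -> pd.DataFrame:
    """Assign every retained gene pair to a tier.

    Tiers are exclusive and assigned in order: tier 1 (either endpoint
    ranks the other within ``top_n`` for that pair's sign), then tier 2
    (``MR <= mr_level2``), then tier 3 (``MR <= mr_level3``); everything
    else is dropped.  Returns a DataFrame with columns
    gene_a, gene_b, pcc, mr, sign, tier  (gene_a < gene_b, sorted).
    """
    genes = sorted(ct.index)
    ct = ct.loc[genes, genes]
    P = ct.to_numpy(dtype=float, copy=True)
    out: list[tuple] = []
    for positive in (True, False):
        ranks = _rank_matrix(P, positive)
        ii, jj = np.nonzero(np.triu(ranks, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            pcc = P[i, j]
            if abs(pcc) < cfg.min_abs_pcc:
                continue
            a, b = int(ranks[i, j]), int(ranks[j, i])
            mr = math.sqrt(a * b)
            if a <= cfg.top_n or b <= cfg.top_n:
                tier = 1
            elif mr <= cfg.mr_level2:
                tier = 2
            elif mr <= cfg.mr_level3:
                tier = 3
            else:
                continue
            out.append((genes[i], genes[j], float(pcc), mr,
                        "positive" if positive else "negative", tier))
    edges = pd.DataFrame(out, columns=EDGE_COLUMNS)
    return edges.sort_values(["gene_a", "gene_b"], kind="mergesort",
                             ignore_index=True)


def build_coexpression_network(
    m: pd.DataFrame,
    cfg: TierConfig = TierConfig(),
    genome_size: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Correlation table + tier classification + summary counts.

    Returns ``(edges, summary)`` where summary reports per-sign/per-tier
    edge counts, the number of network nodes and, when *genome_size* is
    given, node coverage as a percentage of the genome.
    """
    ct = correlation_table(m)
    edges = classify_edges(ct, cfg)
    nodes = pd.unique(edges[["gene_a", "gene_b"]].to_numpy().ravel())
    summary: dict = {
        "n_genes_in": int(len(m)),
        "n_edges": int(len(edges)),
        "n_nodes": int(len(nodes)),
        "edges_by_sign": edges["sign"].value_counts().to_dict(),
        "edges_by_tier": {int(k): int(v)
                          for k, v in edges["tier"].value_counts().items()},
    }
    if genome_size:
        summary["genome_size"] = int(genome_size)
        summary["coverage_pct"] = round(100.0 * len(nodes) / genome_size, 1)
    return edges, summary


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_edge_table(edges: pd.DataFrame, path) -> None:
    """TSV with pcc at 4 decimals and mr at 3 (deterministic row order)."""
    out = edges.copy()
    out["pcc"] = out["pcc"].map(lambda v: f"{v:.4f}")
    out["mr"] = out["mr"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return edges


def write_sif(edges: pd.DataFrame, path, relation: str = "pp") -> None:
    """Cytoscape SIF: one ``gene_a <relation> gene_b`` line per edge."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.gene_a}\t{relation}\t{row.gene_b}\n")
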