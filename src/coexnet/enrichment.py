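"""Overlap-based gene-set enrichment (hypergeometric / one-sided Fisher).

For a query of ``n`` genes drawn from a universe of ``N``, the chance of
seeing ``k`` or more members of a gene set of size ``K`` is the upper
tail of the hypergeometric distribution -- identical to a one-sided
Fisher exact test.  The enrichment p-value per set is that tail
probability; q-values come from Benjamini-Hochberg FDR across all sets
tested in a call.  The default universe size is the sorghum v2.1 gene
count (33,032), overridable per collection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: Sorghum bicolor v2.1 annotated gene count; default enrichment universe.
DEFAULT_UNIVERSE_SIZE = 33032

RESULT_COLUMNS = ("set_id", "n", "k", "K", "N", "p_value", "q_value", "description")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they live in.

    If an explicit *universe* is given it defines both membership and N;
    otherwise only *universe_size* is used and membership is not checked.
    """

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset | None = None
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        self.sets = {sid: frozenset(g) for sid, g in self.sets.items()}
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")
            if self.universe is not None and not members <= self.universe:
                raise ValueError(f"gene set {sid!r} not a subset of the universe")

    @property
    def N(self) -> int:
        return len(self.universe) if self.universe is not None else self.universe_size


def read_gmt(path, universe: frozenset | None = None,
             universe_size: int = DEFAULT_UNIVERSE_SIZE) -> GeneSetCollection:
    """Read GMT (set_id <tab> description <tab> member...)."""
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
            desc[parts[0]] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc, universe=universe,
                             universe_size=universe_size)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(gsc.sets):
            members = "\t".join(sorted(gsc.sets[sid]))
            fh.write(f"{sid}\t{gsc.descriptions.get(sid, '')}\t{members}\n")


# ---------------------------------------------------------------------------
# hypergeometric machinery
# ---------------------------------------------------------------------------

def _check_bounds(N: int, n: int, K: int, k: int) -> None:
    if not (0 <= k <= min(n, K) and 0 < K <= N and 0 < n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} n={n} K={K} k={k}")


def hypergeom_pmf(N: int, n: int, K: int, k: int) -> float:
    """P(overlap == k) = C(n,k) C(N-n, K-k) / C(N,K) (log-space internally)."""
    _check_bounds(N, n, K, k)
    return float(hypergeom.pmf(k, N, K, n))


def hypergeom_tail(N: int, n: int, K: int, k: int) -> float:
    """P(overlap >= k): the one-sided enrichment p-value."""
    _check_bounds(N, n, K, k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def gsea(query, gsc: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Enrichment of *query* against every set with a non-empty overlap.

    Returns a DataFrame (columns :data:`RESULT_COLUMNS` plus
    ``significant``) sorted by p-value then set id.  Query genes outside
    an explicit universe are dropped with a warning.
    """
    qset = set(query)
    if gsc.universe is not None:
        outside = qset - gsc.universe
        if outside:
            warnings.warn(f"{len(outside)} query genes outside the universe "
                          "were dropped")
            qset -= outside
    if not qset:
        raise ValueError("query is empty after universe filtering")
    n, N = len(qset), gsc.N
    rows = []
    for sid in sorted(gsc.sets):
        members = gsc.sets[sid]
        k = len(qset & members)
        if k == 0:
            continue
        p = hypergeom_tail(N, n, len(members), k)
        rows.append((sid, n, k, len(members), N, p,
                     gsc.descriptions.get(sid, "")))
    res = pd.DataFrame(rows, columns=["set_id", "n", "k", "K", "N", "p_value",
                                      "description"])
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
    else:
        res["q_value"] = pd.Series(dtype=float)
    res["significant"] = res["q_value"] <= alpha if len(res) else False
    res = res.sort_values(["p_value", "set_id"], kind="mergesort",
                          ignore_index=True)
    return res[list(RESULT_COLUMNS) + ["significant"]]


def annotate_modules(ms, gsc: GeneSetCollection, p_max: float = 0.05,
                     q_max: float = 0.05) -> pd.DataFrame:
    """Label each module with the gene sets enriched at both thresholds.

    Returns one row per module with the passing set ids (comma-joined,
    best p first) or ``"unannotated"`` when none pass.
    """
    if not len(ms.communities):
        raise ValueError("module set is empty")
    rows = []
    for i, community in enumerate(ms.communities):
        try:
            res = gsea(community, gsc)
        except ValueError:
            res = pd.DataFrame(columns=list(RESULT_COLUMNS))
        hits = res[(res["p_value"] <= p_max) & (res["q_value"] <= q_max)] \
            if len(res) else res
        rows.append({
            "module_id": f"M{i + 1:04d}",
            "size": len(community),
            "annotation": ",".join(hits["set_id"]) if len(hits) else "unannotated",
            "best_p": float(hits["p_value"].iloc[0]) if len(hits) else float("nan"),
        })
    return pd.DataFrame(rows)
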