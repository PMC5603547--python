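"""Hypergeometric pathway over-representation and the lncRNA-pathway
projection network.

Enrichment of a query gene list (typically the differentially expressed
mRNAs) in each annotated gene set uses the upper-tail hypergeometric test
(inclusive of the observed overlap), BH adjustment across the tested sets,
and the rich factor — observed overlap divided by its expected value under
the hypergeometric null, k*N/(K*n).

The projection links a lncRNA to a pathway when at least ``min_support`` of
its co-expressed mRNA partners belong to that pathway's gene set, by
default restricted to the significantly enriched pathways.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import network_nodes
from .de import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeom_pvalue",
    "rich_factor",
    "hypergeom_enrich",
    "build_lnc_pathway_network",
    "pathway_lncrna_counts",
]


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file into {pathway_id: (description, gene set)}."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need id, description, genes): {line[:60]}")
            sets[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(sets):
            desc, genes = sets[pid]
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p = P(X >= k) with X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError("pathway and query sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def rich_factor(k: int, K: int, n: int, N: int) -> float:
    """Observed overlap over expected overlap: k*N/(K*n)."""
    if K <= 0 or n <= 0 or N <= 0:
        raise ValueError("K, n and N must be positive")
    return k * N / (K * n)


def hypergeom_enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, tuple[str, frozenset[str]]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    The universe is typically the expressed genes surviving the CPM filter.
    Query ids outside the universe are dropped (count reported in
    ``df.attrs["n_query_dropped"]``); gene sets with no universe member are
    skipped (``df.attrs["skipped_empty"]``).  Returns one row per tested
    set with N, K, n, k, pvalue, BH qvalue, rich_factor and a boolean
    ``significant`` (q < alpha), sorted by p-value.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query_all = frozenset(query)
    query_u = query_all & universe
    rows, skipped = [], []
    for pid in sorted(gene_sets):
        desc, genes = gene_sets[pid]
        K = len(genes & universe)
        if K == 0:
            skipped.append(pid)
            continue
        k = len(genes & query_u)
        N, n = len(universe), len(query_u)
        rows.append(
            {
                "pathway_id": pid,
                "description": desc,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "pvalue": hypergeom_pvalue(k, K, n, N),
                "rich_factor": rich_factor(k, K, n, N),
            }
        )
    if not rows:
        raise ValueError("no testable gene set overlaps the universe")
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] < alpha
    df = df.sort_values(["pvalue", "pathway_id"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_query_dropped"] = len(query_all - universe)
    df.attrs["skipped_empty"] = skipped
    return df


def build_lnc_pathway_network(
    coexp: nx.Graph,
    enrichment: pd.DataFrame,
    gene_sets: Mapping[str, tuple[str, frozenset[str]]],
    require_enriched: bool = True,
    min_support: int = 1,
) -> nx.Graph:
    """Project the co-expression network onto pathways.

    For each lncRNA node of ``coexp`` and each pathway (restricted to rows
    of ``enrichment`` with ``significant`` True when ``require_enriched``),
    an edge is added when at least ``min_support`` of the lncRNA's mRNA
    neighbors lie in the pathway's gene set; the supporting mRNAs are
    stored on the edge.  An empty co-expression network yields an empty
    projection.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    rows = enrichment[enrichment["significant"]] if require_enriched else enrichment
    pathways = [p for p in rows["pathway_id"] if p in gene_sets]
    g = nx.Graph(params={"require_enriched": require_enriched, "min_support": min_support})
    lncs = network_nodes(coexp, biotype="lncRNA")
    for lnc in lncs:
        neighbors = frozenset(coexp.neighbors(lnc))
        for pid in pathways:
            support = sorted(neighbors & gene_sets[pid][1])
            if len(support) >= min_support:
                g.add_node(lnc, kind="lncRNA", bipartite=0)
                g.add_node(pid, kind="pathway", bipartite=1)
                g.add_edge(lnc, pid, supporting_mrnas=tuple(support), n_support=len(support))
    return g


def pathway_lncrna_counts(projection: nx.Graph) -> pd.DataFrame:
    """Per-pathway count of linked regulatory lncRNAs, sorted descending."""
    rows = [
        {"pathway_id": n, "n_lncrnas": projection.degree(n)}
        for n, d in projection.nodes(data=True)
        if d.get("kind") == "pathway"
    ]
    df = pd.DataFrame(rows, columns=["pathway_id", "n_lncrnas"])
    return df.sort_values(
        ["n_lncrnas", "pathway_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
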