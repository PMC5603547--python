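"""lncRNA-mRNA co-expression network construction and hub selection.

Every differentially expressed lncRNA is paired with every differentially
expressed mRNA; the Pearson correlation of their normalized expression
profiles is tested (two-sided t on n-2 degrees of freedom), p-values are
Benjamini-Hochberg adjusted jointly over all tested pairs, and pairs with
r above a high threshold (0.99 by default, positive-only) and q below the
FDR threshold become edges of a bipartite graph.  Hubs are the top-degree
nodes, either a fixed top-k (default 20) or a top fraction of nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "pearson_r",
    "corr_pvalue",
    "build_network",
    "network_nodes",
    "select_hubs",
    "HubSet",
]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def corr_pvalue(r: float, n: int) -> float:
    """Two-sided p for H0: rho = 0 via t = r*sqrt(n-2)/sqrt(1-r^2).

    |r| = 1 returns 0 by convention.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlations between two matrices over shared columns.

    Rows with zero variance yield NaN.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(sa, sb)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def build_network(
    expr: pd.DataFrame,
    de_lnc: Iterable[str],
    de_mrna: Iterable[str],
    r_threshold: float = 0.99,
    q_threshold: float = 0.05,
    signed: str = "positive",
    samples: Sequence[str] | None = None,
) -> nx.Graph:
    """Bipartite lncRNA-mRNA co-expression network from normalized expression.

    Tests every (lncRNA, mRNA) pair over the selected ``samples`` (all
    columns by default), BH-adjusts the t-test p-values over all pairs
    jointly, and keeps pairs with q < ``q_threshold`` and r >=
    ``r_threshold`` (``signed="positive"``) or |r| >= ``r_threshold``
    (``signed="absolute"``).  Returns a graph whose nodes carry ``biotype``
    and ``bipartite`` attributes and whose edges carry ``r``, ``pvalue``,
    ``qvalue``; only nodes incident to at least one edge are included.
    Pairs where either profile is constant are untestable and skipped (the
    count is recorded in ``G.graph["n_zero_variance_pairs"]``).
    """
    if signed not in ("positive", "absolute"):
        raise ValueError("signed must be 'positive' or 'absolute'")
    de_lnc = sorted(dict.fromkeys(de_lnc))
    de_mrna = sorted(dict.fromkeys(de_mrna))
    if set(de_lnc) & set(de_mrna):
        raise ValueError("a gene cannot be both lncRNA and mRNA")
    missing = (set(de_lnc) | set(de_mrna)) - set(expr.index)
    if missing:
        raise ValueError(f"ids absent from expression matrix: {sorted(missing)[:5]}...")
    cols = list(expr.columns) if samples is None else list(samples)
    if len(cols) < 3:
        raise ValueError("need at least 3 samples to correlate")
    if not de_lnc or not de_mrna:
        raise ValueError("need at least one lncRNA and one mRNA to test")

    n = len(cols)
    a = expr.loc[de_lnc, cols].to_numpy(dtype=float)
    b = expr.loc[de_mrna, cols].to_numpy(dtype=float)
    r = _pairwise_corr(a, b)
    testable = ~np.isnan(r)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0

    q = np.full_like(p, np.nan)
    q[testable] = bh_adjust(p[testable])

    strong = r >= r_threshold if signed == "positive" else np.abs(r) >= r_threshold
    keep = testable & strong & (q < q_threshold)

    g = nx.Graph(
        params={
            "r_threshold": r_threshold,
            "q_threshold": q_threshold,
            "signed": signed,
            "n_samples": n,
        },
        n_pairs_tested=int(testable.sum()),
        n_zero_variance_pairs=int((~testable).sum()),
    )
    for i, j in zip(*np.nonzero(keep)):
        lnc, mrna = de_lnc[i], de_mrna[j]
        g.add_node(lnc, biotype="lncRNA", bipartite=0)
        g.add_node(mrna, biotype="mRNA", bipartite=1)
        g.add_edge(lnc, mrna, r=float(r[i, j]), pvalue=float(p[i, j]), qvalue=float(q[i, j]))
    return g


def network_nodes(g: nx.Graph, biotype: str | None = None) -> list[str]:
    """Node ids, optionally restricted to one biotype, sorted."""
    return sorted(
        n for n, d in g.nodes(data=True) if biotype is None or d.get("biotype") == biotype
    )


@dataclass(frozen=True)
class HubSet:
    """Top-degree nodes of a network, with the selection rule applied."""

    hubs: pd.DataFrame  # columns: id, biotype, degree; sorted by degree desc
    rule: str
    k_effective: int

    @property
    def composition(self) -> dict:
        return self.hubs["biotype"].value_counts().to_dict()


def select_hubs(
    g: nx.Graph, rule: str = "top_k", k: int = 20, fraction: float = 0.05
) -> HubSet:
    """Select hub nodes by degree.

    ``top_k`` takes the ``k`` highest-degree nodes; ``top_fraction`` takes
    ceil(fraction * n_nodes).  Ties are broken lexicographically by id so
    the selection is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network has no hubs")
    if rule == "top_k":
        if k < 1:
            raise ValueError("k must be >= 1")
        k_eff = min(k, g.number_of_nodes())
    elif rule == "top_fraction":
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        k_eff = int(np.ceil(fraction * g.number_of_nodes()))
    else:
        raise ValueError("rule must be 'top_k' or 'top_fraction'")
    ranked = sorted(g.degree(), key=lambda nd: (-nd[1], nd[0]))[:k_eff]
    df = pd.DataFrame(
        {
            "id": [n for n, _ in ranked],
            "biotype": [g.nodes[n].get("biotype", "") for n, _ in ranked],
            "degree": [d for _, d in ranked],
        }
    )
    return HubSet(hubs=df, rule=rule, k_effective=k_eff)
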