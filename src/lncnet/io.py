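"""Shared readers/writers: provenance-stamped TSV, GMT, SIF and GraphML.

All tabular interchange is plain TSV with '#'-prefixed provenance header
lines (tool version, config hash, seed), so re-runs with identical
configuration are byte-identical.  Networks additionally export in SIF and
GraphML for Cytoscape.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from . import __version__

__all__ = [
    "config_hash",
    "provenance_lines",
    "write_tsv",
    "read_tsv",
    "read_counts",
    "write_sif",
    "write_graphml",
]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_lines(meta: Mapping | None = None) -> list[str]:
    lines = [f"# lncnet {__version__}"]
    for key in sorted(meta or {}):
        lines.append(f"# {key}: {meta[key]}")
    return lines


def write_tsv(
    df: pd.DataFrame, path: str | Path, meta: Mapping | None = None, index: bool = True
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (gene ids in column 0)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty:
        raise ValueError(f"no counts in {path}")
    return df.astype("int64")


def _edge_attrs_scalar(g: nx.Graph) -> nx.Graph:
    """Copy with tuple/set edge attributes flattened to comma-joined strings
    (GraphML holds scalars only)."""
    h = g.copy()
    for u, v, data in h.edges(data=True):
        for key, value in list(data.items()):
            if isinstance(value, (tuple, list, set, frozenset)):
                data[key] = ",".join(map(str, sorted(value)))
    h.graph = {k: v for k, v in h.graph.items() if isinstance(v, (str, int, float, bool))}
    return h


def write_sif(g: nx.Graph, path: str | Path, interaction: str = "coexp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for node in sorted(n for n in g.nodes() if g.degree(n) == 0):
            fh.write(f"{node}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(_edge_attrs_scalar(g), str(path))
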