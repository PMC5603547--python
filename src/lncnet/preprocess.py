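"""Count filtering, normalization and sample-outlier screening.

The entry point of the pipeline is a genes x samples matrix of non-negative
integer counts (a :class:`pandas.DataFrame` with gene ids as the index and
sample ids as columns).  This module provides:

* counts-per-million (CPM) scaling and low-expression filtering,
* median-of-ratios size factors (the DESeq-family normalization: each
  sample's factor is the median, over genes detected in every sample, of
  that sample's count divided by the gene's across-sample geometric mean),
* classical multidimensional scaling of 1 - Pearson correlation distances
  on log2(CPM+1) profiles, with a robust centroid-distance rule for
  flagging replicate outliers.

The normalized matrix feeds the co-expression stage only; differential
expression works on raw counts with internal library-size equalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cpm",
    "filter_expressed",
    "size_factors",
    "median_of_ratios",
    "mds_outliers",
    "OutlierReport",
]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("gene and sample ids must be unique")


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: 1e6 * count / library size, per sample.

    ``lib_sizes`` defaults to the column sums of ``counts``; pass the
    pre-filtering sums when computing CPM on a subsetted matrix.
    """
    _check_counts(counts)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.reindex(counts.columns)
    if (lib_sizes <= 0).any():
        bad = list(lib_sizes.index[lib_sizes <= 0])
        raise ValueError(f"zero/negative library size for samples {bad}")
    return counts.div(lib_sizes, axis=1) * 1e6


def filter_expressed(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 4
) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    Library sizes for the CPM computation are the column sums of the input
    matrix (i.e. computed before filtering).  ``min_samples`` defaults to 4,
    the smallest per-group replicate number in the reference design.
    """
    _check_counts(counts)
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.shape[1]} available samples"
        )
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every sample;
    gene g's reference value is its geometric mean across samples, and
    s_j = median_g count_gj / geomean_g.
    """
    _check_counts(counts)
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "median-of-ratios undefined: no gene has positive counts in every sample"
        )
    ref = x[positive]
    log_geomean = np.log(ref).mean(axis=1)
    s = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize counts by median-of-ratios size factors.

    Returns ``(normalized, size_factors)`` with ``normalized = counts / s_j``
    column-wise.
    """
    s = size_factors(counts)
    return counts.div(s, axis=1), s


@dataclass(frozen=True)
class OutlierReport:
    """Result of MDS-based replicate screening."""

    coordinates: pd.DataFrame  # samples x (dim1, dim2)
    flagged: tuple[str, ...]
    exempt_groups: tuple[str, ...]  # groups of size 1, not screened
    rule_params: dict = field(default_factory=dict)

    @property
    def flagged_set(self) -> frozenset:
        return frozenset(self.flagged)


def _classical_mds(d: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center -d^2/2, take top eigenvectors."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def mds_outliers(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_flag_max: int = 2,
    k: float = 3.0,
    pseudocount: float = 1.0,
) -> OutlierReport:
    """Flag replicate outliers in a 2-D MDS embedding.

    Distances are 1 - Pearson correlation between log2(CPM + pseudocount)
    sample profiles, embedded by classical MDS.  A sample is flagged when its
    Euclidean distance to its own group's centroid exceeds
    median + k*MAD of all within-group centroid distances, at most
    ``n_flag_max`` samples (largest distances first).  Groups with a single
    sample cannot form a spread and are exempt (reported).
    """
    _check_counts(counts)
    if counts.shape[1] < 3:
        raise ValueError("MDS outlier screening needs at least 3 samples")
    groups = pd.Series(groups).reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")

    logcpm = np.log2(cpm(counts) + pseudocount)
    r = np.corrcoef(logcpm.to_numpy().T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    coords = _classical_mds(d, n_dims=2)
    coords_df = pd.DataFrame(coords, index=counts.columns, columns=["dim1", "dim2"])

    sizes = groups.value_counts()
    exempt = tuple(sorted(sizes.index[sizes < 2].astype(str)))
    screened = [s for s in counts.columns if sizes[groups[s]] >= 2]

    dist = {}
    for g, members in groups.groupby(groups).groups.items():
        members = [m for m in members if m in screened]
        if not members:
            continue
        centroid = coords_df.loc[members].mean(axis=0)
        for m in members:
            dist[m] = float(np.linalg.norm(coords_df.loc[m] - centroid))

    flagged: tuple[str, ...] = ()
    if dist and n_flag_max > 0:
        values = np.array(list(dist.values()))
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        threshold = med + k * mad
        over = [(v, s) for s, v in dist.items() if v > threshold]
        over.sort(key=lambda t: (-t[0], t[1]))
        flagged = tuple(s for _, s in over[:n_flag_max])

    return OutlierReport(
        coordinates=coords_df,
        flagged=flagged,
        exempt_groups=exempt,
        rule_params={
            "metric": "1 - pearson r of log2(CPM + pseudocount)",
            "pseudocount": pseudocount,
            "k": k,
            "n_flag_max": n_flag_max,
        },
    )
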