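"""Two-group negative-binomial exact-test differential expression.

The test conditions on the per-gene total of group-summed counts after the
libraries have been equalized to a common (geometric-mean) size.  Under the
null, the two group sums are negative binomial with means proportional to
the group sizes and dispersion phi/n_group; the two-sided p-value sums the
probabilities of every partition of the total that is no more probable than
the observed one, normalized over all partitions.  With phi = 0 and equal
group sizes this reduces to the exact two-sided (minimum-likelihood)
binomial test with success probability 1/2.

Dispersion is a single common value estimated by a trimmed method-of-moments
across genes; fold changes are reported as log2 of the ratio of group mean
pseudo-counts with a small prior count.  Multiple testing uses the
Benjamini-Hochberg step-up, and the up/down/ns call requires both q < alpha
and |log2FC| above the fold-change threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import trim_mean

__all__ = [
    "DispersionEstimate",
    "equalize_libraries",
    "estimate_common_dispersion",
    "nb_exact_test",
    "exact_test_pvalue",
    "bh_adjust",
    "call_degs",
    "summarize_calls",
]

# relative slack when comparing partition probabilities, guards against
# float noise deciding whether a tied partition is "as likely" as observed
_TIE_REL = 1e-8


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str = "trimmed method-of-moments"


def _group_masks(groups: pd.Series, columns: pd.Index) -> tuple[str, str, np.ndarray, np.ndarray]:
    groups = pd.Series(groups).reindex(columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    a, b = levels
    return a, b, (groups == a).to_numpy(), (groups == b).to_numpy()


def equalize_libraries(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to the geometric-mean library size and round.

    Produces integer pseudo-counts on approximately equal libraries, the
    working representation for the conditional exact test.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    common = np.exp(np.mean(np.log(lib)))
    return (counts * (common / lib)).round().astype(np.int64)


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: Mapping[str, str] | pd.Series, trim: float = 0.2
) -> DispersionEstimate:
    """Common NB dispersion by trimmed method of moments.

    On library-size-equalized counts, each gene contributes
    phi_g = max(0, (v - m) / m^2) where v is the pooled within-group sample
    variance and m the mean of the two group means; phi is the ``trim``-each-
    tail trimmed mean over genes with m > 0.  Requires >= 2 samples per group.
    """
    _, _, mask_a, mask_b = _group_masks(pd.Series(groups), counts.columns)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("dispersion estimation needs >= 2 samples per group")
    x = equalize_libraries(counts).to_numpy(dtype=float)
    xa, xb = x[:, mask_a], x[:, mask_b]
    na, nb = xa.shape[1], xb.shape[1]
    m = 0.5 * (xa.mean(axis=1) + xb.mean(axis=1))
    v = (xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g = np.where(m > 0, np.maximum(0.0, (v - m) / m**2), np.nan)
    phi_g = phi_g[~np.isnan(phi_g)]
    if phi_g.size == 0:
        raise ValueError("no gene with positive mean count")
    return DispersionEstimate(phi=float(trim_mean(phi_g, trim)))


def _partition_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(y_A = a, y_B = t - a) for a = 0..t under the conditional null.

    Group sums are NB with means t*n/(n_a+n_b) and dispersion phi/n (Poisson
    when phi == 0).
    """
    a = np.arange(t + 1)
    mu_a = t * n_a / (n_a + n_b)
    mu_b = t * n_b / (n_a + n_b)
    if phi == 0.0:
        return stats.poisson.logpmf(a, mu_a) + stats.poisson.logpmf(t - a, mu_b)
    r_a, r_b = n_a / phi, n_b / phi
    return stats.nbinom.logpmf(a, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
        t - a, r_b, r_b / (r_b + mu_b)
    )


def exact_test_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for one gene.

    Sums the probabilities of all partitions (a, t-a) of t = y_a + y_b whose
    null probability does not exceed the observed partition's, normalized by
    the total over partitions.  t = 0 is defined as p = 1.
    """
    t = int(y_a) + int(y_b)
    if t == 0:
        return 1.0
    logp = _partition_logpmf(t, n_a, n_b, phi)
    p = np.exp(logp - logp.max())
    obs = p[int(y_a)]
    return float(p[p <= obs * (1.0 + _TIE_REL)].sum() / p.sum())


def nb_exact_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    phi: float,
    ref_group: str | None = None,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Per-gene exact test of two groups at common dispersion ``phi``.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (treatment
    vs reference group mean pseudo-count ratio, with ``prior_count`` added
    to both means) and ``pvalue``.  ``ref_group`` defaults to the
    lexicographically first group label (CTRL before E2).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a, b, mask_a, mask_b = _group_masks(pd.Series(groups), counts.columns)
    if ref_group is not None:
        if ref_group not in (a, b):
            raise ValueError(f"ref_group {ref_group!r} not among groups {(a, b)}")
        if ref_group == b:
            a, b = b, a
            mask_a, mask_b = mask_b, mask_a
    pseudo = equalize_libraries(counts).to_numpy()
    y_a = pseudo[:, mask_a].sum(axis=1)
    y_b = pseudo[:, mask_b].sum(axis=1)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())

    log2fc = np.log2((y_b / n_b + prior_count) / (y_a / n_a + prior_count))
    log2fc = np.where((y_a + y_b) == 0, 0.0, log2fc)
    pvals = np.array(
        [exact_test_pvalue(ya, yb, n_a, n_b, phi) for ya, yb in zip(y_a, y_b)]
    )
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvals}, index=counts.index)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_degs(
    results: pd.DataFrame,
    biotypes: Mapping[str, str] | pd.Series | None = None,
    alpha: float = 0.05,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """Attach BH q-values and up/down/ns calls to exact-test results.

    A gene is ``up`` when q < alpha and log2FC > log2(fc_min), ``down`` when
    q < alpha and log2FC < -log2(fc_min), otherwise ``ns``.  If ``biotypes``
    is given, a ``biotype`` column is added (missing ids get NaN and are
    excluded from per-biotype summaries only).
    """
    if not {"log2fc", "pvalue"} <= set(results.columns):
        raise ValueError("results must have log2fc and pvalue columns")
    out = results.copy()
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    cut = np.log2(fc_min)
    sig = out["qvalue"] < alpha
    out["call"] = np.select(
        [sig & (out["log2fc"] > cut), sig & (out["log2fc"] < -cut)],
        ["up", "down"],
        default="ns",
    )
    if biotypes is not None:
        out["biotype"] = pd.Series(biotypes).reindex(out.index)
    return out


def summarize_calls(called: pd.DataFrame) -> dict:
    """Counts of up/down calls, overall and per biotype when present."""
    summary: dict = {
        "up": int((called["call"] == "up").sum()),
        "down": int((called["call"] == "down").sum()),
        "ns": int((called["call"] == "ns").sum()),
    }
    if "biotype" in called.columns:
        missing = called.index[called["biotype"].isna()]
        per = (
            called.dropna(subset=["biotype"])
            .groupby("biotype")["call"]
            .value_counts()
            .unstack(fill_value=0)
        )
        summary["by_biotype"] = {
            bt: {c: int(per.loc[bt].get(c, 0)) for c in ("up", "down", "ns")}
            for bt in per.index
        }
        summary["missing_biotype"] = sorted(map(str, missing))
    return summary
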