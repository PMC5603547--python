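"""Synthetic RNA-seq count generator with planted ground truth.

Emulates a two-treatment (vehicle control vs 17beta-estradiol), two-time-
point (24 h, 72 h) bulk muscle RNA-seq design with four replicates per
cell: negative-binomial counts around log-normal baseline means, uneven
library sizes, a minority of genes with a planted treatment effect
(|log2FC| above a floor, by default only at 24 h, mirroring a transient
response), latent-factor co-expression modules tying small sets of lncRNAs
and mRNAs together, and pathway annotations in which a few sets are
deliberately packed with differentially expressed mRNAs so that
over-representation is recoverable.

For gene g in sample j the count is drawn NB with mean

    s_j * mu_g * 2^(x_j * beta_g) * exp(lambda_m * f_{m,j})

where s_j is the sample's library-size factor, x_j the treatment indicator
(1 for treated samples at a DE-active time point), beta_g the planted
log2 fold change (0 for non-DE genes), f_{m,j} a per-sample standard
normal latent factor shared by module m's genes, and lambda_m the module
strength.  Dispersion phi = 0 degenerates to Poisson.  All randomness
derives from one seed through per-component substreams, so identical
configurations reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SimTruth", "SimulatedExperiment", "simulate_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Counts of genes/samples/modules/pathways must be >= 1 where used;
    fractions in [0, 1]; dispersion >= 0; the module gene demand cannot
    exceed the gene pools.
    """

    n_mrna: int = 2000
    n_lncrna: int = 500
    n_samples_per_group: int = 4
    groups: tuple[str, str] = ("CTRL", "E2")  # (reference, treatment)
    times: tuple[int, ...] = (24, 72)
    base_mean_log_mu: float = 3.5  # natural-log scale; median baseline ~33 counts
    base_mean_log_sigma: float = 1.0
    dispersion: float = 0.2
    frac_de: float = 0.1
    de_log2fc_min: float = 1.0
    de_log2fc_max: float = 3.0
    de_times: tuple[int, ...] = (24,)  # treatment effect active only here
    n_modules: int = 3
    module_size_lnc: int = 10
    module_size_mrna: int = 15
    module_strength: float = 3.0
    n_pathways: int = 20
    pathway_size: int = 30
    frac_pathway_de_overlap: float = 0.5
    n_enriched_pathways: int = 5
    lib_size_factor_range: tuple[float, float] = (0.7, 1.3)
    lnc_len_range: tuple[int, int] = (200, 3000)
    mrna_len_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_de", "frac_pathway_de_overlap"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.module_strength < 0:
            raise ValueError("module_strength must be >= 0")
        if self.n_modules < 0 or self.n_pathways < 0:
            raise ValueError("n_modules and n_pathways must be >= 0")
        if self.n_modules > 0 and (self.module_size_lnc < 1 or self.module_size_mrna < 1):
            raise ValueError("module sizes must be >= 1 when modules are requested")
        if self.n_modules * self.module_size_lnc > self.n_lncrna:
            raise ValueError("module lncRNA demand exceeds n_lncrna")
        if self.n_modules * self.module_size_mrna > self.n_mrna:
            raise ValueError("module mRNA demand exceeds n_mrna")
        if self.n_pathways > 0 and not (1 <= self.pathway_size <= self.n_mrna):
            raise ValueError("pathway_size must lie in [1, n_mrna]")
        if self.n_enriched_pathways > self.n_pathways:
            raise ValueError("n_enriched_pathways cannot exceed n_pathways")
        if self.de_log2fc_min < 0 or self.de_log2fc_max < self.de_log2fc_min:
            raise ValueError("need 0 <= de_log2fc_min <= de_log2fc_max")
        if not set(self.de_times) <= set(self.times):
            raise ValueError("de_times must be a subset of times")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SimTruth:
    """Planted structure: what a perfect analysis should recover."""

    de_genes: dict[str, float]  # gene id -> signed planted log2FC
    de_times: tuple[int, ...]
    module_assignments: dict[str, int]  # gene id -> module index
    pathway_assignments: dict[str, tuple[str, ...]]  # pathway id -> member genes
    enriched_pathways: tuple[str, ...]

    def de_ids(self, biotype_prefix: str | None = None) -> frozenset[str]:
        ids = self.de_genes.keys()
        if biotype_prefix is None:
            return frozenset(ids)
        return frozenset(g for g in ids if g.startswith(biotype_prefix))

    def module_members(self, module: int) -> frozenset[str]:
        return frozenset(g for g, m in self.module_assignments.items() if m == module)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "de_times": list(self.de_times),
            "module_assignments": self.module_assignments,
            "pathway_assignments": {k: list(v) for k, v in self.pathway_assignments.items()},
            "enriched_pathways": list(self.enriched_pathways),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass(frozen=True)
class SimulatedExperiment:
    counts: pd.DataFrame  # genes x samples, int
    samples: pd.DataFrame  # sample, group, time_h, replicate
    transcripts: pd.DataFrame  # index id; biotype, length
    pathways: dict[str, tuple[str, frozenset[str]]]
    truth: SimTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Draw one synthetic experiment from ``config``.

    Returns the count matrix, sample sheet, transcript table, pathway
    annotation and the planted truth.  The same config (including seed)
    always yields bit-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    (
        ss_means,
        ss_de,
        ss_modules,
        ss_factors,
        ss_libs,
        ss_counts,
        ss_pathways,
        ss_lengths,
    ) = ss.spawn(8)

    mrna_ids = [f"MRNA_{i:05d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC_{i:05d}" for i in range(config.n_lncrna)]
    gene_ids = mrna_ids + lnc_ids
    n_genes = len(gene_ids)

    # sample sheet: groups x times x replicates
    rows = []
    for group in config.groups:
        for time in config.times:
            for rep in range(1, config.n_samples_per_group + 1):
                rows.append(
                    {
                        "sample": f"{group}_{time}_{rep}",
                        "group": group,
                        "time_h": time,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample", drop=False)
    n_samples = len(samples)
    treated = (
        (samples["group"] == config.groups[1])
        & samples["time_h"].isin(config.de_times)
    ).to_numpy()

    # baseline means and library-size factors
    rng = np.random.default_rng(ss_means)
    mu = rng.lognormal(config.base_mean_log_mu, config.base_mean_log_sigma, size=n_genes)
    s = np.random.default_rng(ss_libs).uniform(*config.lib_size_factor_range, size=n_samples)

    # planted DE (independently within each biotype, so both carry signal)
    rng_de = np.random.default_rng(ss_de)
    beta = np.zeros(n_genes)
    de_genes: dict[str, float] = {}
    for ids, offset in ((mrna_ids, 0), (lnc_ids, config.n_mrna)):
        n_de = int(round(config.frac_de * len(ids)))
        chosen = rng_de.choice(len(ids), size=n_de, replace=False)
        signs = rng_de.choice([-1.0, 1.0], size=n_de)
        mags = rng_de.uniform(config.de_log2fc_min, config.de_log2fc_max, size=n_de)
        for idx, sign, mag in zip(chosen, signs, mags):
            beta[offset + idx] = sign * mag
            de_genes[ids[idx]] = float(sign * mag)

    # co-expression modules: disjoint gene sets sharing a latent factor,
    # drawn from the planted DE genes when enough exist (so the modules
    # survive DE-based selection downstream), topped up from non-DE genes
    rng_mod = np.random.default_rng(ss_modules)

    def _pick(pool_de: list[str], pool_other: list[str], size: int) -> list[str]:
        take_de = min(size, len(pool_de))
        picked = (
            [str(g) for g in rng_mod.choice(pool_de, size=take_de, replace=False)]
            if take_de
            else []
        )
        if take_de < size:
            picked += [
                str(g) for g in rng_mod.choice(pool_other, size=size - take_de, replace=False)
            ]
        return picked

    module_assignments: dict[str, int] = {}
    de_lnc_pool = [g for g in lnc_ids if g in de_genes]
    de_mrna_pool = [g for g in mrna_ids if g in de_genes]
    other_lnc = [g for g in lnc_ids if g not in de_genes]
    other_mrna = [g for g in mrna_ids if g not in de_genes]
    for m in range(config.n_modules):
        members = _pick(de_lnc_pool, other_lnc, config.module_size_lnc) + _pick(
            de_mrna_pool, other_mrna, config.module_size_mrna
        )
        for g in members:
            module_assignments[g] = m
        de_lnc_pool = [g for g in de_lnc_pool if g not in module_assignments]
        de_mrna_pool = [g for g in de_mrna_pool if g not in module_assignments]
        other_lnc = [g for g in other_lnc if g not in module_assignments]
        other_mrna = [g for g in other_mrna if g not in module_assignments]

    factors = np.random.default_rng(ss_factors).standard_normal(
        (max(config.n_modules, 1), n_samples)
    )
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    module_of = np.full(n_genes, -1, dtype=int)
    for g, m in module_assignments.items():
        module_of[gene_index[g]] = m

    # mean matrix and NB draw
    mean = mu[:, None] * s[None, :] * 2.0 ** (beta[:, None] * treated[None, :])
    in_module = module_of >= 0
    if in_module.any():
        mean[in_module] *= np.exp(
            config.module_strength * factors[module_of[in_module], :]
        )
    counts = pd.DataFrame(
        _nb_draw(np.random.default_rng(ss_counts), mean, config.dispersion),
        index=gene_ids,
        columns=samples.index,
        dtype=np.int64,
    )

    # pathway annotation over the mRNA universe; the first
    # n_enriched_pathways sets are packed with planted DE mRNAs
    rng_pw = np.random.default_rng(ss_pathways)
    de_mrna_all = [g for g in mrna_ids if g in de_genes]
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    pathway_assignments: dict[str, tuple[str, ...]] = {}
    enriched: list[str] = []
    for p in range(config.n_pathways):
        pid = f"PW_{p:03d}"
        if p < config.n_enriched_pathways and de_mrna_all:
            n_from_de = min(
                int(round(config.frac_pathway_de_overlap * config.pathway_size)),
                len(de_mrna_all),
            )
            members = set(rng_pw.choice(de_mrna_all, size=n_from_de, replace=False))
            rest = [g for g in mrna_ids if g not in members]
            members |= set(
                rng_pw.choice(rest, size=config.pathway_size - n_from_de, replace=False)
            )
            enriched.append(pid)
            desc = "planted enriched pathway"
        else:
            members = set(rng_pw.choice(mrna_ids, size=config.pathway_size, replace=False))
            desc = "background pathway"
        members_t = tuple(sorted(str(g) for g in members))
        pathways[pid] = (desc, frozenset(members_t))
        pathway_assignments[pid] = members_t

    # transcript table (lengths only; sequence content is out of scope)
    rng_len = np.random.default_rng(ss_lengths)
    lengths = np.concatenate(
        [
            rng_len.integers(*config.mrna_len_range, size=config.n_mrna, endpoint=True),
            rng_len.integers(*config.lnc_len_range, size=config.n_lncrna, endpoint=True),
        ]
    )
    transcripts = pd.DataFrame(
        {
            "biotype": ["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna,
            "length": lengths,
        },
        index=pd.Index(gene_ids, name="id"),
    )

    truth = SimTruth(
        de_genes=de_genes,
        de_times=tuple(config.de_times),
        module_assignments=module_assignments,
        pathway_assignments=pathway_assignments,
        enriched_pathways=tuple(enriched),
    )
    return SimulatedExperiment(
        counts=counts,
        samples=samples,
        transcripts=transcripts,
        pathways=pathways,
        truth=truth,
    )
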