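"""End-to-end driver: simulate/load -> filter -> screen -> DE -> network ->
enrich -> project, with every stage artifact written to an output directory
and a manifest recording seed, configuration hash and per-stage counts.

The driver is deliberately deterministic: no timestamps are written, all
randomness flows from the single configured seed, and re-running with the
same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, io
from .coexpression import build_network, network_nodes, select_hubs
from .de import call_degs, estimate_common_dispersion, nb_exact_test, summarize_calls
from .pathway import (
    build_lnc_pathway_network,
    hypergeom_enrich,
    pathway_lncrna_counts,
    read_gmt,
    write_gmt,
)
from .preprocess import filter_expressed, mds_outliers, median_of_ratios
from .simulate import SimConfig, simulate_experiment

__all__ = ["DEFAULT_CONFIG", "merge_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimConfig overrides; set to None to load inputs instead
    "inputs": {"counts": None, "samples": None, "transcripts": None, "gmt": None},
    "filter": {"min_cpm": 1.0, "min_samples": 4},
    "outliers": {"enabled": True, "k": 3.0, "n_flag_max": 2, "pseudocount": 1.0},
    "de": {"alpha": 0.05, "fc_min": 2.0, "prior_count": 0.125},
    "network": {
        "time_h": 24,
        "r_threshold": 0.99,
        "q_threshold": 0.05,
        "signed": "positive",
        "pool_times": False,
        "hub_rule": "top_k",
        "hub_k": 20,
        "hub_fraction": 0.05,
    },
    "enrich": {"alpha": 0.05},
    "project": {"require_enriched": True, "min_support": 1},
}


def merge_config(overrides: Mapping | None) -> dict:
    """DEFAULT_CONFIG with nested overrides applied."""
    config = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(base: dict, over: Mapping) -> None:
        for key, value in over.items():
            if isinstance(value, Mapping) and isinstance(base.get(key), dict):
                _merge(base[key], value)
            else:
                base[key] = value

    if overrides:
        _merge(config, overrides)
    return config


def _load_inputs(config: dict):
    paths = config["inputs"]
    for key in ("counts", "samples", "transcripts", "gmt"):
        if not paths.get(key):
            raise ValueError(f"simulation disabled but inputs.{key} is missing")
    counts = io.read_counts(paths["counts"])
    samples = io.read_tsv(paths["samples"])
    samples = samples.set_index("sample", drop=False)
    transcripts = io.read_tsv(paths["transcripts"], index_col=0)
    pathways = read_gmt(paths["gmt"])
    return counts, samples, transcripts, pathways, None


def run_pipeline(overrides: Mapping | None = None, outdir: str | Path = "lncnet_out") -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    config = merge_config(overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config)
    meta = {"config_hash": chash, "seed": config["seed"]}
    manifest: dict = {
        "tool": "lncnet",
        "version": __version__,
        "seed": config["seed"],
        "config_hash": chash,
        "stages": {},
    }

    # --- simulate or load -------------------------------------------------
    if config["simulate"] is not None:
        sim_cfg = SimConfig(**{"seed": config["seed"], **config["simulate"]})
        sim = simulate_experiment(sim_cfg)
        counts, samples, transcripts, pathways = (
            sim.counts,
            sim.samples,
            sim.transcripts,
            sim.pathways,
        )
        io.write_tsv(counts, outdir / "counts.tsv", meta)
        io.write_tsv(samples, outdir / "samples.tsv", meta, index=False)
        io.write_tsv(transcripts, outdir / "transcripts.tsv", meta)
        write_gmt(pathways, outdir / "pathways.gmt")
        sim.truth.to_json(outdir / "truth.json")
        manifest["stages"]["simulate"] = {
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "n_planted_de": len(sim.truth.de_genes),
            "n_pathways": len(pathways),
        }
    else:
        counts, samples, transcripts, pathways, _ = _load_inputs(config)
        manifest["stages"]["load"] = {
            "n_genes": int(counts.shape[0]),
            "n_samples": int(counts.shape[1]),
            "n_pathways": len(pathways),
        }

    if "biotype" not in transcripts.columns:
        raise ValueError("transcript table needs a biotype column (run `lncnet classify`)")
    biotypes = transcripts["biotype"]

    # --- low-expression filter -------------------------------------------
    fcfg = config["filter"]
    filtered = filter_expressed(
        counts, min_cpm=fcfg["min_cpm"], min_samples=fcfg["min_samples"]
    )
    io.write_tsv(filtered, outdir / "filtered_counts.tsv", meta)
    manifest["stages"]["filter"] = {
        "n_genes_in": int(counts.shape[0]),
        "n_genes_kept": int(filtered.shape[0]),
    }

    # --- replicate screening ---------------------------------------------
    ocfg = config["outliers"]
    dropped: list[str] = []
    if ocfg["enabled"] and filtered.shape[1] >= 3:
        cell = samples["group"].astype(str) + "_" + samples["time_h"].astype(str)
        report = mds_outliers(
            filtered,
            cell.reindex(filtered.columns),
            n_flag_max=ocfg["n_flag_max"],
            k=ocfg["k"],
            pseudocount=ocfg["pseudocount"],
        )
        dropped = list(report.flagged)
        (outdir / "outliers.json").write_text(
            json.dumps(
                {
                    "flagged": dropped,
                    "exempt_groups": list(report.exempt_groups),
                    "rule_params": report.rule_params,
                    "coordinates": {
                        s: [round(v, 6) for v in row]
                        for s, row in report.coordinates.iterrows()
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )
    retained = [s for s in filtered.columns if s not in dropped]
    filtered = filtered[retained]
    samples = samples.loc[retained]
    manifest["stages"]["outliers"] = {"flagged": sorted(dropped), "n_retained": len(retained)}

    # --- differential expression per time point ---------------------------
    dcfg = config["de"]
    de_tables: dict[int, pd.DataFrame] = {}
    de_summary: dict = {}
    for time in sorted(samples["time_h"].unique()):
        cols = samples.index[samples["time_h"] == time]
        sub = filtered[cols]
        groups = samples.loc[cols, "group"]
        disp = estimate_common_dispersion(sub, groups)
        res = nb_exact_test(sub, groups, disp.phi, prior_count=dcfg["prior_count"])
        called = call_degs(res, biotypes, alpha=dcfg["alpha"], fc_min=dcfg["fc_min"])
        de_tables[int(time)] = called
        de_summary[str(int(time))] = {
            "dispersion": round(disp.phi, 6),
            **summarize_calls(called),
        }
        io.write_tsv(
            called.round({"log2fc": 6, "pvalue": 10, "qvalue": 10}),
            outdir / f"de_{int(time)}h.tsv",
            meta,
        )
    (outdir / "de_summary.json").write_text(json.dumps(de_summary, indent=1, sort_keys=True))
    manifest["stages"]["de"] = {
        t: {
            "n_tested": int(len(tab)),
            "n_de": int((tab["call"] != "ns").sum()),
        }
        for t, tab in de_tables.items()
    }

    # --- normalization and co-expression network --------------------------
    ncfg = config["network"]
    normalized, sfac = median_of_ratios(filtered)
    io.write_tsv(normalized.round(4), outdir / "normalized.tsv", meta)
    time = int(ncfg["time_h"])
    if time not in de_tables:
        raise ValueError(f"network.time_h={time} has no DE contrast")
    called = de_tables[time]
    de_ids = called.index[called["call"] != "ns"]
    de_lnc = [g for g in de_ids if biotypes.get(g) == "lncRNA"]
    de_mrna = [g for g in de_ids if biotypes.get(g) == "mRNA"]
    net_samples = (
        list(filtered.columns)
        if ncfg["pool_times"]
        else list(samples.index[samples["time_h"] == time])
    )
    manifest["stages"]["network"] = {"n_de_lnc": len(de_lnc), "n_de_mrna": len(de_mrna)}
    if de_lnc and de_mrna:
        net = build_network(
            normalized,
            de_lnc,
            de_mrna,
            r_threshold=ncfg["r_threshold"],
            q_threshold=ncfg["q_threshold"],
            signed=ncfg["signed"],
            samples=net_samples,
        )
        edges = pd.DataFrame(
            [
                {
                    "lnc_id": u if net.nodes[u]["biotype"] == "lncRNA" else v,
                    "mrna_id": v if net.nodes[u]["biotype"] == "lncRNA" else u,
                    "r": round(d["r"], 6),
                    "pvalue": d["pvalue"],
                    "qvalue": d["qvalue"],
                }
                for u, v, d in net.edges(data=True)
            ]
        ).sort_values(["lnc_id", "mrna_id"]) if net.number_of_edges() else pd.DataFrame(
            columns=["lnc_id", "mrna_id", "r", "pvalue", "qvalue"]
        )
        io.write_tsv(edges, outdir / "network_edges.tsv", meta, index=False)
        io.write_sif(net, outdir / "network.sif")
        io.write_graphml(net, outdir / "network.graphml")
        manifest["stages"]["network"].update(
            {
                "n_edges": net.number_of_edges(),
                "n_lnc_nodes": len(network_nodes(net, "lncRNA")),
                "n_mrna_nodes": len(network_nodes(net, "mRNA")),
            }
        )
        if net.number_of_nodes():
            hubs = select_hubs(
                net, rule=ncfg["hub_rule"], k=ncfg["hub_k"], fraction=ncfg["hub_fraction"]
            )
            io.write_tsv(hubs.hubs, outdir / "hubs.tsv", meta, index=False)
            manifest["stages"]["network"]["n_hubs"] = hubs.k_effective
    else:
        net = None
        manifest["stages"]["network"]["n_edges"] = 0

    # --- enrichment and lncRNA-pathway projection --------------------------
    ecfg = config["enrich"]
    universe = [g for g in filtered.index if biotypes.get(g) == "mRNA"]
    if de_mrna and universe:
        enr = hypergeom_enrich(de_mrna, pathways, universe, alpha=ecfg["alpha"])
        io.write_tsv(
            enr.round({"pvalue": 10, "qvalue": 10, "rich_factor": 6}),
            outdir / "enrichment.tsv",
            meta,
            index=False,
        )
        manifest["stages"]["enrich"] = {
            "n_tested": int(len(enr)),
            "n_significant": int(enr["significant"].sum()),
        }
        pcfg = config["project"]
        if net is not None:
            proj = build_lnc_pathway_network(
                net,
                enr,
                pathways,
                require_enriched=pcfg["require_enriched"],
                min_support=pcfg["min_support"],
            )
            counts_tab = pathway_lncrna_counts(proj)
            io.write_tsv(counts_tab, outdir / "pathway_lncrna_counts.tsv", meta, index=False)
            io.write_sif(proj, outdir / "lnc_pathway.sif", interaction="regulates")
            io.write_graphml(proj, outdir / "lnc_pathway.graphml")
            manifest["stages"]["project"] = {
                "n_lncrnas": sum(
                    1 for _, d in proj.nodes(data=True) if d.get("kind") == "lncRNA"
                ),
                "n_pathways": sum(
                    1 for _, d in proj.nodes(data=True) if d.get("kind") == "pathway"
                ),
                "n_edges": proj.number_of_edges(),
            }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
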