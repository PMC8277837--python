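"""End-to-end orchestration: counts -> DE -> RIF -> networks -> DK -> diff-corr -> ORA.

Stages run in analysis order; every intermediate is written as plain text
and a JSON manifest records, per stage, the input hashes, outputs, row
counts and wall time. Re-running with the same inputs and seed reproduces
every output byte-for-byte (timings aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__, diffcorr, enrich, io, pcit, preprocess, rewiring, rif, simdata
from .containers import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str | None = None
    samples: str | None = None
    tfs: str | None = None
    gmt: str | None = None
    markers: str | None = None
    de_table: str | None = None
    outdir: str = "asmnet_out"
    seed: int = 0
    # thresholds (documented defaults)
    alpha_de: float = 0.1
    rif_z: float = 2.0
    r_min: float = 0.95
    alpha_r: float = 0.05
    dk_z: float = 1.96
    alpha_adj: float = 0.05
    class_alpha: float = 0.05
    kappa: float = 0.4
    cpm: float = 0.5
    frac: float = 0.5
    prior_count: float = 0.5
    anchor_all_tfs: bool = False  # anchor every listed TF, not only RIF-significant ones
    use_covariates: bool = True
    simulate: dict | None = None  # SimConfig overrides; used when counts is None

    def validate(self) -> None:
        checks = {
            "alpha_de": 0 <= self.alpha_de <= 1,
            "alpha_r": 0 < self.alpha_r <= 1,
            "alpha_adj": 0 < self.alpha_adj <= 1,
            "class_alpha": 0 < self.class_alpha <= 1,
            "r_min": 0 < self.r_min <= 1,
            "rif_z": self.rif_z >= 0,
            "dk_z": self.dk_z >= 0,
            "cpm": self.cpm > 0,
            "frac": 0 < self.frac <= 1,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ConfigurationError(f"threshold(s) out of domain: {bad}")
        for name in ("counts", "samples", "tfs", "gmt", "markers", "de_table"):
            path = getattr(self, name)
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.data = {
            "software": {"name": "asmnet", "version": __version__},
            "config": asdict(config),
            "stages": {},
            "timings_sec": {},
        }

    def record(self, stage: str, inputs: list[str], outputs: list[str], counts: dict, wall: float):
        self.data["stages"][stage] = {
            "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
            "counts": counts,
        }
        self.data["timings_sec"][stage] = round(wall, 3)

    def write(self, path: str):
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = io.ensure_dir(config.outdir)
    manifest = _Manifest(config)

    def path(name: str) -> str:
        return os.path.join(out, name)

    # --- stage 0: inputs (simulate when no counts are supplied) -------------
    t0 = time.perf_counter()
    if config.counts is None:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", config.seed)
        sim_cfg = simdata.SimConfig(**sim_kwargs)
        cm, truth = simdata.simulate_counts(sim_cfg)
        sim_paths = simdata.write_outputs(cm, truth, sim_cfg, out)
        counts_path, samples_path = sim_paths["counts"], sim_paths["samples"]
        tf_path = sim_paths["tfs"]
        manifest.record(
            "simulate", [], list(sim_paths.values()),
            {"genes": cm.counts.shape[0], "samples": cm.counts.shape[1]},
            time.perf_counter() - t0,
        )
    else:
        if config.samples is None:
            raise ConfigurationError("samples sheet required with --counts")
        counts_path, samples_path, tf_path = config.counts, config.samples, config.tfs
        cm = io.read_counts(counts_path, samples_path)
    if tf_path is None:
        raise ConfigurationError("a TF list is required (tfs path)")
    tf_ids = io.read_gene_list(tf_path)

    # --- preprocess ---------------------------------------------------------
    t0 = time.perf_counter()
    filtered = preprocess.filter_low_expression(cm, config.cpm, config.frac)
    expr = preprocess.normalize(filtered, prior_count=config.prior_count)
    io.write_matrix(filtered.counts, path("filtered_counts.tsv"))
    io.write_matrix(expr.values, path("expression.tsv"))
    if config.de_table is not None:
        de = pd.read_csv(config.de_table, sep="\t", index_col=0)
        need = {"log2FC", "pvalue", "padj"}
        if not need.issubset(de.columns):
            raise ConfigurationError(f"external DE table needs columns {sorted(need)}")
        if "status" not in de.columns:
            de["status"] = np.where(
                (de["padj"] <= config.alpha_de) & (de["log2FC"] > 0), "up",
                np.where((de["padj"] <= config.alpha_de) & (de["log2FC"] < 0), "down", "ns"),
            )
    else:
        de = preprocess.differential_expression(expr, alpha_de=config.alpha_de, use_covariates=config.use_covariates)
    de = de.loc[de.index.intersection(expr.values.index)]
    de.to_csv(path("de_table.tsv"), sep="\t", index_label="gene_id")
    degs = preprocess.deg_ids(de, config.alpha_de)
    manifest.record(
        "preprocess", [counts_path, samples_path],
        [path("filtered_counts.tsv"), path("expression.tsv"), path("de_table.tsv")],
        {"genes_in": cm.counts.shape[0], "genes_kept": filtered.counts.shape[0], "degs": len(degs)},
        time.perf_counter() - t0,
    )

    if not degs and not config.anchor_all_tfs:
        raise ConfigurationError(
            f"empty anchors: no DEGs at padj <= {config.alpha_de} (and anchor_all_tfs is off)"
        )

    # --- RIF ----------------------------------------------------------------
    t0 = time.perf_counter()
    rif_table = rif.rif_scores(expr, tf_ids, degs, z_thresh=config.rif_z)
    rif_table.to_csv(path("rif_table.tsv"), sep="\t", index_label="tf_id")
    sig_tfs = rif.significant_tfs(rif_table)
    manifest.record(
        "rif", [path("expression.tsv"), tf_path], [path("rif_table.tsv")],
        {"tfs_scored": len(rif_table), "tfs_significant": len(sig_tfs)},
        time.perf_counter() - t0,
    )

    # --- anchors ------------------------------------------------------------
    anchor_tfs = [t for t in tf_ids if t in set(expr.values.index)] if config.anchor_all_tfs else sig_tfs
    anchors = sorted(set(degs) | set(anchor_tfs))
    if not anchors:
        raise ConfigurationError("empty anchors: no DEGs and no significant TFs")
    io.write_gene_list(anchors, path("anchors.txt"))

    # --- per-condition PCIT networks ---------------------------------------
    edge_tables = {}
    summary = {"thresholds": {"r_min": config.r_min, "alpha_r": config.alpha_r}}
    for cond in ("case", "control"):
        t0 = time.perf_counter()
        corr, valid = pcit.correlation_matrix(expr, cond)
        mask = pcit.pcit_significance(corr.to_numpy(), valid)
        n_cond = len(expr.condition_samples(cond))
        edges = pcit.build_network(
            corr, mask, anchors, n_cond, r_min=config.r_min, alpha_r=config.alpha_r, condition=cond
        )
        edge_tables[cond] = edges
        io.write_table(edges, path(f"edges_{cond}.tsv"))
        io.write_sif(edges, path(f"network_{cond}.sif"))
        hubs = pcit.hub_genes(edges) if len(edges) else pd.DataFrame(columns=["degree", "is_hub"])
        hubs.to_csv(path(f"hubs_{cond}.tsv"), sep="\t", index_label="gene_id")
        r2 = pcit.scale_free_fit(edges) if len(edges) else float("nan")
        summary[cond] = {
            "nodes": int(pd.concat([edges["gene_a"], edges["gene_b"]]).nunique()) if len(edges) else 0,
            "edges": int(len(edges)),
            "hubs": int(hubs["is_hub"].sum()) if len(hubs) else 0,
            "scale_free_r2": None if np.isnan(r2) else round(float(r2), 4),
        }
        manifest.record(
            f"network_{cond}", [path("expression.tsv"), path("anchors.txt")],
            [path(f"edges_{cond}.tsv"), path(f"network_{cond}.sif"), path(f"hubs_{cond}.tsv")],
            summary[cond] | {"scale_free_r2": summary[cond]["scale_free_r2"] or "nan"},
            time.perf_counter() - t0,
        )
        if len(edges) == 0:
            raise ConfigurationError(f"empty {cond} network: nothing to rewire")
    with open(path("network_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # --- union network + differential connectivity --------------------------
    t0 = time.perf_counter()
    union = rewiring.union_network(edge_tables["case"], edge_tables["control"])
    io.write_table(union.nodes, path("union_nodes.tsv"))
    io.write_table(union.edges, path("union_edges.tsv"))
    io.write_sif(union.edges, path("union_network.sif"))
    conn = rewiring.differential_connectivity(union, z_thresh=config.dk_z)
    io.write_table(conn, path("connectivity.tsv"))
    manifest.record(
        "rewiring", [path("edges_case.tsv"), path("edges_control.tsv")],
        [path("union_nodes.tsv"), path("union_edges.tsv"), path("connectivity.tsv")],
        {
            "union_nodes": len(union.nodes),
            "union_edges": len(union.edges),
            "gain": int((conn["call"] == "gain").sum()),
            "loss": int((conn["call"] == "loss").sum()),
        },
        time.perf_counter() - t0,
    )

    # --- differential correlation (anchored universe) -----------------------
    t0 = time.perf_counter()
    records = diffcorr.differential_coexpression_scan(
        expr, anchor_genes=anchors, alpha_adj=config.alpha_adj, class_alpha=config.class_alpha
    )
    keep_cols = [
        "gene_a", "gene_b", "r_case", "r_control", "z_diff", "pval_diff", "pval_diff_adj", "class",
    ]
    io.write_table(records[keep_cols], path("diffcorr.tsv"))
    with open(path("diffcorr_summary.json"), "w") as fh:
        json.dump(
            {
                "pairs_tested": int(len(records)),
                "significant": int(records["significant"].sum()),
                "class_counts": diffcorr.class_counts(records, significant_only=True),
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    manifest.record(
        "diffcorr", [path("expression.tsv"), path("anchors.txt")],
        [path("diffcorr.tsv"), path("diffcorr_summary.json")],
        {"pairs": int(len(records)), "significant": int(records["significant"].sum())},
        time.perf_counter() - t0,
    )

    # --- enrichment / marker intersection (optional inputs) ------------------
    if config.gmt is not None:
        t0 = time.perf_counter()
        sets = io.read_gmt(config.gmt)
        universe = list(expr.values.index)
        dc_genes = list(conn.loc[conn["call"] != "ns", "gene_id"])
        query = sorted(set(anchors) | set(dc_genes))
        ora = enrich.hypergeometric_ora(query, sets, universe)
        ora = enrich.kappa_grouping(ora, sets, query, kappa_min=config.kappa)
        io.write_table(ora, path("enrichment.tsv"))
        manifest.record(
            "enrich", [config.gmt], [path("enrichment.tsv")],
            {"terms": len(ora), "significant": int((ora["pvalue"] <= 0.05).sum())},
            time.perf_counter() - t0,
        )
    if config.markers is not None:
        t0 = time.perf_counter()
        markers = io.read_gene_list(config.markers)
        hits = enrich.marker_intersection(anchors, markers)
        io.write_table(hits, path("marker_intersection.tsv"))
        manifest.record(
            "markers", [config.markers], [path("marker_intersection.tsv")],
            {"common": len(hits)}, time.perf_counter() - t0,
        )

    manifest.write(path("manifest.json"))
    return manifest.data
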