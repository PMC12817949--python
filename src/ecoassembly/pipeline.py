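"""Config-driven orchestration of the full analysis graph.

Stages: load -> rarefy -> beta-diversity tests -> (low-occurrence filter ->
assembly null models) -> DOC -> niche metrics -> (top-k -> co-occurrence
network). Every run writes per-stage TSV/JSON outputs plus one consolidated
JSON report and a manifest echoing the effective configuration, so a run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assembly, betadiversity, doc, network, niche
from .core_io import (
    CommunityTable,
    SampleMetadata,
    filter_low_occurrence,
    rarefy,
    read_community_table,
    read_metadata,
    read_tree,
    relative_abundance,
    write_community_table,
)

logger = logging.getLogger("ecoassembly")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Effective settings of one pipeline run.

    Defaults equal the analysis' canonical settings: betaNTI threshold 2,
    RCbray threshold 0.95, 999 null randomizations, DOC with 1,000
    bootstraps, Levins-breadth class boundaries 1.5/5, network over the top
    400 taxa at |r| > 0.75 and p < 0.001, rarefaction to the minimum sample
    depth.
    """

    table_path: str
    metadata_path: str
    tree_path: str | None = None
    output_dir: str = "ecoassembly_out"
    rarefaction_depth: int | str = "min"  # "min" or an explicit depth
    seed: int = 0
    # stage toggles
    run_betadiversity: bool = True
    run_assembly: bool = True
    run_doc: bool = True
    run_niche: bool = True
    run_network: bool = True
    # thresholds
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    n_randomizations: int = 999
    n_permutations: int = 999
    n_boot: int = 1000
    doc_span: float = 0.7
    specialist_max: float = 1.5
    generalist_min: float = 5.0
    network_top_k: int = 400
    network_r_min: float = 0.75
    network_p_max: float = 0.001

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(
    config: RunConfig,
    table: CommunityTable | None = None,
    meta: SampleMetadata | None = None,
    tree=None,
) -> dict:
    """Run the configured stages and return the consolidated report.

    Inputs may be passed in memory (``table``, ``meta``, ``tree``) or read
    from the paths in the config. Fails before any computation when the
    assembly stage is enabled without a tree.
    """
    if config.run_assembly and tree is None and config.tree_path is None:
        raise ValueError("assembly stage enabled but no tree supplied")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table is None:
        table = read_community_table(config.table_path)
    if meta is None:
        meta = read_metadata(config.metadata_path)
    if tree is None and config.tree_path is not None:
        tree = read_tree(config.tree_path)

    report: dict = {"config": config.to_dict(), "stages": {}}

    # --- rarefaction
    depth = config.rarefaction_depth
    if depth == "min":
        depth = int(table.values.sum(axis=0).min())
    table = rarefy(table, int(depth), seed=config.seed)
    report["rarefaction"] = {
        "depth": int(depth),
        "n_samples_kept": table.n_samples,
        "n_taxa": table.n_taxa,
    }
    write_community_table(table, outdir / "rarefied_table.tsv")

    # --- beta diversity
    if config.run_betadiversity:
        bc = betadiversity.bray_curtis_matrix(table)
        bc.write_tsv(outdir / "bray_curtis.tsv")
        anosim_res = betadiversity.anosim(
            bc, meta, n_perm=config.n_permutations, seed=config.seed
        )
        permanova_res = betadiversity.permanova(
            bc, meta, n_perm=config.n_permutations, seed=config.seed
        )
        report["stages"]["betadiversity"] = {
            "anosim": anosim_res.to_dict(),
            "permanova": permanova_res.to_dict(),
        }

    # --- assembly null models
    if config.run_assembly:
        filtered = filter_low_occurrence(table)
        nm_config = assembly.NullModelConfig(
            n_randomizations=config.n_randomizations,
            bnti_threshold=config.bnti_threshold,
            rc_threshold=config.rc_threshold,
            seed=config.seed,
        )
        dist = assembly.patristic_matrix(tree, filtered.taxon_ids)
        bnti_dm = assembly.bnti(filtered, tree, nm_config, _dist=dist)
        rc_dm = assembly.raup_crick_bray(filtered, nm_config)
        bnti_dm.write_tsv(outdir / "bnti.tsv")
        rc_dm.write_tsv(outdir / "rcbray.tsv")
        partition = assembly.partition_processes(
            bnti_dm,
            rc_dm,
            bnti_threshold=config.bnti_threshold,
            rc_threshold=config.rc_threshold,
        )
        partition.pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
        group_summary = assembly.group_bnti_summary(bnti_dm, meta)
        report["stages"]["assembly"] = {
            **partition.to_dict(),
            "n_taxa_after_filter": filtered.n_taxa,
            "group_bnti": {
                g: {k: v for k, v in s.items() if k != "values"}
                for g, s in group_summary.items()
            },
        }

    # --- dissimilarity-overlap curve
    if config.run_doc:
        doc_res = doc.doc_analysis(
            relative_abundance(table),
            n_boot=config.n_boot,
            span=config.doc_span,
            seed=config.seed,
        )
        doc_res.points.to_csv(outdir / "doc_points.tsv", sep="\t", index=False)
        report["stages"]["doc"] = doc_res.to_dict()

    # --- niche metrics
    if config.run_niche:
        profile = niche.community_niche_summary(
            table,
            meta,
            specialist_max=config.specialist_max,
            generalist_min=config.generalist_min,
        )
        profile.per_taxon.to_csv(outdir / "niche_per_taxon.tsv", sep="\t")
        profile.bcom.to_csv(outdir / "bcom_per_sample.tsv", sep="\t")
        report["stages"]["niche"] = {
            "class_proportions": profile.class_proportions(),
            "bcom_mean": float(profile.bcom.mean()),
            "ocom": profile.ocom,
        }

    # --- co-occurrence network
    if config.run_network:
        global_net = network.build_global_network(
            table,
            k=config.network_top_k,
            r_min=config.network_r_min,
            p_max=config.network_p_max,
        )
        global_net.edge_frame().to_csv(
            outdir / "network_edges_global.tsv", sep="\t", index=False
        )
        net_report = {"global": network.topology_metrics(global_net).to_dict()}
        for g in meta.group_labels:
            sub = network.extract_subnetwork(global_net, table, meta, g)
            sub.edge_frame().to_csv(
                outdir / f"network_edges_{g}.tsv", sep="\t", index=False
            )
            net_report[g] = network.topology_metrics(sub).to_dict()
        report["stages"]["network"] = net_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    return report
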