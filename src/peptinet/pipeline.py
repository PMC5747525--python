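"""One-command orchestration: simulate/preprocess -> network -> taxonomy
[-> cross-species], with a machine-readable run report.

The configuration is a YAML (or plain dict) with one section per stage;
every stage writes its outputs under ``out_dir`` and the report records
each stage's parameters and output files plus the seed and package
version. Any stage failure raises :class:`PipelineError` naming the
stage (the CLI maps this to a non-zero exit code).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from . import __version__
from .io import (
    read_expression_table,
    read_gene_roles,
    read_node_layout,
    read_orthology_table,
    read_pair_table,
    write_expression_table,
    write_gene_roles,
    write_gexf,
    write_node_layout,
    write_pair_table,
)
from .network import build_all_channel_graphs, combine_channels, network_stats
from .preprocess import build_node_layout, merge_duplicate_cells, normalize_rpkm_to_logcpm
from .simulate import SimConfig, generate_dataset
from .taxonomy import classify_cells, count_peptides_per_cell, find_autocrine_channels
from .xspecies import compare_species, write_masked_matrix

logger = logging.getLogger("peptinet")

__all__ = ["PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def _sim_config(section: dict, seed: int) -> SimConfig:
    known = {f.name for f in fields(SimConfig)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    return SimConfig(seed=int(section.get("seed", seed)), **{
        k: v for k, v in section.items() if k != "seed"
    })


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages in order and return the report dict
    (also written to ``out_dir/report.json``)."""
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "peptinet_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": seed, "stages": {}}

    matrix = roles = pairs = layout = coords = None

    # ---- simulate ------------------------------------------------------
    if "simulate" in config:
        stage = "simulate"
        try:
            sim_cfg = _sim_config(config["simulate"] or {}, seed)
            matrix, roles, pairs, coords, truth = generate_dataset(sim_cfg)
            write_expression_table(matrix, out_dir / "expr.csv")
            write_gene_roles(roles, out_dir / "roles.csv")
            write_pair_table(pairs, out_dir / "pairs.csv")
            coords.to_csv(out_dir / "coords.csv", index=False)
            with open(out_dir / "truth.json", "w") as fh:
                json.dump(
                    {
                        "duplicate_groups": truth.duplicate_groups,
                        "planted_edges": {
                            cid: sorted(map(list, e)) for cid, e in truth.planted_edges.items()
                        },
                        "category": truth.category,
                        "n_peptides_per_cell": truth.n_peptides_per_cell,
                    },
                    fh,
                    indent=2,
                )
            report["stages"][stage] = {
                "params": asdict(sim_cfg),
                "outputs": [str(out_dir / f) for f in
                            ("expr.csv", "roles.csv", "pairs.csv", "coords.csv", "truth.json")],
            }
        except Exception as exc:  # noqa: BLE001 - report failing stage
            raise PipelineError(stage, str(exc)) from exc

    # ---- preprocess ----------------------------------------------------
    if "preprocess" in config or matrix is not None:
        stage = "preprocess"
        try:
            section = config.get("preprocess", {}) or {}
            if matrix is None:
                expr_path = section["expr"]
                matrix = read_expression_table(
                    expr_path,
                    orientation=section.get("orientation", "cells_in_rows"),
                    scale=section.get("scale", "raw_rpkm"),
                )
            threshold = float(section.get("merge_threshold", 0.95))
            if matrix.scale.value == "raw_rpkm":
                matrix = normalize_rpkm_to_logcpm(matrix)
            merged, groups = merge_duplicate_cells(matrix, threshold=threshold)
            write_expression_table(merged, out_dir / "merged.csv")
            with open(out_dir / "groups.json", "w") as fh:
                json.dump(groups, fh, indent=2)
            if coords is not None:
                # re-key coordinates of merged samples via their first member
                sample_xy = coords.set_index("cell_id")
                rows = {
                    cell: sample_xy.loc[groups[cell][0], ["x", "y"]].astype(float)
                    for cell in merged.cell_ids
                }
                import pandas as pd  # local: avoids top-level dependency churn

                coords = pd.DataFrame(rows).T.rename_axis("cell_id").reset_index()
            matrix = merged
            report["stages"][stage] = {
                "params": {"merge_threshold": threshold},
                "n_cells_merged": len(merged.cell_ids),
                "outputs": [str(out_dir / "merged.csv"), str(out_dir / "groups.json")],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---- network -------------------------------------------------------
    if "network" in config or (matrix is not None and pairs is not None):
        stage = "network"
        try:
            section = config.get("network", {}) or {}
            if pairs is None:
                pairs = read_pair_table(section["pairs"])
            level = section.get("level", "node")
            min_expr = float(section.get("min_expr", 0.0))
            if "layout" in section:
                layout = read_node_layout(section["layout"])
            elif coords is not None:
                layout = build_node_layout(matrix, coords)
            if level == "node" and layout is None:
                raise ValueError("node-level networks need a layout (or simulated coords)")
            graphs = build_all_channel_graphs(
                matrix, pairs, level=level, layout=layout, expression_threshold=min_expr
            )
            combined = combine_channels(graphs)
            gdir = out_dir / "graphs"
            gdir.mkdir(exist_ok=True)
            stats = {}
            for cg in graphs:
                write_gexf(cg, gdir / f"{cg.channel_id}.gexf",
                           layout=layout if level == "node" else None)
                stats[cg.channel_id] = network_stats(cg, seed=seed).to_dict()
            write_gexf(combined, gdir / "combined.gexf",
                       layout=layout if level == "node" else None)
            stats["combined"] = network_stats(combined, seed=seed).to_dict()
            if layout is not None:
                write_node_layout(layout, out_dir / "layout.csv")
            with open(out_dir / "stats.json", "w") as fh:
                json.dump(stats, fh, indent=2)
            report["stages"][stage] = {
                "params": {"level": level, "min_expr": min_expr},
                "outputs": [str(out_dir / "stats.json"), str(gdir)],
            }
            report["combined_stats"] = {
                k: stats["combined"][k]
                for k in ("n_nodes", "n_edges", "graph_density",
                          "avg_clustering_directed", "avg_clustering_undirected",
                          "avg_path_length", "n_components", "modularity")
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---- taxonomy ------------------------------------------------------
    if "taxonomy" in config or (matrix is not None and roles is not None):
        stage = "taxonomy"
        try:
            section = config.get("taxonomy", {}) or {}
            if roles is None:
                roles = read_gene_roles(section["roles"])
            min_expr = float(section.get("min_expr", 0.0))
            cat, counts = classify_cells(matrix, roles, min_expr=min_expr)
            pep = count_peptides_per_cell(matrix, roles, min_expr=min_expr)
            cell_graphs = build_all_channel_graphs(matrix, pairs, level="cell",
                                                   expression_threshold=min_expr) if pairs else []
            autocrine = find_autocrine_channels(cell_graphs)
            payload = {
                "category_counts": counts.to_dict(),
                "category_per_cell": cat.to_dict(),
                "n_peptides_per_cell": pep.to_dict(),
                "max_peptides": int(pep.max()),
                "autocrine": [list(t) for t in autocrine],
            }
            with open(out_dir / "taxonomy.json", "w") as fh:
                json.dump(payload, fh, indent=2)
            report["stages"][stage] = {
                "params": {"min_expr": min_expr},
                "outputs": [str(out_dir / "taxonomy.json")],
            }
            report["taxonomy_counts"] = counts["count"].to_dict()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # ---- cross-species -------------------------------------------------
    if "xspecies" in config:
        stage = "xspecies"
        try:
            section = config["xspecies"] or {}
            mat_a = read_expression_table(section["expr_a"], scale=section.get("scale", "log_cpm"))
            mat_b = read_expression_table(section["expr_b"], scale=section.get("scale", "log_cpm"))
            orth = read_orthology_table(section["orthology"])
            result = compare_species(
                mat_a,
                mat_b,
                orth,
                n_perm=int(section.get("n_perm", 1000)),
                seed=int(section.get("seed", seed)),
            )
            result.to_json(out_dir / "xspecies.json")
            write_masked_matrix(result.corr_a, result.pairs, "a", out_dir / "masked_a.csv")
            write_masked_matrix(result.corr_b, result.pairs, "b", out_dir / "masked_b.csv")
            report["stages"][stage] = {
                "params": {"n_perm": result.n_permutations, "seed": result.seed},
                "global_r": result.global_r,
                "global_p_empirical": result.global_p_empirical,
                "outputs": [str(out_dir / f) for f in
                            ("xspecies.json", "masked_a.csv", "masked_b.csv")],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline finished: %s", out_dir / "report.json")
    return report
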