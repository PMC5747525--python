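"""Domain types and file I/O for the peptidergic-connectome pipeline.

The pipeline moves between a small set of plain-text formats: delimited
expression tables (cells x genes, or transposed), ligand-receptor pair
tables, gene-role tables, orthology tables, node-layout tables, and GEXF
1.2draft graph files (Gephi-compatible). Every external format touched by
the pipeline is read and written here; the analysis modules only see the
typed containers defined below.
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("peptinet")

__all__ = [
    "Scale",
    "Side",
    "ExpressionMatrix",
    "GeneRoleTable",
    "Channel",
    "PairTable",
    "NodeLayout",
    "ChannelGraph",
    "NetworkStats",
    "OrthologyMap",
    "CrossSpeciesResult",
    "read_expression_table",
    "write_expression_table",
    "read_pair_table",
    "write_pair_table",
    "read_gene_roles",
    "write_gene_roles",
    "read_orthology_table",
    "write_orthology_table",
    "read_node_layout",
    "write_node_layout",
    "write_gexf",
    "read_gexf",
]

#: valid per-cell spatial-symmetry codes: N = no prediction, Y1 = asymmetric
#: single cell, Y2 = bilaterally symmetric pair (rendered as two mirror nodes).
SYMMETRY_CODES = ("N", "Y1", "Y2")

#: recognised gene roles; a gene may carry several.
GENE_ROLES = (
    "proneuropeptide",
    "gpcr_receptor",
    "transmitter_marker",
    "sensory_receptor",
    "endocrine_marker",
    "other",
)


class Scale(str, enum.Enum):
    """Measurement scale of an expression matrix."""

    raw_rpkm = "raw_rpkm"
    log_cpm = "log_cpm"


class Side(str, enum.Enum):
    """Which body side a layout node represents."""

    left = "left"
    right = "right"
    single = "single"


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values plus per-cell metadata.

    Parameters
    ----------
    values
        DataFrame indexed by cell id with one column per gene. Values are
        RPKM (``scale=raw_rpkm``) or log10(1 + cpm) (``scale=log_cpm``).
    scale
        Measurement scale flag.
    cell_meta
        DataFrame indexed by cell id. Always carries a ``symmetry`` column
        (N/Y1/Y2); may carry ``total_mapped_reads`` and ``provenance`` (list
        of merged source sample ids).
    """

    values: pd.DataFrame
    scale: Scale = Scale.log_cpm
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.scale = Scale(self.scale)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.values.index.copy())
        if "symmetry" not in self.cell_meta.columns:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta["symmetry"] = "N"
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        dup_cells = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_cells):
            raise ValueError(f"duplicate cell identifiers: {sorted(map(str, dup_cells))}")
        dup_genes = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_genes):
            raise ValueError(f"duplicate gene identifiers: {sorted(map(str, dup_genes))}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale is Scale.log_cpm and (arr < 0).any():
            raise ValueError("log_cpm values must be >= 0")
        if not self.cell_meta.index.equals(self.values.index):
            missing = self.values.index.difference(self.cell_meta.index)
            if len(missing):
                raise ValueError(f"cell_meta missing cells: {list(map(str, missing))}")
            self.cell_meta = self.cell_meta.loc[self.values.index]
        bad = set(self.cell_meta["symmetry"]) - set(SYMMETRY_CODES)
        if bad:
            raise ValueError(f"unknown symmetry codes: {sorted(bad)}")

    # -- convenience ----------------------------------------------------
    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def expr(self, cell: str, gene: str) -> float:
        return float(self.values.at[cell, gene])

    def __eq__(self, other: object) -> bool:  # value equality, for round-trips
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.values.equals(other.values)
            and list(self.cell_meta["symmetry"]) == list(other.cell_meta["symmetry"])
        )


# ---------------------------------------------------------------------------
# GeneRoleTable / PairTable / OrthologyMap
# ---------------------------------------------------------------------------


@dataclass
class GeneRoleTable:
    """Mapping gene id -> set of functional roles (roles may overlap)."""

    roles: dict[str, set[str]]

    def __post_init__(self) -> None:
        for gene, rset in self.roles.items():
            bad = set(rset) - set(GENE_ROLES)
            if bad:
                raise ValueError(f"unknown roles for {gene!r}: {sorted(bad)}")
            self.roles[gene] = set(rset)

    def genes_with_role(self, role: str) -> list[str]:
        if role not in GENE_ROLES:
            raise ValueError(f"unknown role {role!r}")
        return sorted(g for g, r in self.roles.items() if role in r)

    def __contains__(self, gene: str) -> bool:
        return gene in self.roles

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneRoleTable):
            return NotImplemented
        return self.roles == other.roles


@dataclass(frozen=True)
class Channel:
    """One directed peptide -> receptor signaling channel."""

    channel_id: str
    ligand_gene: str
    receptor_gene: str


@dataclass
class PairTable:
    """Deorphanized ligand-receptor pairs; many-to-many allowed (one
    receptor may be activated by several ligands, e.g. the corazonin
    receptor by both CRZ1 and CRZ2)."""

    channels: list[Channel]

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate channel_ids: {dups}")

    def __iter__(self):
        return iter(self.channels)

    def __len__(self) -> int:
        return len(self.channels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairTable):
            return NotImplemented
        return self.channels == other.channels


@dataclass
class OrthologyMap:
    """Species-A gene -> candidate (and optionally resolved) species-B genes."""

    rows: pd.DataFrame  # columns: gene_a, candidates_b (list), resolved_b (str|None)

    def __post_init__(self) -> None:
        required = {"gene_a", "candidates_b"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"orthology table needs columns {sorted(required)}")
        if "resolved_b" not in self.rows.columns:
            self.rows = self.rows.copy()
            self.rows["resolved_b"] = None
        if self.rows["gene_a"].duplicated().any():
            dups = sorted(self.rows.loc[self.rows["gene_a"].duplicated(), "gene_a"])
            raise ValueError(f"duplicate species-A genes: {dups}")
        for _, row in self.rows.iterrows():
            cands = list(row["candidates_b"])
            if not cands:
                raise ValueError(f"gene {row['gene_a']!r} has no candidates")
            if row["resolved_b"] is not None and row["resolved_b"] not in cands:
                raise ValueError(
                    f"resolved gene {row['resolved_b']!r} not a candidate of {row['gene_a']!r}"
                )
        self.rows = self.rows.reset_index(drop=True)

    @property
    def genes_a(self) -> list[str]:
        return list(self.rows["gene_a"])

    def candidates(self, gene_a: str) -> list[str]:
        sel = self.rows.loc[self.rows["gene_a"] == gene_a, "candidates_b"]
        if sel.empty:
            raise KeyError(gene_a)
        return list(sel.iloc[0])

    def resolved(self, gene_a: str) -> str | None:
        sel = self.rows.loc[self.rows["gene_a"] == gene_a, "resolved_b"]
        if sel.empty:
            raise KeyError(gene_a)
        return sel.iloc[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyMap):
            return NotImplemented
        a = self.rows[["gene_a", "candidates_b", "resolved_b"]]
        b = other.rows[["gene_a", "candidates_b", "resolved_b"]]
        return a.to_dict("records") == b.to_dict("records")


# ---------------------------------------------------------------------------
# NodeLayout
# ---------------------------------------------------------------------------


@dataclass
class NodeLayout:
    """Planar node positions for the virtual brain map.

    Bilaterally symmetric (Y2) cells appear as two mirror-image nodes at
    (-x, y) and (x, y); N/Y1 cells as a single node.
    """

    table: pd.DataFrame  # columns: node_id, cell_id, side, x, y

    def __post_init__(self) -> None:
        required = ["node_id", "cell_id", "side", "x", "y"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"layout table missing columns: {missing}")
        if self.table["node_id"].duplicated().any():
            dups = sorted(self.table.loc[self.table["node_id"].duplicated(), "node_id"])
            raise ValueError(f"duplicate node_ids: {dups}")
        bad = set(self.table["side"]) - {s.value for s in Side}
        if bad:
            raise ValueError(f"unknown side values: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def node_ids(self) -> list[str]:
        return list(self.table["node_id"])

    def nodes_of_cell(self, cell_id: str) -> list[str]:
        return list(self.table.loc[self.table["cell_id"] == cell_id, "node_id"])

    def position(self, node_id: str) -> tuple[float, float]:
        row = self.table.loc[self.table["node_id"] == node_id]
        if row.empty:
            raise KeyError(node_id)
        return float(row["x"].iloc[0]), float(row["y"].iloc[0])

    def cell_of(self, node_id: str) -> str:
        row = self.table.loc[self.table["node_id"] == node_id]
        if row.empty:
            raise KeyError(node_id)
        return str(row["cell_id"].iloc[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodeLayout):
            return NotImplemented
        cols = ["node_id", "cell_id", "side", "x", "y"]
        return self.table[cols].to_dict("records") == other.table[cols].to_dict("records")


# ---------------------------------------------------------------------------
# ChannelGraph / NetworkStats
# ---------------------------------------------------------------------------


@dataclass
class ChannelGraph:
    """Directed weighted signaling graph for one channel (or the combined
    multichannel connectome). ``level`` records whether nodes are merged
    cells or mirrored layout nodes."""

    channel_id: str
    graph: nx.DiGraph
    level: str = "cell"  # "cell" | "node"

    def __post_init__(self) -> None:
        if self.level not in ("cell", "node"):
            raise ValueError(f"level must be 'cell' or 'node', got {self.level!r}")
        for u, v, data in self.graph.edges(data=True):
            w = data.get("weight")
            if w is None or w <= 0:
                raise ValueError(f"edge {u!r}->{v!r} must carry weight > 0")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}


@dataclass
class NetworkStats:
    """Per-graph summary statistics of a peptidergic connectome."""

    n_nodes: int
    n_edges: int
    graph_density: float | None
    weighted_in_degree: dict[str, float]
    weighted_out_degree: dict[str, float]
    authority: dict[str, float]
    hub: dict[str, float]
    avg_clustering_directed: float
    avg_clustering_undirected: float
    avg_path_length: float | None
    n_components: int
    modularity: float | None = None
    communities: dict[str, int] | None = None
    small_world_sigma: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "graph_density": self.graph_density,
            "weighted_in_degree": self.weighted_in_degree,
            "weighted_out_degree": self.weighted_out_degree,
            "authority": self.authority,
            "hub": self.hub,
            "avg_clustering_directed": self.avg_clustering_directed,
            "avg_clustering_undirected": self.avg_clustering_undirected,
            "avg_path_length": self.avg_path_length,
            "n_components": self.n_components,
            "modularity": self.modularity,
            "communities": self.communities,
            "small_world_sigma": self.small_world_sigma,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# CrossSpeciesResult
# ---------------------------------------------------------------------------


@dataclass
class CrossSpeciesResult:
    """Output of the cross-species co-expression comparison."""

    corr_a: pd.DataFrame
    corr_b: pd.DataFrame
    global_r: float
    global_p_analytic: float
    global_p_empirical: float
    pairs: pd.DataFrame  # per gene-pair records
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (1.0 / (self.n_permutations + 1) - 1e-12 <= self.global_p_empirical <= 1.0):
            raise ValueError("empirical p outside (0, 1] / below 1/(n_perm+1)")

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairs.loc[self.pairs["significant_in_both"]]

    def to_json(self, path) -> None:
        payload = {
            "global_r": self.global_r,
            "global_p_analytic": self.global_p_analytic,
            "global_p_empirical": self.global_p_empirical,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "pairs": self.pairs.to_dict("records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Delimited-text helpers
# ---------------------------------------------------------------------------


def _sniff_sep(path) -> str:
    # comma default, tab auto-detected (Excel exports are one or the other)
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


# -- expression tables --------------------------------------------------


def read_expression_table(
    path,
    orientation: str = "cells_in_rows",
    scale: Scale | str = Scale.log_cpm,
    meta_columns: tuple[str, ...] = ("symmetry", "total_mapped_reads"),
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited cells x genes (or genes x cells) expression table.

    Metadata columns named in ``meta_columns`` are split off into
    ``cell_meta``; a missing symmetry column defaults to ``N`` with a
    logged warning. Duplicate identifiers and non-numeric expression
    values are hard errors.
    """
    if orientation not in ("cells_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "genes_in_rows":
        meta_rows = [m for m in meta_columns if m in df.index]
        df = df.T  # now cells in rows, meta as columns
    else:
        meta_rows = [m for m in meta_columns if m in df.columns]

    meta = df[meta_rows].copy() if meta_rows else pd.DataFrame(index=df.index)
    expr = df.drop(columns=meta_rows)

    dup = expr.index[expr.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate cell identifiers: {sorted(map(str, dup))}")
    dup = expr.columns[expr.columns.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene identifiers: {sorted(map(str, dup))}")

    values = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=float)
    for col in expr.columns:
        parsed = pd.to_numeric(expr[col], errors="coerce")
        bad = parsed.isna() & expr[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric expression value at row {row!r}, column {col!r}: "
                f"{expr.at[row, col]!r}"
            )
        if parsed.isna().any():
            row = parsed.isna().idxmax()
            raise ValueError(f"missing expression value at row {row!r}, column {col!r}")
        values[col] = parsed

    if "symmetry" not in meta.columns:
        logger.warning("no symmetry column in %s; defaulting all cells to 'N'", path)
        meta["symmetry"] = "N"
    if "total_mapped_reads" in meta.columns:
        meta["total_mapped_reads"] = pd.to_numeric(meta["total_mapped_reads"])
    return ExpressionMatrix(values=values, scale=Scale(scale), cell_meta=meta)


def write_expression_table(matrix: ExpressionMatrix, path, sep: str = ",") -> None:
    """Write cells-in-rows delimited table with metadata columns first."""
    out = matrix.cell_meta.copy()
    out = out.drop(columns=[c for c in ("provenance",) if c in out.columns])
    out = pd.concat([out, matrix.values], axis=1)
    out.index.name = "cell_id"
    out.to_csv(path, sep=sep)


# -- pair / role / orthology / layout tables ----------------------------


def read_pair_table(path, gene_universe: set[str] | None = None, sep: str | None = None) -> PairTable:
    """Read CSV with columns channel_id, ligand_gene, receptor_gene."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        warnings.warn(f"empty pair table {path}", stacklevel=2)
        return PairTable(channels=[])
    required = ["channel_id", "ligand_gene", "receptor_gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing columns: {missing}")
    channels = [
        Channel(str(r.channel_id), str(r.ligand_gene), str(r.receptor_gene))
        for r in df.itertuples()
    ]
    if gene_universe is not None:
        for ch in channels:
            for g in (ch.ligand_gene, ch.receptor_gene):
                if g not in gene_universe:
                    warnings.warn(
                        f"channel {ch.channel_id!r} references unknown gene {g!r}",
                        stacklevel=2,
                    )
    return PairTable(channels=channels)


def write_pair_table(pairs: PairTable, path, sep: str = ",") -> None:
    pd.DataFrame(
        [
            {"channel_id": c.channel_id, "ligand_gene": c.ligand_gene,
             "receptor_gene": c.receptor_gene}
            for c in pairs
        ],
        columns=["channel_id", "ligand_gene", "receptor_gene"],
    ).to_csv(path, sep=sep, index=False)


def read_gene_roles(path, sep: str | None = None) -> GeneRoleTable:
    """Read CSV with columns gene_id, roles (semicolon-separated role names)."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        warnings.warn(f"empty gene-role table {path}", stacklevel=2)
        return GeneRoleTable(roles={})
    if not {"gene_id", "roles"}.issubset(df.columns):
        raise ValueError("gene-role table needs columns gene_id, roles")
    roles: dict[str, set[str]] = {}
    for r in df.itertuples():
        roles[str(r.gene_id)] = {tok for tok in str(r.roles).split(";") if tok}
    return GeneRoleTable(roles=roles)


def write_gene_roles(table: GeneRoleTable, path, sep: str = ",") -> None:
    pd.DataFrame(
        [{"gene_id": g, "roles": ";".join(sorted(r))} for g, r in sorted(table.roles.items())],
        columns=["gene_id", "roles"],
    ).to_csv(path, sep=sep, index=False)


def read_orthology_table(path, sep: str | None = None) -> OrthologyMap:
    """Read CSV with columns geneA, candidatesB (semicolon-separated),
    optionally resolvedB."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        warnings.warn(f"empty orthology table {path}", stacklevel=2)
        return OrthologyMap(rows=pd.DataFrame(columns=["gene_a", "candidates_b", "resolved_b"]))
    if not {"geneA", "candidatesB"}.issubset(df.columns):
        raise ValueError("orthology table needs columns geneA, candidatesB")
    rows = pd.DataFrame(
        {
            "gene_a": df["geneA"].astype(str),
            "candidates_b": [
                [tok for tok in str(c).split(";") if tok] for c in df["candidatesB"]
            ],
            "resolved_b": (
                [None if pd.isna(v) else str(v) for v in df["resolvedB"]]
                if "resolvedB" in df.columns
                else None
            ),
        }
    )
    return OrthologyMap(rows=rows)


def write_orthology_table(orth: OrthologyMap, path, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "geneA": orth.rows["gene_a"],
            "candidatesB": [";".join(c) for c in orth.rows["candidates_b"]],
            "resolvedB": orth.rows["resolved_b"],
        }
    ).to_csv(path, sep=sep, index=False)


def read_node_layout(path, sep: str | None = None) -> NodeLayout:
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"node_id": str, "cell_id": str, "side": str})
    df["x"] = df["x"].astype(float)
    df["y"] = df["y"].astype(float)
    return NodeLayout(table=df)


def write_node_layout(layout: NodeLayout, path, sep: str = ",") -> None:
    layout.table[["node_id", "cell_id", "side", "x", "y"]].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GEXF
# ---------------------------------------------------------------------------


def write_gexf(
    graph: ChannelGraph,
    path,
    layout: NodeLayout | None = None,
    node_attrs: dict[str, dict[str, float]] | None = None,
) -> None:
    """Export a channel graph as GEXF 1.2draft with edge weights, node
    positions and optional numeric node attributes.

    Raises if a graph node has no layout entry.
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.graph.nodes())
    for u, v, data in graph.graph.edges(data=True):
        attrs = {"weight": float(data["weight"])}
        if "channels" in data:
            attrs["channels"] = ";".join(
                f"{cid}={w:.6g}" for cid, w in sorted(data["channels"].items())
            )
        g.add_edge(u, v, **attrs)
    if layout is not None:
        known = set(layout.node_ids)
        for node in g.nodes():
            if node not in known:
                raise ValueError(f"node {node!r} missing from layout")
            x, y = layout.position(node)
            g.nodes[node]["viz"] = {"position": {"x": float(x), "y": float(y), "z": 0.0}}
    if node_attrs:
        for name, mapping in node_attrs.items():
            for node, value in mapping.items():
                if node in g.nodes:
                    g.nodes[node][name] = float(value)
    g.graph["channel_id"] = graph.channel_id
    g.graph["level"] = graph.level
    nx.write_gexf(g, path, version="1.2draft")


def read_gexf(path) -> ChannelGraph:
    """Re-read a GEXF file written by :func:`write_gexf`."""
    g = nx.read_gexf(path)
    if not g.is_directed():
        g = g.to_directed()
    out = nx.DiGraph()
    out.add_nodes_from(str(n) for n in g.nodes())
    for u, v, data in g.edges(data=True):
        attrs = {"weight": float(data.get("weight", 1.0))}
        if "channels" in data:
            attrs["channels"] = {
                tok.split("=")[0]: float(tok.split("=")[1])
                for tok in str(data["channels"]).split(";")
                if tok
            }
        out.add_edge(str(u), str(v), **attrs)
    return ChannelGraph(
        channel_id=str(g.graph.get("channel_id", "unknown")),
        graph=out,
        level=str(g.graph.get("level", "cell")),
    )
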