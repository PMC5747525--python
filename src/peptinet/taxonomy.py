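"""Cell classification by signaling repertoire.

Cells are scored against a gene-role table: a cell is *peptidergic* if
any proneuropeptide gene is expressed above threshold and
*transmitter-positive* if any small-neurotransmitter marker (synthesis
enzyme or transporter) is. The cross of the two predicates yields four
classes — purely peptidergic, transmitter-only, dual, and neither (likely
non-neuronal). The module also counts distinct proneuropeptides per cell,
lists autocrine channels (a peptide and its receptor co-expressed in one
cell, i.e. self-loops of the cell-level channel graphs), and builds
combined-expression display maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ChannelGraph, ExpressionMatrix, GeneRoleTable, NodeLayout

__all__ = [
    "CATEGORIES",
    "classify_cells",
    "count_peptides_per_cell",
    "find_autocrine_channels",
    "combined_expression_map",
]

CATEGORIES = ("peptidergic_only", "transmitter_only", "both", "neither")


def _role_genes(matrix: ExpressionMatrix, roles: GeneRoleTable, role: str) -> list[str]:
    return [g for g in roles.genes_with_role(role) if g in matrix.values.columns]


def classify_cells(
    matrix: ExpressionMatrix,
    roles: GeneRoleTable,
    min_expr: float = 0.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cell to one of the four signaling categories.

    Returns (per-cell category Series, count table with columns
    ``count`` and ``percent``, percentages to 1 decimal).
    """
    peptides = _role_genes(matrix, roles, "proneuropeptide")
    transmitters = _role_genes(matrix, roles, "transmitter_marker")
    if not peptides:
        raise ValueError("gene-role table provides no proneuropeptide genes in matrix")
    if not transmitters:
        raise ValueError("gene-role table provides no transmitter_marker genes in matrix")
    pep_pos = (matrix.values[peptides] > min_expr).any(axis=1)
    trans_pos = (matrix.values[transmitters] > min_expr).any(axis=1)
    cat = pd.Series("neither", index=matrix.values.index, name="category")
    cat[pep_pos & ~trans_pos] = "peptidergic_only"
    cat[~pep_pos & trans_pos] = "transmitter_only"
    cat[pep_pos & trans_pos] = "both"
    counts = pd.DataFrame(
        {
            "count": [int((cat == c).sum()) for c in CATEGORIES],
            "percent": [round(100.0 * (cat == c).mean(), 1) for c in CATEGORIES],
        },
        index=pd.Index(CATEGORIES, name="category"),
    )
    return cat, counts


def count_peptides_per_cell(
    matrix: ExpressionMatrix,
    roles: GeneRoleTable,
    min_expr: float = 0.0,
) -> pd.Series:
    """Number of distinct proneuropeptide genes expressed above threshold
    in each cell."""
    peptides = _role_genes(matrix, roles, "proneuropeptide")
    return (matrix.values[peptides] > min_expr).sum(axis=1).rename("n_peptides")


def find_autocrine_channels(channel_graphs: list[ChannelGraph]) -> list[tuple[str, str]]:
    """All (channel_id, cell_id) pairs where a cell signals to itself —
    self-loops of the cell-level channel graphs — in deterministic
    (channel_id, cell_id) order."""
    records = []
    for cg in channel_graphs:
        if cg.level != "cell":
            raise ValueError("autocrine detection requires cell-level channel graphs")
        for u, v in cg.graph.edges():
            if u == v:
                records.append((cg.channel_id, u))
    return sorted(records)


def combined_expression_map(
    matrix: ExpressionMatrix,
    genes: list[str],
    layout: NodeLayout | None = None,
) -> pd.Series:
    """Per-cell (or, with a layout, per-node) sum of log-normalized
    expression over a gene set, for display as a node attribute."""
    if not genes:
        raise ValueError("gene set must be non-empty")
    missing = [g for g in genes if g not in matrix.values.columns]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    per_cell = matrix.values[genes].sum(axis=1)
    if layout is None:
        return per_cell.rename("combined_expression")
    values = {
        node: float(per_cell[layout.cell_of(node)]) for node in layout.node_ids
    }
    return pd.Series(values, name="combined_expression")
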