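"""Normalization, duplicate-cell merging, and mirrored node layout.

Single-cell samples dissociated from several larvae can re-isolate the
same biological cell. Such re-sampled duplicates are detected by
all-against-all Pearson correlation of normalized log expression and
merged (mean per gene) above a correlation cutoff of 0.95. Cells
predicted to be one of a bilaterally symmetric pair (symmetry code Y2)
are then expanded into two mirror-image nodes in the planar map.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, NodeLayout, Scale

logger = logging.getLogger("peptinet")

__all__ = [
    "normalize_rpkm_to_logcpm",
    "pairwise_pearson",
    "merge_duplicate_cells",
    "build_node_layout",
]


def normalize_rpkm_to_logcpm(
    matrix: ExpressionMatrix,
    total_mapped_reads: pd.Series | dict | None = None,
) -> ExpressionMatrix:
    """Convert raw RPKM to log10(1 + cpm).

    cpm = RPKM * 1e6 / total_mapped_reads per cell; the +1 inside the log
    keeps zeros at exactly zero. Library sizes come from the argument or,
    if omitted, from ``cell_meta['total_mapped_reads']``.
    """
    if matrix.scale is not Scale.raw_rpkm:
        raise ValueError("input matrix must be on the raw_rpkm scale")
    if total_mapped_reads is None:
        if "total_mapped_reads" not in matrix.cell_meta.columns:
            raise ValueError("total_mapped_reads not supplied and absent from cell_meta")
        totals = matrix.cell_meta["total_mapped_reads"].astype(float)
    else:
        totals = pd.Series(dict(total_mapped_reads), dtype=float).reindex(matrix.values.index)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise ValueError(f"missing total_mapped_reads for cells: {missing}")
    if (totals <= 0).any():
        raise ValueError("total_mapped_reads must be > 0 for every cell")
    arr = matrix.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("RPKM values must be >= 0")
    cpm = arr * 1e6 / totals.to_numpy()[:, None]
    logv = np.log10(1.0 + cpm)
    meta = matrix.cell_meta.copy()
    meta["total_mapped_reads"] = totals
    return ExpressionMatrix(
        values=pd.DataFrame(logv, index=matrix.values.index, columns=matrix.values.columns),
        scale=Scale.log_cpm,
        cell_meta=meta,
    )


def pairwise_pearson(matrix: ExpressionMatrix) -> pd.DataFrame:
    """All-against-all Pearson correlation between cell expression vectors.

    Computed across genes; a zero-variance cell gets NaN correlations (it
    cannot be meaningfully compared) and a warning.
    """
    if matrix.n_genes < 2:
        raise ValueError("need >= 2 genes to correlate cells")
    arr = matrix.values.to_numpy()
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = np.asarray(r, dtype=float)
    flat = sd == 0
    if flat.any():
        cells = [matrix.cell_ids[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"zero-variance cells excluded from correlation: {cells}", stacklevel=2)
        r[flat, :] = np.nan
        r[:, flat] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame(r, index=matrix.values.index, columns=matrix.values.index)


def _connected_components(adj: np.ndarray) -> list[list[int]]:
    """Components of an undirected boolean adjacency matrix (iterative DFS)."""
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(adj[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def merge_duplicate_cells(
    matrix: ExpressionMatrix,
    threshold: float = 0.95,
    iterative: bool = False,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Merge samples representing the same cell.

    Groups are connected components of the graph linking cells with
    Pearson r >= ``threshold`` (single pass on the input matrix by
    default; ``iterative=True`` re-correlates after each merge round until
    a fixed point). Each group is replaced by one cell holding the mean
    normalized expression per gene; member ids are recorded in
    ``cell_meta['provenance']`` and in the returned group map
    ``merged_cell_id -> [member ids]``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if matrix.scale is not Scale.log_cpm:
        raise ValueError("merging operates on log_cpm matrices; normalize first")

    def one_pass(m: ExpressionMatrix) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
        r = pairwise_pearson(m).to_numpy()
        with np.errstate(invalid="ignore"):
            adj = r >= threshold
        adj &= ~np.isnan(r)
        np.fill_diagonal(adj, False)
        comps = _connected_components(adj | adj.T)
        cells = m.cell_ids
        merged_rows, meta_rows, group_map = [], [], {}
        for comp in comps:
            members = [cells[i] for i in comp]
            # provenance accumulates through rounds
            sources: list[str] = []
            for member in members:
                prov = (
                    m.cell_meta["provenance"].get(member)
                    if "provenance" in m.cell_meta.columns
                    else None
                )
                sources.extend(prov if isinstance(prov, list) else [member])
            new_id = members[0] if len(members) == 1 else "+".join(sorted(members))
            group_map[new_id] = sorted(sources)
            merged_rows.append(m.values.iloc[comp].mean(axis=0).rename(new_id))
            sym = m.cell_meta["symmetry"].iloc[comp].mode().iloc[0]
            meta_rows.append({"cell_id": new_id, "symmetry": sym, "provenance": sorted(sources)})
        values = pd.DataFrame(merged_rows)
        meta = pd.DataFrame(meta_rows).set_index("cell_id")
        out = ExpressionMatrix(values=values, scale=Scale.log_cpm, cell_meta=meta)
        return out, group_map

    merged, groups = one_pass(matrix)
    if iterative:
        while True:
            nxt, nxt_groups = one_pass(merged)
            if nxt.n_cells == merged.n_cells:
                break
            merged, groups = nxt, nxt_groups
    n_merged = sum(1 for g in groups.values() if len(g) > 1)
    if n_merged:
        logger.info("merged %d duplicate groups (threshold %.2f)", n_merged, threshold)
    return merged, groups


def build_node_layout(
    matrix: ExpressionMatrix,
    coordinates: pd.DataFrame | dict[str, tuple[float, float]],
) -> NodeLayout:
    """Expand cells into planar map nodes.

    Y2 (bilateral pair) cells yield two mirror-image nodes at (-x, y) and
    (x, y) with ids ``<cell>__L`` / ``<cell>__R``; N and Y1 cells yield a
    single node ``<cell>`` at (x, y).
    """
    if isinstance(coordinates, dict):
        coords = pd.DataFrame(
            [(c, xy[0], xy[1]) for c, xy in coordinates.items()],
            columns=["cell_id", "x", "y"],
        ).set_index("cell_id")
    else:
        coords = coordinates.set_index("cell_id") if "cell_id" in coordinates.columns else coordinates
    missing = [c for c in matrix.cell_ids if c not in coords.index]
    if missing:
        raise ValueError(f"cells without coordinates: {missing}")
    rows = []
    for cell in matrix.cell_ids:
        x = float(coords.at[cell, "x"])
        y = float(coords.at[cell, "y"])
        sym = matrix.cell_meta.at[cell, "symmetry"]
        if sym == "Y2":
            if x == 0.0:
                warnings.warn(
                    f"Y2 cell {cell!r} sits on the midline (x=0); mirror nodes coincide",
                    stacklevel=2,
                )
            rows.append({"node_id": f"{cell}__L", "cell_id": cell, "side": "left", "x": -x, "y": y})
            rows.append({"node_id": f"{cell}__R", "cell_id": cell, "side": "right", "x": x, "y": y})
        else:
            rows.append({"node_id": cell, "cell_id": cell, "side": "single", "x": x, "y": y})
    return NodeLayout(table=pd.DataFrame(rows, columns=["node_id", "cell_id", "side", "x", "y"]))
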