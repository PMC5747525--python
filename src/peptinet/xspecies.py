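"""Cross-species comparison of gene co-expression structure.

Two single-cell datasets (e.g. annelid episphere and mouse hypothalamus)
are compared over a table of orthologous marker genes. Within each
species, all-against-all Pearson correlations between marker genes are
computed across cells. One-to-many orthologs are resolved by keeping the
candidate whose correlation *profile* best matches (lowest correlation-
test p-value). The global statistic is the Pearson correlation between
the two correlation matrices over matched off-diagonal entries
(identical-marker entries are excluded: they are 1 in both species and
would induce a spurious signal).

Significance comes from a per-gene cell-permutation scheme: each gene's
values are independently shuffled across cells in both datasets and the
whole statistic chain recomputed, many times. The null distribution of
the global correlation gives an empirical global p-value, and the null
per-pair p-values drive a minP (Westfall-Young) family-wise correction
of the per-pair correlation tests. Presence/absence Fisher exact tests
and the Maximal Information Coefficient are reported per pair as
complementary association measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CrossSpeciesResult, ExpressionMatrix, OrthologyMap
from .mic import mic_score

__all__ = [
    "gene_correlation_matrix",
    "resolve_orthologs",
    "global_cross_species_correlation",
    "permutation_scheme",
    "PermutationNull",
    "corrected_pair_pvalues",
    "presence_absence_fisher",
    "mic_score",
    "compare_species",
    "write_masked_matrix",
]


def _values(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return matrix


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r from the t distribution with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return p


def gene_correlation_matrix(
    matrix,
    markers: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation across cells for every marker-gene pair.

    Returns (r matrix, two-sided analytic p matrix), both genes x genes
    with unit diagonal (p diagonal NaN). Constant genes get NaN rows and
    columns with a warning.
    """
    values = _values(matrix)
    if markers is not None:
        missing = [g for g in markers if g not in values.columns]
        if missing:
            raise ValueError(f"markers absent from matrix: {missing}")
        values = values[markers]
    n = values.shape[0]
    if n < 3:
        raise ValueError("need >= 3 cells for correlation tests")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r = np.atleast_2d(np.asarray(r, dtype=float))
    flat = sd == 0
    if flat.any():
        genes = [values.columns[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"constant genes excluded from correlation: {genes}", stacklevel=2)
        r[flat, :] = np.nan
        r[:, flat] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    p = _corr_pvalues(r, n)
    np.fill_diagonal(p, np.nan)
    genes = values.columns
    return (
        pd.DataFrame(r, index=genes, columns=genes),
        pd.DataFrame(p, index=genes, columns=genes),
    )


# ---------------------------------------------------------------------------
# ortholog resolution
# ---------------------------------------------------------------------------


def _profile_test(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """p-value of the correlation test between two correlation profiles."""
    mask = np.isfinite(profile_a) & np.isfinite(profile_b)
    m = int(mask.sum())
    if m < 3:
        return 1.0
    r = np.corrcoef(profile_a[mask], profile_b[mask])[0, 1]
    if np.isnan(r):
        return 1.0
    return float(_corr_pvalues(np.array([r]), m)[0])


def resolve_orthologs(
    corr_a: pd.DataFrame,
    corr_b: pd.DataFrame,
    orthology: OrthologyMap,
) -> OrthologyMap:
    """Pick one species-B gene per species-A gene.

    Single-candidate genes resolve trivially (these act as anchors).
    For a multi-candidate gene, the candidate whose correlation profile
    over the anchor positions best matches the A-gene's profile (lowest
    correlation-test p) is retained; ties break lexicographically.
    Candidates absent from the B matrix are dropped with a warning; genes
    with no usable candidate are excluded from the resolved map.
    """
    rows = []
    anchors_a: list[str] = []
    anchors_b: list[str] = []
    pending = []
    for _, row in orthology.rows.iterrows():
        gene_a = row["gene_a"]
        if gene_a not in corr_a.index:
            warnings.warn(f"species-A gene {gene_a!r} absent from matrix A; excluded", stacklevel=2)
            continue
        cands = [c for c in row["candidates_b"] if c in corr_b.index]
        dropped = [c for c in row["candidates_b"] if c not in corr_b.index]
        if dropped:
            warnings.warn(f"candidates absent from matrix B dropped for {gene_a!r}: {dropped}",
                          stacklevel=2)
        if not cands:
            warnings.warn(f"gene {gene_a!r} has no usable candidate; excluded", stacklevel=2)
            continue
        if len(cands) == 1:
            anchors_a.append(gene_a)
            anchors_b.append(cands[0])
            rows.append({"gene_a": gene_a, "candidates_b": cands, "resolved_b": cands[0]})
        else:
            pending.append((gene_a, cands))
    for gene_a, cands in pending:
        pos_a = [g for g in anchors_a if g != gene_a]
        if not pos_a:
            warnings.warn(
                f"no anchor genes to resolve {gene_a!r}; using lexicographic first candidate",
                stacklevel=2,
            )
            best = sorted(cands)[0]
        else:
            pos_b = [anchors_b[anchors_a.index(g)] for g in pos_a]
            prof_a = corr_a.loc[gene_a, pos_a].to_numpy(dtype=float)
            scored = []
            for cand in cands:
                prof_b = corr_b.loc[cand, pos_b].to_numpy(dtype=float)
                scored.append((_profile_test(prof_a, prof_b), cand))
            best = min(scored)[1]  # p then lexicographic
        rows.append({"gene_a": gene_a, "candidates_b": cands, "resolved_b": best})
    order = {g: i for i, g in enumerate(orthology.genes_a)}
    rows.sort(key=lambda r: order[r["gene_a"]])
    return OrthologyMap(rows=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# global correlation of correlations
# ---------------------------------------------------------------------------


def _matched_offdiag(
    corr_a: pd.DataFrame,
    corr_b: pd.DataFrame,
    genes_a: list[str],
    genes_b: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    a = corr_a.loc[genes_a, genes_a].to_numpy(dtype=float)
    b = corr_b.loc[genes_b, genes_b].to_numpy(dtype=float)
    iu = np.triu_indices(len(genes_a), k=1)
    va, vb = a[iu], b[iu]
    mask = np.isfinite(va) & np.isfinite(vb)
    return va[mask], vb[mask]


def _resolved_gene_lists(orthology: OrthologyMap, corr_a, corr_b) -> tuple[list[str], list[str]]:
    genes_a, genes_b = [], []
    for _, row in orthology.rows.iterrows():
        if row["resolved_b"] is None:
            continue
        if row["gene_a"] in corr_a.index and row["resolved_b"] in corr_b.index:
            genes_a.append(row["gene_a"])
            genes_b.append(row["resolved_b"])
    return genes_a, genes_b


def global_cross_species_correlation(
    corr_a: pd.DataFrame,
    corr_b: pd.DataFrame,
    orthology: OrthologyMap,
) -> tuple[float | None, float | None]:
    """Pearson correlation between the two correlation matrices over
    matched off-diagonal (non-identical-marker) entries, plus its
    analytic two-sided p. Returns (None, None) when fewer than 3 usable
    entries exist."""
    genes_a, genes_b = _resolved_gene_lists(orthology, corr_a, corr_b)
    va, vb = _matched_offdiag(corr_a, corr_b, genes_a, genes_b)
    if len(va) < 3:
        return None, None
    r = float(np.corrcoef(va, vb)[0, 1])
    p = float(_corr_pvalues(np.array([r]), len(va))[0])
    return r, p


# ---------------------------------------------------------------------------
# permutation scheme
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Null distributions from the per-gene cell-permutation scheme."""

    null_global_r: np.ndarray  # (n_perm,)
    null_pair_p_a: np.ndarray  # (n_perm, n_pairs)
    null_pair_p_b: np.ndarray  # (n_perm, n_pairs)
    pair_index: list[tuple[str, str]]  # species-A gene pairs (i < j)
    n_permutations: int
    seed: int


def _permute_columns(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each gene (column) across cells (rows),
    drawing permutations sequentially in column order."""
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        out[:, j] = arr[rng.permutation(n), j]
    return out


def permutation_scheme(
    matrix_a,
    matrix_b,
    orthology: OrthologyMap,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Recompute the full statistic chain on per-gene permuted data.

    For each replicate, every gene's values are independently permuted
    across cells in both datasets; correlation matrices, per-pair
    analytic p-values and the global correlation are recomputed with the
    ortholog resolution fixed to the observed one (given by
    ``orthology``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    va = _values(matrix_a)
    vb = _values(matrix_b)
    genes_a, genes_b = _resolved_gene_lists(
        orthology, va.T, vb.T  # membership check only needs the gene index
    )
    arr_a = va[genes_a].to_numpy(dtype=float)
    arr_b = vb[genes_b].to_numpy(dtype=float)
    na, nb = arr_a.shape[0], arr_b.shape[0]
    g = len(genes_a)
    iu = np.triu_indices(g, k=1)
    pair_index = [(genes_a[i], genes_a[j]) for i, j in zip(*iu)]
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    null_pa = np.empty((n_perm, len(pair_index)))
    null_pb = np.empty((n_perm, len(pair_index)))
    for k in range(n_perm):
        pa = _permute_columns(arr_a, rng)
        pb = _permute_columns(arr_b, rng)
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = np.corrcoef(pa, rowvar=False)
            rb = np.corrcoef(pb, rowvar=False)
        ra = np.atleast_2d(ra)
        rb = np.atleast_2d(rb)
        vra, vrb = ra[iu], rb[iu]
        mask = np.isfinite(vra) & np.isfinite(vrb)
        if mask.sum() >= 3:
            null_r[k] = np.corrcoef(vra[mask], vrb[mask])[0, 1]
        else:
            null_r[k] = np.nan
        null_pa[k] = _corr_pvalues(vra, na)
        null_pb[k] = _corr_pvalues(vrb, nb)
    return PermutationNull(
        null_global_r=null_r,
        null_pair_p_a=null_pa,
        null_pair_p_b=null_pb,
        pair_index=pair_index,
        n_permutations=n_perm,
        seed=seed,
    )


def empirical_global_p(observed_r: float, null: PermutationNull) -> float:
    """(1 + #{null >= observed}) / (n_perm + 1)."""
    null_r = null.null_global_r
    finite = null_r[np.isfinite(null_r)]
    return float((1 + np.sum(finite >= observed_r)) / (null.n_permutations + 1))


def corrected_pair_pvalues(
    observed_p: np.ndarray,
    null_pair_p: np.ndarray,
    method: str = "single-step",
) -> np.ndarray:
    """minP (Westfall-Young) family-wise corrected p-values.

    single-step: corrected p_i = (1 + #{replicates with min_j null_p_j <=
    observed p_i}) / (n_perm + 1). step-down: the minimum is taken over
    the pairs whose observed p is >= the current one (Westfall-Young
    step-down), with monotonicity enforced.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    n_perm = null_pair_p.shape[0]
    if method == "single-step":
        minp = np.nanmin(null_pair_p, axis=1)  # (n_perm,)
        counts = (minp[:, None] <= observed_p[None, :]).sum(axis=0)
        return (1 + counts) / (n_perm + 1)
    if method == "step-down":
        order = np.argsort(observed_p, kind="mergesort")
        corrected = np.empty_like(observed_p)
        prev = 0.0
        for rank, idx in enumerate(order):
            sub = null_pair_p[:, order[rank:]]
            minp = np.nanmin(sub, axis=1)
            p = (1 + np.sum(minp <= observed_p[idx])) / (n_perm + 1)
            prev = max(prev, p)
            corrected[idx] = prev
        return corrected
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# per-pair auxiliary statistics
# ---------------------------------------------------------------------------


def presence_absence_fisher(gene_a_values, gene_b_values, threshold: float = 0.0) -> float:
    """Two-sided Fisher exact p on the 2x2 presence/absence table of two
    genes across the cells of one species. Degenerate margins (a gene
    expressed in all or no cells) give p = 1 with a warning."""
    a = np.asarray(gene_a_values, dtype=float) > threshold
    b = np.asarray(gene_b_values, dtype=float) > threshold
    if len(a) != len(b) or len(a) < 1:
        raise ValueError("need equal-length non-empty vectors")
    if a.all() or (~a).all() or b.all() or (~b).all():
        warnings.warn("degenerate presence/absence margin: Fisher p = 1", stacklevel=2)
        return 1.0
    table = [
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# top-level comparison
# ---------------------------------------------------------------------------


def compare_species(
    matrix_a,
    matrix_b,
    orthology: OrthologyMap,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    correction: str = "single-step",
    compute_fisher: bool = True,
    compute_mic: bool = True,
) -> CrossSpeciesResult:
    """Run the full cross-species co-expression comparison.

    ``matrix_a``/``matrix_b`` are cells x genes tables (ExpressionMatrix
    or DataFrame) on whatever scale the correlations should be computed
    on (log-normalized by convention). Markers are the orthology table's
    species-A genes and their candidates.
    """
    va, vb = _values(matrix_a), _values(matrix_b)
    markers_a = [g for g in orthology.genes_a if g in va.columns]
    cand_b = sorted({c for g in markers_a for c in orthology.candidates(g) if c in vb.columns})
    corr_a, pmat_a = gene_correlation_matrix(va, markers_a)
    corr_b, pmat_b = gene_correlation_matrix(vb, cand_b)
    resolved = resolve_orthologs(corr_a, corr_b, orthology)
    global_r, global_p_analytic = global_cross_species_correlation(corr_a, corr_b, resolved)
    if global_r is None:
        raise ValueError("fewer than 3 matched off-diagonal entries; comparison undefined")

    null = permutation_scheme(va, vb, resolved, n_perm=n_perm, seed=seed)
    global_p_emp = empirical_global_p(global_r, null)

    genes_a, genes_b = _resolved_gene_lists(resolved, corr_a, corr_b)
    b_of = dict(zip(genes_a, genes_b))
    obs_pa = np.array([pmat_a.at[i, j] for i, j in null.pair_index])
    obs_pb = np.array([pmat_b.at[b_of[i], b_of[j]] for i, j in null.pair_index])
    corr_pa = corrected_pair_pvalues(obs_pa, null.null_pair_p_a, method=correction)
    corr_pb = corrected_pair_pvalues(obs_pb, null.null_pair_p_b, method=correction)

    records = []
    for k, (gi, gj) in enumerate(null.pair_index):
        bi, bj = b_of[gi], b_of[gj]
        rec = {
            "gene_a_i": gi,
            "gene_a_j": gj,
            "gene_b_i": bi,
            "gene_b_j": bj,
            "r_a": float(corr_a.at[gi, gj]),
            "r_b": float(corr_b.at[bi, bj]),
            "p_raw_a": float(obs_pa[k]),
            "p_raw_b": float(obs_pb[k]),
            "p_corr_a": float(corr_pa[k]),
            "p_corr_b": float(corr_pb[k]),
            "significant_in_both": bool(corr_pa[k] <= alpha and corr_pb[k] <= alpha),
        }
        if compute_fisher:
            rec["fisher_p_a"] = presence_absence_fisher(va[gi], va[gj])
            rec["fisher_p_b"] = presence_absence_fisher(vb[bi], vb[bj])
        if compute_mic:
            rec["mic_a"] = mic_score(va[gi].to_numpy(), va[gj].to_numpy())
            rec["mic_b"] = mic_score(vb[bi].to_numpy(), vb[bj].to_numpy())
        records.append(rec)
    pairs = pd.DataFrame(records)
    return CrossSpeciesResult(
        corr_a=corr_a.loc[genes_a, genes_a],
        corr_b=corr_b.loc[genes_b, genes_b],
        global_r=global_r,
        global_p_analytic=global_p_analytic,
        global_p_empirical=global_p_emp,
        pairs=pairs,
        n_permutations=n_perm,
        seed=seed,
    )


def write_masked_matrix(
    corr: pd.DataFrame,
    pairs: pd.DataFrame,
    species: str,
    path,
    alpha: float = 0.05,
) -> None:
    """Export a correlation matrix as CSV with entries whose corrected p
    exceeds alpha left empty (diagonal kept)."""
    suffix = {"a": ("gene_a_i", "gene_a_j", "p_corr_a"),
              "b": ("gene_b_i", "gene_b_j", "p_corr_b")}[species]
    col_i, col_j, col_p = suffix
    masked = corr.copy().astype(object)
    sig = {
        frozenset((row[col_i], row[col_j]))
        for _, row in pairs.iterrows()
        if row[col_p] <= alpha
    }
    for i in corr.index:
        for j in corr.columns:
            if i != j and frozenset((i, j)) not in sig:
                masked.at[i, j] = ""
    masked.to_csv(path)
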