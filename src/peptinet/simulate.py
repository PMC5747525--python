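"""Synthetic single-cell datasets with planted ground truth.

The generator emulates the statistical regime of a sparse, log-scale
single-cell expression study of a peptidergic brain region:

* zero-inflated log-normal background expression;
* a small panel of proneuropeptide and GPCR genes expressed strongly in
  designated, overlapping sender/receiver cell subsets (one subset pair
  per ligand-receptor channel), so each channel induces a known sparse
  edge set;
* re-sampled duplicate cells — noisy copies of a common profile whose
  within-group Pearson correlation exceeds the 0.95 merge cutoff;
* per-cell bilateral-symmetry flags and half-plane coordinates for the
  mirror-node layout;
* a two-species mode in which K latent co-expression modules drive
  orthologous marker genes in both species, with optional decoy
  ortholog candidates.

Expression is drafted in log10(1 + cpm) space and converted back to
RPKM with per-sample library sizes, so that the pipeline's normalization
step recovers the planted log values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    Channel,
    ExpressionMatrix,
    GeneRoleTable,
    OrthologyMap,
    PairTable,
    Scale,
)

__all__ = ["SimConfig", "TruthBundle", "TwoSpeciesTruth", "generate_dataset", "generate_two_species"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a head-sized dataset: 120 samples over 300 genes,
    10 signaling channels with 6 senders and 6 receivers each, 8 planted
    duplicate groups of 2, half of the cells bilaterally symmetric, and
    rare dropout of the strongly expressed signal genes (deeply
    sequenced full-length scRNA-seq loses few transcripts of that
    abundance).
    """

    seed: int
    n_cells: int = 120
    n_genes: int = 300
    n_peptides: int = 20
    n_receptors: int = 12
    n_transmitters: int = 6
    n_channels: int = 10
    senders_per_channel: int = 6
    receivers_per_channel: int = 6
    dup_group_count: int = 8
    dup_group_size: int = 2
    dup_noise_sd: float = 0.05
    fraction_bilateral: float = 0.5
    fraction_asymmetric: float = 0.1
    dropout: float = 0.01
    transmitter_fraction: float = 0.2
    background_on_rate: float = 0.15
    background_log_mean: float = 1.5
    background_log_sd: float = 0.5
    signal_log_mean: float = 2.5
    signal_log_sd: float = 0.3
    # two-species mode
    n_markers: int = 24
    n_cells_a: int = 60
    n_cells_b: int = 60
    n_modules: int = 3
    genes_per_module: int = 4
    module_strength: float = 0.9
    multi_candidate_fraction: float = 0.25
    max_candidates: int = 3

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        roles_total = self.n_peptides + self.n_receptors + self.n_transmitters
        if roles_total > self.n_genes:
            raise ValueError("role genes exceed n_genes")
        if self.senders_per_channel > self.n_cells or self.receivers_per_channel > self.n_cells:
            raise ValueError("channel subsets exceed the cell set")
        if self.n_channels > min(self.n_peptides, self.n_receptors):
            raise ValueError(
                "each channel needs its own ligand and receptor gene: "
                "n_channels must not exceed min(n_peptides, n_receptors)"
            )
        if self.dup_group_count * self.dup_group_size > self.n_cells:
            raise ValueError("duplicate groups exceed the cell set")
        for p in (self.fraction_bilateral, self.fraction_asymmetric, self.dropout,
                  self.background_on_rate, self.multi_candidate_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.fraction_bilateral + self.fraction_asymmetric > 1.0:
            raise ValueError("symmetry fractions sum above 1")
        if not 0.0 <= self.module_strength <= 1.0:
            raise ValueError("module_strength outside [0, 1]")
        if self.n_modules * self.genes_per_module > self.n_markers:
            raise ValueError("module genes exceed marker count")


@dataclass
class TruthBundle:
    """Planted ground truth of a single-species dataset."""

    channels: list[Channel]
    senders: dict[str, list[str]]  # channel_id -> designated sender samples
    receivers: dict[str, list[str]]
    planted_edges: dict[str, set[tuple[str, str]]]  # designated, pre-dropout
    duplicate_groups: list[list[str]]  # sample ids per planted group (size >= 2)
    category: dict[str, str]  # designed signaling class per sample
    n_peptides_per_cell: dict[str, int]  # designed (pre-dropout) peptide counts

    def all_planted_edges(self) -> set[tuple[str, str, str]]:
        return {(cid, s, t) for cid, edges in self.planted_edges.items() for s, t in edges}


@dataclass
class TwoSpeciesTruth:
    """Planted ground truth of a two-species dataset."""

    module_of_gene_a: dict[str, int | None]
    module_pairs: set[tuple[str, str]]  # within-module A-gene pairs (i < j)
    true_ortholog: dict[str, str]


def _draw_log_matrix(rng, n_cells, n_genes, cfg: SimConfig) -> np.ndarray:
    on = rng.random((n_cells, n_genes)) < cfg.background_on_rate
    vals = rng.normal(cfg.background_log_mean, cfg.background_log_sd, (n_cells, n_genes))
    return np.where(on, np.clip(vals, 0.1, None), 0.0)


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, GeneRoleTable, PairTable, pd.DataFrame, TruthBundle]:
    """Generate one single-species dataset.

    Returns (raw-RPKM ExpressionMatrix with symmetry and library-size
    metadata, GeneRoleTable, PairTable, per-sample coordinate table,
    TruthBundle). Deterministic given ``config.seed``.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    pep_genes = [f"PNP{i:03d}" for i in range(cfg.n_peptides)]
    rec_genes = [f"GPCR{i:03d}" for i in range(cfg.n_receptors)]
    trm_genes = [f"TRM{i:03d}" for i in range(cfg.n_transmitters)]
    n_other = cfg.n_genes - cfg.n_peptides - cfg.n_receptors - cfg.n_transmitters
    other_genes = [f"G{i:04d}" for i in range(n_other)]
    genes = pep_genes + rec_genes + trm_genes + other_genes

    roles = {g: {"proneuropeptide"} for g in pep_genes}
    roles |= {g: {"gpcr_receptor"} for g in rec_genes}
    roles |= {g: {"transmitter_marker"} for g in trm_genes}
    roles |= {g: {"other"} for g in other_genes}
    role_table = GeneRoleTable(roles=roles)

    # base cells (before duplicate re-sampling)
    n_base = cfg.n_cells - cfg.dup_group_count * (cfg.dup_group_size - 1)
    base_ids = [f"C{i:03d}" for i in range(n_base)]

    # channels: one private ligand and receptor gene each, so the
    # expression predicate reproduces exactly the designated subsets
    lig_picks = rng.choice(pep_genes, size=cfg.n_channels, replace=False)
    rec_picks = rng.choice(rec_genes, size=cfg.n_channels, replace=False)
    channels, senders, receivers = [], {}, {}
    for k, (lig, rec) in enumerate(zip(lig_picks, rec_picks)):
        cid = f"ch{k:02d}"
        channels.append(Channel(cid, lig, rec))
        senders[cid] = sorted(rng.choice(base_ids, size=cfg.senders_per_channel, replace=False))
        receivers[cid] = sorted(rng.choice(base_ids, size=cfg.receivers_per_channel, replace=False))
    pair_table = PairTable(channels=channels)

    # base log-expression: zero-inflated background, then planted signal.
    # channel genes are wiped outside their designated subset so each
    # channel's edge set is exactly the designated sender x receiver product.
    log_expr = _draw_log_matrix(rng, n_base, cfg.n_genes, cfg)
    gi = {g: j for j, g in enumerate(genes)}
    ci = {c: j for j, c in enumerate(base_ids)}
    # transmitter markers: planted in a designated cell fraction (the
    # background rate would make dual peptide/transmitter cells dominate)
    trm_cols_idx = [gi[g] for g in trm_genes]
    log_expr[:, trm_cols_idx] = 0.0
    trm_positive = rng.random(n_base) < cfg.transmitter_fraction
    for b in np.flatnonzero(trm_positive):
        k = int(rng.integers(1, 3))  # one or two markers per transmitter cell
        for j in rng.choice(trm_cols_idx, size=k, replace=False):
            log_expr[b, j] = np.clip(rng.normal(cfg.signal_log_mean, cfg.signal_log_sd), 0.5, None)
    for ch in channels:
        log_expr[:, gi[ch.ligand_gene]] = 0.0
        log_expr[:, gi[ch.receptor_gene]] = 0.0
    for ch in channels:
        for s in senders[ch.channel_id]:
            log_expr[ci[s], gi[ch.ligand_gene]] = max(
                log_expr[ci[s], gi[ch.ligand_gene]],
                np.clip(rng.normal(cfg.signal_log_mean, cfg.signal_log_sd), 0.5, None),
            )
        for t in receivers[ch.channel_id]:
            log_expr[ci[t], gi[ch.receptor_gene]] = max(
                log_expr[ci[t], gi[ch.receptor_gene]],
                np.clip(rng.normal(cfg.signal_log_mean, cfg.signal_log_sd), 0.5, None),
            )

    # designed truth, recorded before dropout
    planted_edges = {
        ch.channel_id: {
            (s, t) for s in senders[ch.channel_id] for t in receivers[ch.channel_id]
        }
        for ch in channels
    }
    pep_cols = [gi[g] for g in pep_genes]
    trm_cols = [gi[g] for g in trm_genes]
    pep_counts = (log_expr[:, pep_cols] > 0).sum(axis=1)
    trm_pos = (log_expr[:, trm_cols] > 0).any(axis=1)
    category = {}
    for cell in base_ids:
        p, t = pep_counts[ci[cell]] > 0, trm_pos[ci[cell]]
        category[cell] = (
            "both" if (p and t) else "peptidergic_only" if p
            else "transmitter_only" if t else "neither"
        )

    # dropout on the planted signal (rare: these are abundant transcripts)
    if cfg.dropout > 0:
        drop = rng.random(log_expr.shape) < cfg.dropout
        log_expr = np.where(drop, 0.0, log_expr)

    # duplicate groups: noisy re-samples of a common base profile
    dup_bases = rng.choice(n_base, size=cfg.dup_group_count, replace=False)
    sample_ids, sample_rows, sample_base = [], [], []
    dup_groups = []
    dup_base_set = set(dup_bases.tolist())
    for b, cell in enumerate(base_ids):
        if b in dup_base_set:
            group = []
            for rep in range(cfg.dup_group_size):
                sid = f"{cell}r{rep}"
                noise = rng.normal(0.0, cfg.dup_noise_sd, cfg.n_genes)
                row = np.where(log_expr[b] > 0, np.clip(log_expr[b] + noise, 0.01, None), 0.0)
                sample_ids.append(sid)
                sample_rows.append(row)
                sample_base.append(cell)
                group.append(sid)
            dup_groups.append(group)
        else:
            sample_ids.append(cell)
            sample_rows.append(log_expr[b])
            sample_base.append(cell)
    log_samples = np.vstack(sample_rows)

    # per-sample truth views (duplicates inherit their base cell's design)
    base_of = dict(zip(sample_ids, sample_base))
    samples_of = {}
    for sid, b in base_of.items():
        samples_of.setdefault(b, []).append(sid)
    planted_sample_edges = {
        cid: {
            (ss, tt)
            for s, t in edges
            for ss in samples_of[s]
            for tt in samples_of[t]
        }
        for cid, edges in planted_edges.items()
    }
    senders_s = {cid: sorted(ss for s in subs for ss in samples_of[s]) for cid, subs in senders.items()}
    receivers_s = {cid: sorted(tt for t in subs for tt in samples_of[t]) for cid, subs in receivers.items()}
    category_s = {sid: category[base_of[sid]] for sid in sample_ids}
    pep_counts_s = {sid: int(pep_counts[ci[base_of[sid]]]) for sid in sample_ids}

    # symmetry flags and half-plane coordinates per base cell
    u = rng.random(n_base)
    sym_of_base = np.where(
        u < cfg.fraction_bilateral, "Y2",
        np.where(u < cfg.fraction_bilateral + cfg.fraction_asymmetric, "Y1", "N"),
    )
    xs = rng.uniform(1.0, 10.0, n_base)
    ys = rng.uniform(-10.0, 10.0, n_base)
    symmetry = [sym_of_base[ci[base_of[sid]]] for sid in sample_ids]
    coords = pd.DataFrame(
        {
            "cell_id": sample_ids,
            "x": [xs[ci[base_of[sid]]] for sid in sample_ids],
            "y": [ys[ci[base_of[sid]]] for sid in sample_ids],
        }
    )

    # convert to raw RPKM with per-sample library sizes
    totals = rng.uniform(5e5, 2e6, len(sample_ids))
    cpm = 10.0**log_samples - 1.0
    rpkm = cpm * totals[:, None] / 1e6
    meta = pd.DataFrame(
        {"symmetry": symmetry, "total_mapped_reads": totals},
        index=pd.Index(sample_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=meta.index, columns=genes),
        scale=Scale.raw_rpkm,
        cell_meta=meta,
    )
    truth = TruthBundle(
        channels=channels,
        senders=senders_s,
        receivers=receivers_s,
        planted_edges=planted_sample_edges,
        duplicate_groups=dup_groups,
        category=category_s,
        n_peptides_per_cell=pep_counts_s,
    )
    return matrix, role_table, pair_table, coords, truth


# ---------------------------------------------------------------------------
# two-species generator
# ---------------------------------------------------------------------------


def generate_two_species(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologyMap, TwoSpeciesTruth]:
    """Generate two marker-gene expression matrices sharing K planted
    co-expression modules through an orthology map.

    Module genes load on a per-cell latent factor with loading
    sqrt(module_strength), so the within-module gene-gene correlation is
    ~``module_strength`` in both species. A fraction of markers receive
    decoy ortholog candidates (independent-noise genes) to exercise
    resolution. ``n_modules=0`` yields a pure null dataset.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes_a = [f"gA{i:03d}" for i in range(cfg.n_markers)]
    genes_b = [f"gB{i:03d}" for i in range(cfg.n_markers)]

    module_of: dict[str, int | None] = {g: None for g in genes_a}
    idx = rng.permutation(cfg.n_markers)
    for m in range(cfg.n_modules):
        for j in idx[m * cfg.genes_per_module : (m + 1) * cfg.genes_per_module]:
            module_of[genes_a[j]] = m

    def species_matrix(n_cells: int, gene_names: list[str]) -> np.ndarray:
        factors = rng.standard_normal((n_cells, max(cfg.n_modules, 1)))
        z = rng.standard_normal((n_cells, cfg.n_markers))
        lam = np.sqrt(cfg.module_strength)
        out = np.empty((n_cells, cfg.n_markers))
        for j, ga in enumerate(genes_a):
            m = module_of[ga]
            if m is None:
                out[:, j] = z[:, j]
            else:
                out[:, j] = lam * factors[:, m] + np.sqrt(1.0 - cfg.module_strength) * z[:, j]
        return np.clip(1.5 + 0.5 * out, 0.0, None)

    arr_a = species_matrix(cfg.n_cells_a, genes_a)
    arr_b = species_matrix(cfg.n_cells_b, genes_b)

    # decoy ortholog candidates: independent-noise B genes
    rows = []
    decoy_cols = []
    decoy_names = []
    true_ortholog = {}
    for j, ga in enumerate(genes_a):
        cands = [genes_b[j]]
        if rng.random() < cfg.multi_candidate_fraction:
            n_dec = int(rng.integers(1, cfg.max_candidates))
            for d in range(n_dec):
                name = f"gB{j:03d}d{d}"
                decoy_names.append(name)
                decoy_cols.append(np.clip(1.5 + 0.5 * rng.standard_normal(cfg.n_cells_b), 0.0, None))
                cands.append(name)
        true_ortholog[ga] = genes_b[j]
        rows.append({"gene_a": ga, "candidates_b": sorted(cands), "resolved_b": None})
    if decoy_cols:
        arr_b = np.hstack([arr_b, np.column_stack(decoy_cols)])
    all_genes_b = genes_b + decoy_names

    cells_a = [f"a{i:03d}" for i in range(cfg.n_cells_a)]
    cells_b = [f"b{i:03d}" for i in range(cfg.n_cells_b)]
    mat_a = ExpressionMatrix(
        values=pd.DataFrame(arr_a, index=pd.Index(cells_a, name="cell_id"), columns=genes_a),
        scale=Scale.log_cpm,
    )
    mat_b = ExpressionMatrix(
        values=pd.DataFrame(arr_b, index=pd.Index(cells_b, name="cell_id"), columns=all_genes_b),
        scale=Scale.log_cpm,
    )
    pairs = {
        (gi_, gj_) if gi_ < gj_ else (gj_, gi_)
        for gi_ in genes_a
        for gj_ in genes_a
        if gi_ != gj_ and module_of[gi_] is not None and module_of[gi_] == module_of[gj_]
    }
    truth = TwoSpeciesTruth(
        module_of_gene_a=module_of,
        module_pairs=pairs,
        true_ortholog=true_ortholog,
    )
    return mat_a, mat_b, OrthologyMap(rows=pd.DataFrame(rows)), truth
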