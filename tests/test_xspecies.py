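"""Cross-species co-expression comparison: correlations, ortholog
resolution, permutation null, minP correction, Fisher exact."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peptinet import (
    OrthologyMap,
    SimConfig,
    compare_species,
    corrected_pair_pvalues,
    gene_correlation_matrix,
    generate_two_species,
    global_cross_species_correlation,
    permutation_scheme,
    presence_absence_fisher,
    resolve_orthologs,
)
from peptinet.xspecies import empirical_global_p


def _identity_orthology(genes_a, genes_b):
    return OrthologyMap(
        rows=pd.DataFrame(
            {
                "gene_a": genes_a,
                "candidates_b": [[g] for g in genes_b],
                "resolved_b": list(genes_b),
            }
        )
    )


class TestCorrelationMatrix:
    def test_perfectly_covarying_pair(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        r, p = gene_correlation_matrix(df)
        assert r.at["a", "b"] == pytest.approx(1.0)
        assert p.at["a", "b"] == pytest.approx(0.0)

    def test_exactly_uncorrelated_pair_has_p_one(self):
        n = 20
        x = np.arange(n, dtype=float)
        y = np.zeros(n)
        y[::2], y[1::2] = 1.0, -1.0
        y -= y.mean()
        y -= (np.corrcoef(x, y)[0, 1] * y.std() / x.std()) * 0  # x,y constructed orthogonal
        x2 = x - x.mean()
        y = y - (y @ x2) / (x2 @ x2) * x2  # project out any residual
        df = pd.DataFrame({"a": x, "b": y})
        r, p = gene_correlation_matrix(df)
        assert abs(r.at["a", "b"]) < 1e-12
        assert p.at["a", "b"] == pytest.approx(1.0)

    def test_p_matches_closed_form_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        y = 0.7 * x + rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": y})
        r, p = gene_correlation_matrix(df)
        robs = r.at["a", "b"]
        t = robs * math.sqrt((10 - 2) / (1 - robs**2))
        expected = 2 * stats.t.sf(abs(t), df=8)
        assert p.at["a", "b"] == pytest.approx(expected, abs=1e-10)
        # and against scipy's independent implementation
        assert p.at["a", "b"] == pytest.approx(stats.pearsonr(x, y).pvalue, abs=1e-10)

    def test_constant_gene_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            r, p = gene_correlation_matrix(df)
        assert np.isnan(r.at["a", "b"])
        assert r.at["b", "b"] == 1.0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            gene_correlation_matrix(pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]}))


class TestResolveOrthologs:
    def test_single_candidate_kept(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(20, 3)), columns=["x", "y", "z"])
        b = pd.DataFrame(rng.normal(size=(20, 3)), columns=["mx", "my", "mz"])
        ca, _ = gene_correlation_matrix(a)
        cb, _ = gene_correlation_matrix(b)
        orth = _identity_orthology(["x", "y", "z"], ["mx", "my", "mz"])
        resolved = resolve_orthologs(ca, cb, orth)
        assert resolved.resolved("x") == "mx"

    def test_identical_profile_beats_uncorrelated_candidate(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(40, 4))
        a = pd.DataFrame(base, columns=["g1", "g2", "g3", "g4"])
        # species B mirrors A exactly, plus a decoy candidate of pure noise
        b = pd.DataFrame(
            np.column_stack([base, rng.normal(size=40)]),
            columns=["m1", "m2", "m3", "m4", "decoy"],
        )
        ca, _ = gene_correlation_matrix(a)
        cb, _ = gene_correlation_matrix(b)
        rows = pd.DataFrame(
            {
                "gene_a": ["g1", "g2", "g3", "g4"],
                "candidates_b": [["decoy", "m1"], ["m2"], ["m3"], ["m4"]],
                "resolved_b": None,
            }
        )
        resolved = resolve_orthologs(ca, cb, OrthologyMap(rows=rows))
        assert resolved.resolved("g1") == "m1"

    def test_matches_exhaustive_candidate_oracle(self):
        cfg = SimConfig(seed=5, n_markers=16, n_modules=2, genes_per_module=4,
                        multi_candidate_fraction=0.5, n_cells_a=50, n_cells_b=50)
        a, b, orth, truth = generate_two_species(cfg)
        ca, _ = gene_correlation_matrix(a.values)
        cb, _ = gene_correlation_matrix(b.values)
        resolved = resolve_orthologs(ca, cb, orth)
        anchors = [
            (row["gene_a"], row["candidates_b"][0])
            for _, row in orth.rows.iterrows()
            if len(row["candidates_b"]) == 1
        ]
        for _, row in orth.rows.iterrows():
            if len(row["candidates_b"]) == 1:
                continue
            gene_a = row["gene_a"]
            pos_a = [g for g, _ in anchors if g != gene_a]
            pos_b = [m for g, m in anchors if g != gene_a]
            prof_a = ca.loc[gene_a, pos_a].to_numpy()
            scored = []
            for cand in row["candidates_b"]:
                prof_b = cb.loc[cand, pos_b].to_numpy()
                p = stats.pearsonr(prof_a, prof_b).pvalue
                scored.append((p, cand))
            assert resolved.resolved(gene_a) == min(scored)[1]

    def test_absent_candidates_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
        b = pd.DataFrame(rng.normal(size=(10, 2)), columns=["mx", "my"])
        ca, _ = gene_correlation_matrix(a)
        cb, _ = gene_correlation_matrix(b)
        rows = pd.DataFrame(
            {"gene_a": ["x", "y"], "candidates_b": [["mx"], ["ghost"]], "resolved_b": None}
        )
        with pytest.warns(UserWarning, match="ghost"):
            resolved = resolve_orthologs(ca, cb, OrthologyMap(rows=rows))
        assert resolved.genes_a == ["x"]


class TestGlobalCorrelation:
    def test_identical_matrices_give_one(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(size=(30, 5))
        a = pd.DataFrame(arr, columns=list("abcde"))
        b = pd.DataFrame(arr, columns=["ma", "mb", "mc", "md", "me"])
        ca, _ = gene_correlation_matrix(a)
        cb, _ = gene_correlation_matrix(b)
        orth = _identity_orthology(list("abcde"), ["ma", "mb", "mc", "md", "me"])
        r, p = global_cross_species_correlation(ca, cb, orth)
        assert r == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        hits = 0
        genes_a = [f"a{i}" for i in range(50)]
        genes_b = [f"b{i}" for i in range(50)]
        orth = _identity_orthology(genes_a, genes_b)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ca, _ = gene_correlation_matrix(
                pd.DataFrame(rng.normal(size=(40, 50)), columns=genes_a)
            )
            cb, _ = gene_correlation_matrix(
                pd.DataFrame(rng.normal(size=(40, 50)), columns=genes_b)
            )
            r, _ = global_cross_species_correlation(ca, cb, orth)
            hits += abs(r) < 0.1
        assert hits >= 95

    def test_symmetric_under_species_swap(self):
        cfg = SimConfig(seed=9, n_markers=12, n_modules=2, genes_per_module=3,
                        multi_candidate_fraction=0.0)
        a, b, orth, _ = generate_two_species(cfg)
        ca, _ = gene_correlation_matrix(a.values)
        cb, _ = gene_correlation_matrix(b.values)
        fwd = _identity_orthology(
            list(orth.rows["gene_a"]), [c[0] for c in orth.rows["candidates_b"]]
        )
        rev = _identity_orthology(
            [c[0] for c in orth.rows["candidates_b"]], list(orth.rows["gene_a"])
        )
        r_ab, _ = global_cross_species_correlation(ca, cb, fwd)
        r_ba, _ = global_cross_species_correlation(cb, ca, rev)
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_too_few_entries_undefined(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)), columns=["a", "b"])
        ca, _ = gene_correlation_matrix(df)
        orth = _identity_orthology(["a", "b"], ["a", "b"])
        r, p = global_cross_species_correlation(ca, ca, orth)
        assert r is None and p is None


class TestPermutationScheme:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=0, n_markers=8, n_modules=0, multi_candidate_fraction=0.0,
                        n_cells_a=20, n_cells_b=20)
        a, b, orth, _ = generate_two_species(cfg)
        orth = resolve_orthologs(*[gene_correlation_matrix(m.values)[0] for m in (a, b)], orth)
        n1 = permutation_scheme(a.values, b.values, orth, n_perm=1, seed=13)
        n2 = permutation_scheme(a.values, b.values, orth, n_perm=1, seed=13)
        assert n1.null_global_r[0] == n2.null_global_r[0]
        np.testing.assert_array_equal(n1.null_pair_p_a, n2.null_pair_p_a)

    def test_null_mean_near_zero(self):
        cfg = SimConfig(seed=1, n_markers=15, n_modules=0, multi_candidate_fraction=0.0,
                        n_cells_a=40, n_cells_b=40)
        a, b, orth, _ = generate_two_species(cfg)
        orth = resolve_orthologs(*[gene_correlation_matrix(m.values)[0] for m in (a, b)], orth)
        null = permutation_scheme(a.values, b.values, orth, n_perm=200, seed=2)
        se = null.null_global_r.std(ddof=1) / math.sqrt(200)
        assert abs(null.null_global_r.mean()) < 2 * se + 1e-3

    def test_empirical_p_floor(self):
        cfg = SimConfig(seed=2, n_markers=10, n_modules=2, genes_per_module=5,
                        module_strength=0.95, multi_candidate_fraction=0.0)
        a, b, orth, _ = generate_two_species(cfg)
        ca, _ = gene_correlation_matrix(a.values)
        cb, _ = gene_correlation_matrix(b.values)
        orth = resolve_orthologs(ca, cb, orth)
        r, _ = global_cross_species_correlation(ca, cb, orth)
        null = permutation_scheme(a.values, b.values, orth, n_perm=100, seed=3)
        p = empirical_global_p(r, null)
        assert p == pytest.approx(1 / 101)  # observed beats every null draw


class TestMinPCorrection:
    def test_observed_above_all_null_minima_gives_one(self):
        null = np.full((50, 3), 0.2)
        corrected = corrected_pair_pvalues(np.array([0.9, 0.95, 0.99]), null)
        np.testing.assert_allclose(corrected, 1.0)

    def test_zero_observed_p_attains_floor(self):
        null = np.random.default_rng(0).uniform(0.01, 1, size=(200, 4))
        corrected = corrected_pair_pvalues(np.array([0.0, 0.5, 0.5, 0.5]), null)
        assert corrected[0] == pytest.approx(1 / 201)

    def test_hand_built_null_table(self):
        # 3 replicates x 5 pairs; count replicates whose min-p <= observed
        null = np.array(
            [
                [0.50, 0.30, 0.90, 0.70, 0.10],  # min 0.10
                [0.20, 0.80, 0.40, 0.60, 0.35],  # min 0.20
                [0.05, 0.95, 0.55, 0.45, 0.65],  # min 0.05
            ]
        )
        observed = np.array([0.08, 0.15, 0.25, 0.5, 1.0])
        corrected = corrected_pair_pvalues(observed, null)
        np.testing.assert_allclose(corrected, [(1 + 1) / 4, (1 + 2) / 4, 1.0, 1.0, 1.0])

    def test_never_below_raw_empirical_p(self):
        rng = np.random.default_rng(5)
        null = rng.uniform(size=(300, 8))
        observed = rng.uniform(size=8)
        corrected = corrected_pair_pvalues(observed, null)
        raw = (1 + (null <= observed[None, :]).sum(axis=0)) / 301
        assert (corrected >= raw - 1e-12).all()

    def test_step_down_bounded_by_single_step(self):
        rng = np.random.default_rng(6)
        null = rng.uniform(size=(200, 6))
        observed = rng.uniform(0, 0.3, size=6)
        single = corrected_pair_pvalues(observed, null, method="single-step")
        down = corrected_pair_pvalues(observed, null, method="step-down")
        assert (down <= single + 1e-12).all()
        order = np.argsort(observed)
        assert (np.diff(down[order]) >= -1e-12).all()  # monotone in observed p


class TestFisher:
    def test_diagonal_table(self):
        a = [1] * 5 + [0] * 5
        b = [1] * 5 + [0] * 5
        assert presence_absence_fisher(a, b) == pytest.approx(2 / 252)

    def test_balanced_independent_pattern(self):
        a = [1, 1, 0, 0] * 5
        b = [1, 0, 1, 0] * 5
        assert presence_absence_fisher(a, b) == pytest.approx(1.0)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert presence_absence_fisher([1, 1, 1], [1, 0, 1]) == 1.0

    def test_matches_hypergeometric_enumeration(self):
        # every non-degenerate 2x2 table with margins <= 6 (unit-test sweep;
        # the full <= 8 sweep runs in the acceptance suite)
        for a in range(7):
            for b in range(7 - a):
                for c in range(7 - a):
                    for d in range(7 - max(b, c)):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        vec_a = [1] * (a + b) + [0] * (c + d)
                        vec_b = [1] * a + [0] * b + [1] * c + [0] * d
                        expected = _fisher_oracle(a, b, c, d)
                        got = presence_absence_fisher(vec_a, vec_b, threshold=0.5)
                        assert got == pytest.approx(expected, abs=1e-12), (a, b, c, d)


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration (math.comb)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestCompareSpecies:
    def test_planted_modules_detected(self):
        cfg = SimConfig(seed=11, n_markers=18, n_modules=3, genes_per_module=4,
                        module_strength=0.9, multi_candidate_fraction=0.25)
        a, b, orth, truth = generate_two_species(cfg)
        res = compare_species(a, b, orth, n_perm=300, seed=0,
                              compute_fisher=False, compute_mic=False)
        assert res.global_p_empirical < 0.01
        sig = {
            (r.gene_a_i, r.gene_a_j) for r in res.pairs.itertuples() if r.significant_in_both
        }
        recovered = len(sig & truth.module_pairs) / len(truth.module_pairs)
        assert recovered >= 0.9
        non_module = [
            (r.gene_a_i, r.gene_a_j)
            for r in res.pairs.itertuples()
            if (r.gene_a_i, r.gene_a_j) not in truth.module_pairs
        ]
        false_rate = sum((p in sig) for p in non_module) / len(non_module)
        assert false_rate <= 0.05

    def test_result_invariants(self):
        cfg = SimConfig(seed=12, n_markers=10, n_modules=1, genes_per_module=4,
                        multi_candidate_fraction=0.0, n_cells_a=30, n_cells_b=30)
        a, b, orth, _ = generate_two_species(cfg)
        res = compare_species(a, b, orth, n_perm=100, seed=1,
                              compute_fisher=True, compute_mic=False)
        assert res.global_p_empirical >= 1 / 101
        assert (res.pairs["p_corr_a"] >= res.pairs["p_raw_a"] - 1e-12).all()
        np.testing.assert_allclose(res.corr_a, res.corr_a.T)
        np.testing.assert_allclose(np.diag(res.corr_a), 1.0)
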