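"""Co-expression chain: preprocessing, TOM, modules, eigen-taxa, MS/TM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from biocharnet import wgcna
from biocharnet.wgcna import (
    ModuleAssignment,
    WGCNAConfig,
    WGCNAError,
    adjacency,
    adjacency_tom,
    classify_role,
    compute_ms_tm,
    correlation_t_pvalue,
    detect_modules,
    hub_genera,
    merge_modules,
    module_eigentaxon,
    module_trait_correlation,
    pick_soft_threshold,
    preprocess,
    scale_free_fit,
)


def block_matrix(blocks, n_samples=20, noise=0.0, seed=0):
    """Standardised profiles in perfectly correlated blocks (plus noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for size in blocks:
        base = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(base + rng.normal(0, noise, n_samples))
    x = np.asarray(rows)
    x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
    return pd.DataFrame(x, index=[f"O{i}" for i in range(len(rows))])


def brute_force_tom(adj):
    """Naive O(n^3) topological overlap for cross-checking."""
    n = adj.shape[0]
    k = adj.sum(axis=1)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(
                adj[i, u] * adj[u, j] for u in range(n) if u not in (i, j)
            )
            tom[i, j] = (shared + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


class TestPreprocess:
    def test_rows_standardised(self, default_community):
        matrix, _ = preprocess(default_community.table)
        assert np.allclose(matrix.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(matrix.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_outlier_sample_flagged(self, default_community):
        table = default_community.table
        counts = table.counts.copy()
        # one sample made wildly unlike the rest
        counts["AB9"] = 0
        counts.loc[counts.index[:3], "AB9"] = [10**5, 10**5, 10**5]
        from biocharnet.community import OTUTable

        t = OTUTable(counts, table.taxonomy, table.treatments)
        cfg = WGCNAConfig(outlier_cut_height=60.0)
        matrix, report = preprocess(t, cfg)
        assert report["dropped_samples"] == ["AB9"]
        assert "AB9" not in matrix.columns

    def test_no_cut_keeps_all_samples(self, default_community):
        matrix, report = preprocess(default_community.table, WGCNAConfig())
        assert report["dropped_samples"] == []
        assert matrix.shape[1] == 18


class TestSoftThreshold:
    def test_power_one_adjacency_is_absolute_correlation(self):
        m = block_matrix([4, 4], noise=0.5)
        adj = adjacency(m, beta=1)
        expected = np.abs(np.corrcoef(m.to_numpy()))
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(adj, expected)

    def test_mean_connectivity_decreases_with_power(self):
        m = block_matrix([5, 5, 5], noise=0.8, seed=2)
        _, tab = pick_soft_threshold(m, WGCNAConfig(powers=tuple(range(1, 10))))
        k = tab["mean_connectivity"].to_numpy()
        assert np.all(np.diff(k) < 0)

    def test_planted_power_law_degree_sequence_fits_well(self):
        # degrees drawn from p(k) ~ k^-2 give a high scale-free fit index
        rng = np.random.default_rng(1)
        k = (1.0 / rng.uniform(1e-3, 1.0, 3000))  # pareto-ish heavy tail
        k = k[k < 1e4]
        fit, slope = scale_free_fit(k)
        assert fit > 0.9
        assert slope < 0


class TestTOM:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(3, 9)
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            assert np.allclose(adjacency_tom(a), brute_force_tom(a), atol=1e-12)

    def test_identical_neighbourhoods_give_unit_overlap(self):
        # two nodes fully connected to each other and to all others
        n = 5
        a = np.full((n, n), 1.0)
        np.fill_diagonal(a, 0.0)
        tom = adjacency_tom(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_disconnected_cliques_have_zero_cross_overlap(self):
        a = np.zeros((6, 6))
        for blk in (slice(0, 3), slice(3, 6)):
            a[blk, blk] = 0.9
        np.fill_diagonal(a, 0.0)
        tom = adjacency_tom(a)
        assert np.allclose(tom[:3, 3:], 0.0)

    def test_symmetric_unit_diagonal_in_unit_interval(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = adjacency_tom(a)
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert ((tom >= 0) & (tom <= 1)).all()


class TestDetectModules:
    def test_two_planted_blocks_found_exactly(self):
        m = block_matrix([10, 10], noise=0.01, seed=1)
        tom = adjacency_tom(adjacency(m, 6))
        assignment = detect_modules(tom, WGCNAConfig(), otu_ids=list(m.index))
        assert len(assignment.modules) == 2
        labels = assignment.labels.to_numpy()
        assert adjusted_rand_score([0] * 10 + [1] * 10, labels) == pytest.approx(1.0)

    def test_min_module_size_larger_than_any_branch_gives_all_grey(self):
        m = block_matrix([4, 4], noise=0.01, seed=1)
        tom = adjacency_tom(adjacency(m, 6))
        assignment = detect_modules(
            tom, WGCNAConfig(min_module_size=6), otu_ids=list(m.index)
        )
        assert assignment.modules == []

    def test_min_module_size_exceeding_n_rejected(self):
        tom = np.eye(4)
        with pytest.raises(WGCNAError):
            detect_modules(tom, WGCNAConfig(min_module_size=5))

    def test_labels_invariant_under_row_permutation(self, default_community):
        comm = default_community
        matrix, _ = preprocess(comm.table)
        tom = adjacency_tom(adjacency(matrix, 6))
        a1 = detect_modules(tom, otu_ids=list(matrix.index))
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.shape[0])
        tom_p = tom[np.ix_(perm, perm)]
        a2 = detect_modules(tom_p, otu_ids=[matrix.index[i] for i in perm])
        merged = pd.concat(
            [a1.labels.rename("a"), a2.labels.rename("b")], axis=1
        )
        assert adjusted_rand_score(merged["a"], merged["b"]) == pytest.approx(1.0)


class TestEigentaxon:
    def test_module_of_identical_profiles_returns_that_profile(self):
        m = block_matrix([5], noise=0.0, seed=4)
        assignment = ModuleAssignment(
            labels=pd.Series([1] * 5, index=m.index)
        )
        assignment = module_eigentaxon(m, assignment)
        e = assignment.eigentaxa[1].to_numpy()
        profile = m.iloc[0].to_numpy()
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(e, profile)[0, 1] > 0

    def test_sign_oriented_toward_mean_profile(self):
        m = block_matrix([6], noise=0.2, seed=5)
        neg = -m
        for mat in (m, neg):
            assignment = module_eigentaxon(
                mat, ModuleAssignment(labels=pd.Series([1] * 6, index=mat.index))
            )
            r = np.corrcoef(
                assignment.eigentaxa[1], mat.mean(axis=0)
            )[0, 1]
            assert r > 0

    def test_explained_variance_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(3, 12)))
        m = (m - m.mean(1).to_numpy()[:, None]) / m.std(1, ddof=1).to_numpy()[:, None]
        assignment = module_eigentaxon(
            m, ModuleAssignment(labels=pd.Series([1, 1, 1], index=m.index))
        )
        cov = m.to_numpy() @ m.to_numpy().T
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert assignment.explained[1] == pytest.approx(eig[0] / eig.sum())


class TestMergeModules:
    def _two_module_matrix(self, rho, seed=0):
        """Two 6-OTU blocks whose underlying factors correlate at rho."""
        rng = np.random.default_rng(seed)
        n = 20
        a = rng.normal(size=n)
        b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=n)
        rows = [a + rng.normal(0, 0.05, n) for _ in range(6)]
        rows += [b + rng.normal(0, 0.05, n) for _ in range(6)]
        x = np.asarray(rows)
        x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        m = pd.DataFrame(x, index=[f"O{i}" for i in range(12)])
        labels = pd.Series([1] * 6 + [2] * 6, index=m.index)
        return m, ModuleAssignment(labels=labels)

    def test_highly_correlated_modules_merge(self):
        m, assignment = self._two_module_matrix(rho=0.9)
        merged = merge_modules(m, assignment, 0.25)
        assert len(merged.modules) == 1

    def test_weakly_correlated_modules_stay_separate(self):
        m, assignment = self._two_module_matrix(rho=0.5)
        merged = merge_modules(m, assignment, 0.25)
        assert len(merged.modules) == 2

    def test_chain_merge_matches_manual_dendrogram(self):
        # three factors with pairwise correlations ~(0.85, 0.85, 0.72):
        # average linkage merges all three below 0.25 only after the first
        # pair joins; manual expectation: single module
        rng = np.random.default_rng(2)
        n = 40
        a = rng.normal(size=n)
        b = 0.85 * a + np.sqrt(1 - 0.85**2) * rng.normal(size=n)
        c = 0.85 * b + np.sqrt(1 - 0.85**2) * rng.normal(size=n)
        rows = []
        for f in (a, b, c):
            rows += [f + rng.normal(0, 0.02, n) for _ in range(5)]
        x = np.asarray(rows)
        x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        m = pd.DataFrame(x, index=[f"O{i}" for i in range(15)])
        assignment = ModuleAssignment(
            labels=pd.Series([1] * 5 + [2] * 5 + [3] * 5, index=m.index)
        )
        merged = merge_modules(m, assignment, 0.25)
        # manual: eigentaxa correlations all above 0.7, so average-linkage
        # heights fall below 0.25 in one or two rounds -> single module
        assert len(merged.modules) == 1


class TestModuleTrait:
    def test_trait_equal_to_eigentaxon_gives_unit_correlation(self):
        m = block_matrix([6], noise=0.3, seed=7)
        assignment = module_eigentaxon(
            m, ModuleAssignment(labels=pd.Series([1] * 6, index=m.index))
        )
        trait = pd.Series(assignment.eigentaxa[1].to_numpy(), index=m.columns)
        res = module_trait_correlation(assignment, trait)
        assert res.table.loc[1, "r"] == pytest.approx(1.0)
        assert res.table.loc[1, "p"] < 1e-10
        assert res.keystone == 1 and res.significant

    def test_negated_trait_gives_negative_correlation(self):
        m = block_matrix([6], noise=0.3, seed=8)
        assignment = module_eigentaxon(
            m, ModuleAssignment(labels=pd.Series([1] * 6, index=m.index))
        )
        rng = np.random.default_rng(0)
        trait = pd.Series(
            -assignment.eigentaxa[1].to_numpy() + rng.normal(0, 0.05, m.shape[1]),
            index=m.columns,
        )
        res = module_trait_correlation(assignment, trait)
        assert res.table.loc[1, "r"] < -0.95

    def test_constant_trait_rejected(self):
        m = block_matrix([6], noise=0.3, seed=9)
        assignment = module_eigentaxon(
            m, ModuleAssignment(labels=pd.Series([1] * 6, index=m.index))
        )
        with pytest.raises(WGCNAError):
            module_trait_correlation(
                assignment, pd.Series(1.0, index=m.columns)
            )

    def test_published_correlation_p_value_reproduced(self):
        """r = -0.520 with 18 samples gives a two-sided t-test p of 0.027."""
        assert correlation_t_pvalue(-0.520, 18) == pytest.approx(0.027, abs=5e-4)


class TestMSTM:
    @settings(max_examples=300, derandomize=True)
    @given(
        ms=st.floats(0, 1),
        tm=st.floats(-1, 1),
    )
    def test_role_rule_is_pure_four_way_partition(self, ms, tm):
        role = classify_role(ms, tm)
        expected = (
            "hub" if (ms >= 0.6 and abs(tm) >= 0.9)
            else "taxon_hub" if abs(tm) >= 0.9
            else "connector" if ms >= 0.6
            else "peripheral"
        )
        assert role == expected

    def test_self_module_trait_is_hub(self):
        m = block_matrix([5], noise=0.0, seed=10)
        assignment = module_eigentaxon(
            m, ModuleAssignment(labels=pd.Series([1] * 5, index=m.index))
        )
        trait = pd.Series(m.iloc[0].to_numpy(), index=m.columns)
        rec = compute_ms_tm(m, assignment, trait, 1)
        assert (rec["role"] == "hub").all()
        assert np.allclose(rec["MS"], 1.0) and np.allclose(rec["TM"], 1.0)

    def test_records_match_independent_correlations(self, default_community,
                                                    wgcna_result):
        res = wgcna_result
        comm = default_community
        key = res.module_trait.keystone
        trait = comm.trait.reindex(res.matrix.columns)
        e = res.assignment.eigentaxa[key]
        for otu in res.assignment.members(key):
            x = res.matrix.loc[otu]
            ms = abs(np.corrcoef(x, trait)[0, 1])
            tm = np.corrcoef(x, e)[0, 1]
            assert res.ms_tm.loc[otu, "MS"] == pytest.approx(ms, abs=1e-10)
            assert res.ms_tm.loc[otu, "TM"] == pytest.approx(tm, abs=1e-10)
            assert res.ms_tm.loc[otu, "role"] == classify_role(ms, tm)


class TestHubGenera:
    def test_single_hub_otu_lifts_to_its_genus(self):
        records = pd.DataFrame(
            {"MS": [0.9, 0.3], "TM": [0.95, 0.2],
             "role": ["hub", "peripheral"]},
            index=["O1", "O2"],
        )
        tax = pd.Series({
            "O1": "k__Bacteria;g__Devosia;s__",
            "O2": "k__Bacteria;g__Massilia;s__",
        })
        out = hub_genera(records, tax)
        assert list(out.index) == ["Devosia"]

    def test_no_hub_otus_gives_empty_list(self):
        records = pd.DataFrame(
            {"MS": [0.3], "TM": [0.2], "role": ["peripheral"]}, index=["O1"]
        )
        out = hub_genera(records, pd.Series({"O1": "g__X"}))
        assert out.empty

    def test_planted_hub_genera_recovered_without_false_positives(self):
        """Both planted hub genera recovered, no spurious genus, in at least
        18 of 20 seeded replicates of the default community."""
        from biocharnet.synthgen import CommunityConfig, gen_community
        from biocharnet.wgcna import run_wgcna

        successes = 0
        for seed in range(20):
            comm = gen_community(CommunityConfig(seed=seed))
            res = run_wgcna(comm.table, comm.trait, WGCNAConfig(), power=6)
            found = set(res.hub_genera.index)
            successes += found == {"Devosia", "Nocardioides"}
        assert successes >= 18
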