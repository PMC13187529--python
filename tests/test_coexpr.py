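"""Transcriptomic stage: normalization, DE, WGCNA-core, screens, sets."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_tom

from omicsmr import synthdata
from omicsmr.coexpr import (
    adjacency_matrix,
    adjust_batch,
    detect_modules,
    differential_expression,
    gene_significance_membership,
    intersect_gene_sets,
    module_eigengenes,
    module_trait_stats,
    pick_soft_threshold,
    quantile_normalize,
    scale_free_fit,
    spearman_screen,
    tom_similarity,
)


def frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


def sheet(groups, batches=None):
    n = len(groups)
    return pd.DataFrame(
        {
            "sample": [f"s{j}" for j in range(n)],
            "group": groups,
            "batch": batches or ["B1"] * n,
        }
    )


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = frame(np.column_stack([[1.0, 5.0, 9.0]] * 3))
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_mean_order_statistics(self):
        m = frame(np.column_stack([[1, 2, 3], [10, 20, 30]]))
        out = quantile_normalize(m)
        expected = np.column_stack([[5.5, 11, 16.5]] * 2)
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_ties_receive_average_target(self):
        m = frame(np.column_stack([[1.0, 1.0, 1.0], [2.0, 4.0, 6.0]]))
        out = quantile_normalize(m)
        # reference profile = (1.5, 2.5, 3.5); tied column sits at mid rank
        np.testing.assert_allclose(out.iloc[:, 0], [2.5, 2.5, 2.5])
        np.testing.assert_allclose(out.iloc[:, 1], [1.5, 2.5, 3.5])

    def test_column_distributions_identical(self, rng):
        m = frame(rng.normal(size=(50, 6)))
        out = quantile_normalize(m).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-10)


class TestAdjustBatch:
    def test_offset_batches_equalized(self, rng):
        base = rng.normal(7, 1, size=(30, 8))
        shifted = base.copy()
        shifted[:, 4:] += 3.0
        m = frame(shifted)
        s = sheet(["case"] * 4 + ["control"] * 4, ["B1"] * 4 + ["B2"] * 4)
        out = adjust_batch(m, s)
        means_b1 = out.iloc[:, :4].mean(axis=1)
        means_b2 = out.iloc[:, 4:].mean(axis=1)
        np.testing.assert_allclose(means_b1, means_b2, atol=1e-10)

    def test_single_batch_is_identity(self, rng):
        m = frame(rng.normal(size=(20, 6)))
        s = sheet(["case"] * 3 + ["control"] * 3)
        out = adjust_batch(m, s)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), atol=1e-10)

    def test_singleton_batch_rejected(self, rng):
        m = frame(rng.normal(size=(5, 3)))
        s = sheet(["case", "case", "control"], ["B1", "B1", "B2"])
        with pytest.raises(ValueError, match="single sample"):
            adjust_batch(m, s)

    def test_group_signal_survives_batch_removal(self):
        """DEGs planted orthogonally to a batch effect are still recovered."""
        matrix, samples, truth = synthdata.simulate_expression_study(
            n_genes=200, n_samples_per_group=(8, 8), n_modules=0, module_sizes=(),
            de_fraction=0.25, de_log2fc=2.0, batch_offsets=(0.0, 3.0),
            batch_scales=(1.0, 1.5), noise_sd=0.2, seed=7,
        )
        out = adjust_batch(matrix, samples)
        deg = differential_expression(out, samples)
        called = set(deg.index[deg["status"] != "ns"])
        truth_set = set(truth.de_gene_ids)
        assert len(called & truth_set) >= 0.9 * len(truth_set)


class TestDifferentialExpression:
    def test_planted_fourfold_recovered(self):
        matrix, samples, truth = synthdata.simulate_expression_study(
            n_genes=1000, n_samples_per_group=(10, 10), n_modules=0, module_sizes=(),
            de_fraction=0.05, de_log2fc=2.0, batch_offsets=(0.0,), batch_scales=(1.0,),
            noise_sd=0.2, seed=0,
        )
        deg = differential_expression(matrix, samples)
        n_called = int((deg["status"] != "ns").sum())
        assert abs(n_called - len(truth.de_gene_ids)) <= 3

    def test_exact_twofold_boundary_is_inclusive(self):
        case = np.tile([2.0, 2.1, 1.9, 2.0, 2.05, 1.95], (2, 1)) + np.array([[0.0], [0.0]])
        ctrl = case - 0.0  # same shape
        m = np.hstack([case + np.array([[1.0], [0.0]]), ctrl])
        m += np.random.default_rng(0).normal(0, 0.01, m.shape)
        # force gene 0 to exactly 2-fold
        m[0, :6] = m[0, 6:] + 1.0
        matrix = frame(m, genes=["hit", "null"], samples=[f"s{j}" for j in range(12)])
        s = sheet(["case"] * 6 + ["control"] * 6)
        deg = differential_expression(matrix, s)
        assert deg.loc["hit", "log2fc"] == pytest.approx(1.0)
        assert deg.loc["hit", "status"] == "up"

    def test_zero_variance_degenerate_rule(self):
        m = frame(
            [[1.0] * 3 + [0.0] * 3, [2.0] * 6, [0.5] * 3 + [0.4] * 3],
            genes=["diff", "same", "noisefree"],
        )
        s = sheet(["case"] * 3 + ["control"] * 3)
        with pytest.warns(UserWarning, match="zero variance"):
            deg = differential_expression(m, s)
        assert deg.loc["diff", "pval"] == 0.0
        assert deg.loc["same", "pval"] == 1.0

    def test_status_partition(self):
        matrix, samples, _ = synthdata.simulate_expression_study(seed=2)
        deg = differential_expression(adjust_batch(matrix, samples), samples)
        counts = deg["status"].value_counts()
        assert counts.sum() == len(matrix)

    def test_too_few_samples_rejected(self, rng):
        m = frame(rng.normal(size=(10, 5)))
        s = sheet(["case", "case", "control", "control", "control"])
        with pytest.raises(ValueError):
            differential_expression(m, s)


class TestSoftThreshold:
    def test_graded_network_reaches_target(self):
        matrix, *_ = synthdata.simulate_expression_study(
            **synthdata.GRADED_NETWORK_KWARGS, seed=0
        )
        table, power = pick_soft_threshold(matrix)
        fit = table.loc[table["power"] == power, "fit"].iloc[0]
        assert fit >= 0.80
        slope = table.loc[table["power"] == power, "slope"].iloc[0]
        assert slope < 0  # decaying degree distribution

    def test_uniform_correlation_scores_poorly_at_power_one(self, rng):
        # one global factor: near-uniform correlation, not scale-free
        f = rng.standard_normal(40)
        m = frame(0.9 * f + 0.3 * rng.standard_normal((60, 40)))
        cor = np.abs(np.corrcoef(m.to_numpy()))
        k = cor.sum(axis=0) - 1
        fit, _ = scale_free_fit(k)
        assert fit < 0.5

    def test_constant_connectivity_undefined(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.full(100, 3.0))

    def test_fallback_warns(self, rng):
        m = frame(rng.normal(size=(30, 10)))
        with pytest.warns(UserWarning, match="no candidate power"):
            pick_soft_threshold(m, candidate_powers=(1,), r2_target=0.999)


class TestTOM:
    def test_clique_overlap_is_one(self):
        a = np.ones((3, 3))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_empty_graph_zero_off_diagonal(self):
        a = np.eye(4)
        tom = tom_similarity(a)
        assert np.allclose(tom, np.eye(4))

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 1, (6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(tom_similarity(a), brute_tom(a), atol=1e-12)

    def test_symmetry_and_range(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(np.diag(tom), 1.0)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError):
            tom_similarity(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestDetectModules:
    def test_two_perfect_blocks(self):
        tom = np.zeros((6, 6))
        tom[:3, :3] = 1.0
        tom[3:, 3:] = 1.0
        labels = detect_modules(tom, [f"g{i}" for i in range(6)], min_module_size=2)
        parts = labels.groupby(labels).groups
        assert sorted(len(v) for v in parts.values()) == [3, 3]
        assert "grey" not in labels.values

    def test_no_structure_all_grey(self):
        tom = np.eye(5)
        labels = detect_modules(tom, list("abcde"), min_module_size=2)
        assert (labels == "grey").all()

    def test_labels_ordered_by_size(self):
        tom = np.zeros((7, 7))
        tom[:4, :4] = 1.0
        tom[4:, 4:] = 1.0
        labels = detect_modules(tom, [f"g{i}" for i in range(7)], min_module_size=2)
        assert (labels.iloc[:4] == "M1").all() and (labels.iloc[4:] == "M2").all()

    def test_gene_order_permutation_invariance(self, rng):
        matrix, *_ = synthdata.simulate_expression_study(
            **synthdata.SEPARATED_MODULE_KWARGS, seed=3
        )
        tom = tom_similarity(adjacency_matrix(matrix, 6))
        labels = detect_modules(tom, matrix.index, min_module_size=5)
        perm = rng.permutation(len(matrix))
        tom_p = tom[np.ix_(perm, perm)]
        labels_p = detect_modules(tom_p, matrix.index[perm], min_module_size=5)
        # same partition up to label names
        joined = pd.concat([labels.rename("a"), labels_p.rename("b")], axis=1)
        mapping = joined.groupby("a")["b"].nunique()
        assert (mapping == 1).all()

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        matrix, _, truth = synthdata.simulate_expression_study(
            **synthdata.SEPARATED_MODULE_KWARGS, seed=1
        )
        tom = tom_similarity(adjacency_matrix(matrix, 6))
        labels = detect_modules(tom, matrix.index, min_module_size=5)
        ari = adjusted_rand_score(
            [truth.module_assignment[g] for g in labels.index], labels.to_numpy()
        )
        assert ari >= 0.9


class TestEigengenes:
    def test_rank_one_module(self, rng):
        g = rng.standard_normal(12)
        m = frame(np.tile(g, (4, 1)) + 1e-9 * rng.standard_normal((4, 12)))
        labels = pd.Series(["M1"] * 4, index=m.index)
        eig = module_eigengenes(m, labels)
        r = np.corrcoef(eig.loc["M1"], g)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)
        assert np.linalg.norm(eig.loc["M1"]) == pytest.approx(1.0)

    def test_sign_convention_positive_on_mean_profile(self, rng):
        matrix, _, truth = synthdata.simulate_expression_study(seed=4)
        labels = pd.Series(
            {g: truth.module_assignment[g] for g in matrix.index}
        ).replace("none", "grey")
        eig = module_eigengenes(matrix, labels)
        for module in eig.index:
            genes = labels.index[labels == module]
            sub = matrix.loc[genes]
            z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
            assert np.corrcoef(eig.loc[module], z.mean(axis=0))[0, 1] > 0

    def test_zero_variance_module_rejected(self):
        m = frame(np.ones((3, 5)))
        labels = pd.Series(["M1"] * 3, index=m.index)
        with pytest.raises(ValueError, match="zero-variance"):
            module_eigengenes(m, labels)

    def test_pc1_dominates_on_planted_module(self, rng):
        f = rng.standard_normal(20)
        m = frame(0.9 * f + 0.2 * rng.standard_normal((15, 20)))
        labels = pd.Series(["M1"] * 15, index=m.index)
        eig = module_eigengenes(m, labels)
        z = m.sub(m.mean(axis=1), axis=0).div(m.std(axis=1, ddof=1), axis=0)
        _, sv, _ = np.linalg.svd(z.to_numpy(), full_matrices=False)
        assert sv[0] ** 2 / (sv**2).sum() >= 0.8


class TestModuleTrait:
    def test_perfect_correlation(self):
        trait = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        z = (trait - trait.mean()) / trait.std()
        eig = pd.DataFrame([z / np.linalg.norm(z)], index=["M1"])
        mt = module_trait_stats(eig, trait)
        assert mt.loc["M1", "cor"] == pytest.approx(1.0)

    def test_constant_trait_rejected(self):
        eig = pd.DataFrame([[0.1, 0.2, 0.3]], index=["M1"])
        with pytest.raises(ValueError):
            module_trait_stats(eig, np.ones(3))

    def test_trait_module_wins_and_gsmm_positive(self):
        matrix, samples, truth = synthdata.simulate_expression_study(seed=6)
        adjusted = adjust_batch(matrix, samples)
        labels = pd.Series(
            {g: truth.module_assignment[g] for g in matrix.index}
        ).replace("none", "grey")
        trait = (
            samples.set_index("sample").loc[matrix.columns, "group"] == "case"
        ).astype(float).to_numpy()
        eig = module_eigengenes(adjusted, labels)
        mt = module_trait_stats(eig, trait)
        assert mt["cor"].abs().idxmax() == "M1"
        gs_mm = gene_significance_membership(adjusted, eig, labels, trait)
        inside = gs_mm[gs_mm["module"] == "M1"]
        assert np.corrcoef(inside["gs"], inside["mm"])[0, 1] > 0


class TestSpearmanScreen:
    def test_monotone_transform_is_one(self, rng):
        x = rng.normal(size=20)
        m = frame(np.vstack([x, np.exp(x)]), genes=["target", "cand"])
        res = spearman_screen(m, "target", ["cand"])
        assert res.loc["cand", "rho"] == pytest.approx(1.0)
        assert res.loc["cand", "direction"] == "positive"

    def test_reversed_ranks_is_minus_one(self, rng):
        x = rng.normal(size=15)
        m = frame(np.vstack([x, -x]), genes=["target", "cand"])
        res = spearman_screen(m, "target", ["cand"])
        assert res.loc["cand", "rho"] == pytest.approx(-1.0)

    def test_ties_match_rank_formula(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 2.0, 5.0, 4.0, 4.0])
        m = frame(np.vstack([x, y]), genes=["target", "cand"])
        res = spearman_screen(m, "target", ["cand"])
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.loc["cand", "rho"] == pytest.approx(expected, abs=1e-12)

    def test_constant_target_rejected(self):
        m = frame([[1.0] * 5, [1, 2, 3, 4, 5]], genes=["target", "cand"])
        with pytest.raises(ValueError):
            spearman_screen(m, "target", ["cand"])


class TestIntersectGeneSets:
    def test_pairwise(self):
        res = intersect_gene_sets(a={"A", "B", "C"}, b={"B", "C", "D"})
        assert res.intersection == ["B", "C"]

    def test_disjoint(self):
        res = intersect_gene_sets(a={"A"}, b={"B"})
        assert res.intersection == []

    def test_three_set_venn_partitions_union(self):
        res = intersect_gene_sets(
            a={"x", "y", "z", "w"}, b={"y", "z", "q"}, c={"z", "w", "q", "r"}
        )
        union = {"x", "y", "z", "w", "q", "r"}
        assert sum(res.venn.values()) == len(union)
        assert res.venn[frozenset({"a", "b", "c"})] == 1  # only z

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            intersect_gene_sets(only={"A"})
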