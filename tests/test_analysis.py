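"""Normalization, gene selection, PC significance, clustering and the LRT."""

import numpy as np
import pandas as pd
import pytest

import spotseq as ss
from spotseq.simulate import simulate_low_rank, simulate_two_part_matrix


class TestNormalize:
    def test_prelog_scaling_arithmetic(self):
        counts = pd.DataFrame({"b1": [2, 3, 5]}, index=["g1", "g2", "g3"])
        nm = ss.normalize(counts, scale_n=10_000)
        assert nm.linear["b1"].tolist() == [2000.0, 3000.0, 5000.0]
        assert np.allclose(nm.log2["b1"], np.log2([2001, 3001, 5001]))

    def test_column_sums_equal_scale_exactly(self, clean_experiment):
        cm = clean_experiment["cm"]
        nonzero = cm.counts.loc[:, cm.counts.sum(axis=0) > 0]
        for scale in (200_000, 10_000):
            nm = ss.normalize(nonzero, scale_n=scale)
            assert np.allclose(nm.linear.sum(axis=0), scale)

    def test_idempotent_on_normalized_columns(self):
        counts = pd.DataFrame({"b1": [2, 3, 5], "b2": [1, 1, 2]})
        once = ss.normalize(counts, scale_n=10_000)
        twice = ss.normalize(once.linear, scale_n=10_000)
        assert np.allclose(once.linear, twice.linear)

    def test_all_zero_barcode_dropped_with_warning(self):
        counts = pd.DataFrame({"b1": [1, 2], "b2": [0, 0]})
        with pytest.warns(UserWarning):
            nm = ss.normalize(counts, scale_n=100)
        assert list(nm.barcodes) == ["b1"]

    def test_negative_counts_hard_error(self):
        with pytest.raises(ValueError):
            ss.normalize(pd.DataFrame({"b1": [-1, 2]}), scale_n=100)


class TestGeneSelection:
    def test_top_cv_gene_selected(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            {
                f"c{i}": [10 + rng.normal(0, 0.1), 10 + rng.normal(0, 5), 10.0]
                for i in range(30)
            },
            index=["quiet", "noisy", "flat"],
        )
        nm = ss.NormalizedMatrix(linear=mat, log2=np.log2(mat + 1), scale_n=1)
        assert ss.select_variable_genes(nm, n=1) == ["noisy"]
        assert ss.select_variable_genes(nm, n=3)[-1] == "flat"

    def test_abundance_filter_inclusive_and_centred(self):
        mat = pd.DataFrame(
            {"c1": [6.5, 6.3, 10.0], "c2": [6.5, 6.5, 12.0]},
            index=["edge", "below", "high"],
        )
        nm = ss.NormalizedMatrix(linear=mat, log2=np.log2(mat + 1), scale_n=1)
        kept, centred = ss.abundance_filter(nm, min_mean=6.5)
        assert kept == ["edge", "high"]  # mean exactly 6.5 retained, 6.4 excluded
        assert np.allclose(centred.mean(axis=1), 0.0)


class TestSignificantPcs:
    def test_planted_rank_two_recovered(self):
        x = simulate_low_rank(n_cells=80, n_genes=300, rank=2, seed=0)
        res = ss.significant_pcs(x, alpha=0.01, n_perm=100, seed=1, n_components=8)
        assert res.n_significant == 2
        assert res.p_values[0] < 0.01 and res.p_values[1] < 0.01
        assert res.p_values[2] >= 0.01

    def test_pure_noise_rarely_significant(self):
        hits = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal((60, 200))
            res = ss.significant_pcs(x, alpha=0.01, n_perm=100, seed=seed,
                                     n_components=5)
            hits.append(res.n_significant)
        assert sum(h > 0 for h in hits) <= 1

    def test_too_few_permutations_rejected(self):
        x = simulate_low_rank(n_cells=20, n_genes=30, seed=0)
        with pytest.raises(ValueError):
            ss.significant_pcs(x, alpha=0.01, n_perm=10)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            ss.significant_pcs(np.zeros((2, 10)))


class TestTsne:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((60, 5))
        a = ss.tsne_embed(scores, dims=2, n_iter=260, seed=3, perplexity=10)
        b = ss.tsne_embed(scores, dims=2, n_iter=260, seed=3, perplexity=10)
        assert a.shape == (60, 2)
        assert np.array_equal(a, b)

    def test_dims_exceeding_components_rejected(self):
        with pytest.raises(ValueError):
            ss.tsne_embed(np.zeros((50, 2)), dims=3, perplexity=5)

    def test_perplexity_too_large_rejected(self):
        with pytest.raises(ValueError):
            ss.tsne_embed(np.zeros((10, 5)), dims=2, perplexity=30)


def _naive_average_linkage_merges(dist: np.ndarray):
    """Exhaustive agglomeration oracle: returns frozensets in merge order."""
    clusters = {i: [i] for i in range(dist.shape[0])}
    merges = []
    next_id = dist.shape[0]
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a]) | frozenset(clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestHcluster:
    def test_identical_profiles_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(20)
        mat = pd.DataFrame(
            {"c1": base, "c2": base, "c3": rng.standard_normal(20)}
        )
        labels, z = ss.hcluster(mat, k=2)
        assert labels["c1"] == labels["c2"] != labels["c3"]
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_order_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.standard_normal((15, 5)),
                           columns=[f"c{i}" for i in range(5)])
        corr = np.corrcoef(mat.to_numpy(), rowvar=False)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        oracle = _naive_average_linkage_merges(dist)
        _, z = ss.hcluster(mat)
        # rebuild membership sets from the scipy linkage encoding
        members = {i: frozenset([i]) for i in range(5)}
        for step, (row, (oracle_set, oracle_d)) in enumerate(zip(z, oracle)):
            merged = members[int(row[0])] | members[int(row[1])]
            members[5 + step] = merged
            assert merged == oracle_set
            assert row[2] == pytest.approx(oracle_d, abs=1e-10)

    def test_separated_programs_recovered(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(30)
        b = rng.standard_normal(30)
        cols = {}
        for i in range(10):
            cols[f"a{i}"] = a + rng.normal(0, 0.3, 30)
        for i in range(10):
            cols[f"b{i}"] = b + rng.normal(0, 0.3, 30)
        labels, _ = ss.hcluster(pd.DataFrame(cols), k=2)
        a_labels = {labels[f"a{i}"] for i in range(10)}
        b_labels = {labels[f"b{i}"] for i in range(10)}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_zero_variance_cell_excluded(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(
            {"c1": rng.standard_normal(10), "c2": rng.standard_normal(10),
             "dead": np.ones(10)}
        )
        with pytest.warns(UserWarning):
            labels, _ = ss.hcluster(mat, k=2)
        assert labels["dead"] == -1


class TestLrtDe:
    def test_identical_clusters_give_stat_zero(self):
        values = [0.0, 2.0, 3.0, 0.0, 2.0, 3.0]
        mat = pd.DataFrame([values], index=["g1"],
                           columns=[f"c{i}" for i in range(6)])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=mat.columns)
        res = ss.lrt_de(mat, labels)
        assert res.table.loc["g1", "statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res.table.loc["g1", "p_value"] == pytest.approx(1.0)

    def test_all_zero_gene_excluded(self):
        mat = pd.DataFrame(
            [[0.0] * 6, [1.0, 2, 1, 2, 1, 2]], index=["dead", "alive"],
            columns=[f"c{i}" for i in range(6)],
        )
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=mat.columns)
        res = ss.lrt_de(mat, labels)
        assert "dead" not in res.table.index

    def test_null_calibration(self):
        mat, labels, _ = simulate_two_part_matrix(
            n_genes=1000, cells_per_cluster=50, seed=3
        )
        res = ss.lrt_de(mat, labels)
        frac = float((res.table["p_value"] < 0.05).mean())
        sd = np.sqrt(0.05 * 0.95 / len(res.table))
        assert abs(frac - 0.05) <= 3 * sd

    def test_power_monotone_in_effect_size(self):
        powers = []
        for fold in (0.25, 0.5, 1.0):
            mat, labels, shifted = simulate_two_part_matrix(
                n_genes=300, cells_per_cluster=60, log2_fold=fold, seed=5
            )
            res = ss.lrt_de(mat, labels)
            mask = pd.Series(shifted, index=mat.index).loc[res.table.index]
            powers.append(float((res.table.loc[mask, "p_value"] < 0.05).mean()))
        assert powers[0] < powers[1] < powers[2]

    def test_detection_only_difference_found(self):
        """Genes differing only in detection probability are significant."""
        rng = np.random.default_rng(8)
        n = 80
        det_a = rng.random(n) < 0.9
        det_b = rng.random(n) < 0.3
        vals = np.clip(rng.normal(4, 1, 2 * n), 0.05, None)
        row = np.where(np.concatenate([det_a, det_b]), vals, 0.0)
        mat = pd.DataFrame([row], index=["g1"],
                           columns=[f"c{i}" for i in range(2 * n)])
        labels = pd.Series(["a"] * n + ["b"] * n, index=mat.columns)
        res = ss.lrt_de(mat, labels)
        assert res.table.loc["g1", "p_value"] < 0.001

    def test_small_cluster_rejected(self):
        mat = pd.DataFrame([[1.0, 2, 3]], index=["g1"], columns=["c0", "c1", "c2"])
        labels = pd.Series(["a", "a", "b"], index=mat.columns)
        with pytest.raises(ValueError):
            ss.lrt_de(mat, labels)


class TestTopAbundantOverlap:
    def _nm(self, mat):
        return ss.NormalizedMatrix(linear=mat, log2=np.log2(mat + 1), scale_n=1)

    def test_identical_groups_fully_shared(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((30, 4)) + 1,
                           index=[f"g{i}" for i in range(30)])
        out = ss.top_abundant_overlap({"a": self._nm(mat), "b": self._nm(mat)},
                                      top_n=10)
        assert out["shared_all"] == 10
        assert out["exclusive"] == {"a": 0, "b": 0}

    def test_disjoint_programs_fully_exclusive(self):
        genes = [f"g{i}" for i in range(20)]
        a = pd.DataFrame(0.0, index=genes, columns=["c1"])
        b = a.copy()
        a.iloc[:10] = 100.0
        b.iloc[10:] = 100.0
        out = ss.top_abundant_overlap({"a": self._nm(a), "b": self._nm(b)}, top_n=10)
        assert out["exclusive"] == {"a": 10, "b": 10}
        assert out["pairwise"][("a", "b")] == 0


@pytest.fixture(scope="module")
def matrix_and_annotations():
    genes = ["HU-BCYRN1", "HU-MT01", "HU-G0001"]
    mat = pd.DataFrame(np.ones((3, 2)), index=genes, columns=["c1", "c2"])
    annot = pd.DataFrame(
        {"is_mito": [False, True, False]}, index=pd.Index(genes, name="gene_id")
    )
    return mat, annot


class TestRemoveNamedBackgroundGenes:
    def test_named_gene_removed_mito_exempt(self, matrix_and_annotations):
        mat, annot = matrix_and_annotations
        out = ss.remove_named_background_genes(mat, names={"BCYRN1"},
                                               annotations=annot)
        assert list(out.index) == ["HU-MT01", "HU-G0001"]

    def test_include_mito_removes_flagged(self, matrix_and_annotations):
        mat, annot = matrix_and_annotations
        out = ss.remove_named_background_genes(
            mat, names={"BCYRN1"}, include_mito=True, annotations=annot
        )
        assert list(out.index) == ["HU-G0001"]

    def test_absent_name_warns_only(self, matrix_and_annotations):
        mat, annot = matrix_and_annotations
        with pytest.warns(UserWarning):
            out = ss.remove_named_background_genes(mat, names={"NOSUCH"})
        assert out.equals(mat)
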