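from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from drugseq.profiling import (
    DEFormatError,
    DETable,
    DesignError,
    build_feature_matrix,
    embed_tsne,
    hierarchical_cluster,
    internal_de,
    quantile_normalize,
    read_de_table,
    select_candidates,
    select_potent,
    significant_genes,
    size_factors,
    write_de_table,
)

from conftest import make_count_matrix


def nb_counts(rng, means, dispersion, n):
    """n samples x genes negative binomial draws."""
    means = np.asarray(means, dtype=float)
    out = np.empty((n, len(means)), dtype=np.int64)
    for i in range(n):
        lam = rng.gamma(1.0 / dispersion, means * dispersion)
        out[i] = rng.poisson(lam)
    return out


def de_from_values(genes, log2fc, padj, treatment="cmp"):
    return DETable(
        pd.DataFrame({"log2fc": log2fc, "padj": padj, "base_mean": 100.0},
                     index=pd.Index(genes, name="gene")),
        treatment=treatment,
    )


@pytest.fixture(scope="module")
def null_matrix():
    rng = np.random.default_rng(42)
    means = rng.lognormal(4, 1, 2000)
    counts = nb_counts(rng, means, 0.05, 6)
    dense = pd.DataFrame(counts, index=[f"W{i}" for i in range(6)],
                         columns=[f"g{i}" for i in range(2000)])
    return make_count_matrix(dense)


class TestInternalDE:
    def test_null_calibration_bh(self, null_matrix):
        # all 20 balanced 3v3 label splits of 6 identically distributed
        # wells: average fraction of padj < 0.05 stays at or below 0.05
        wells = list(null_matrix.wells.index)
        fracs = []
        for group in combinations(wells, 3):
            rest = [w for w in wells if w not in group]
            det = internal_de(null_matrix, list(group), rest)
            padj = det.table["padj"].dropna()
            fracs.append((padj < 0.05).mean())
        assert len(fracs) == 20
        assert np.mean(fracs) <= 0.05

    def test_planted_lfc_recovery(self):
        # well-to-well variability of plate replicates at adequate depth:
        # near-Poisson counts (dispersion 0.005, ~7% extra CV), mean ~400
        rng = np.random.default_rng(7)
        n_genes, n_planted = 2000, 100
        means = rng.lognormal(6, 0.5, n_genes)
        treat_means = means.copy()
        treat_means[:n_planted] *= 4.0  # true log2FC = 2
        control = nb_counts(rng, means, 0.005, 3)
        treated = nb_counts(rng, treat_means, 0.005, 3)
        dense = pd.DataFrame(
            np.vstack([treated, control]),
            index=["T1", "T2", "T3", "C1", "C2", "C3"],
            columns=[f"g{i}" for i in range(n_genes)],
        )
        cm = make_count_matrix(dense)
        det = internal_de(cm, ["T1", "T2", "T3"], ["C1", "C2", "C3"])
        # estimated log2FC within +/-0.5 of the planted value
        est = det.table["log2fc"].iloc[:n_planted]
        assert (est - 2.0).abs().median() < 0.5
        sig = significant_genes(det, 0.05, 1.0)
        sensitivity = sum(g in sig for g in dense.columns[:n_planted]) / n_planted
        assert sensitivity >= 0.8

    def test_all_zero_gene_untested(self):
        rng = np.random.default_rng(1)
        dense = pd.DataFrame(
            nb_counts(rng, [100.0, 50.0, 0.0], 0.05, 4),
            index=["T1", "T2", "C1", "C2"],
            columns=["g1", "g2", "gz"],
        )
        dense["gz"] = 0
        det = internal_de(make_count_matrix(dense), ["T1", "T2"], ["C1", "C2"])
        assert np.isnan(det.table.loc["gz", "padj"])

    def test_small_group_rejected(self, null_matrix):
        wells = list(null_matrix.wells.index)
        with pytest.raises(DesignError):
            internal_de(null_matrix, wells[:1], wells[1:3])

    def test_size_factors_recover_depth_ratio(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(4, 1, 500)
        counts = np.vstack([rng.poisson(base), rng.poisson(3 * base)])
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(3.0, rel=0.05)


class TestDETableIO:
    def test_csv_roundtrip(self, tmp_path):
        det = de_from_values(["g1", "g2"], [1.5, -2.0], [0.01, 0.2])
        path = tmp_path / "de.csv"
        write_de_table(det, path)
        back = read_de_table(path)
        pd.testing.assert_frame_equal(back.table, det.table)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gene,log2fc\ng1,2.0\n")
        with pytest.raises(DEFormatError):
            read_de_table(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("gene,log2fc,padj\ng1,two,0.1\n")
        with pytest.raises(ValueError):
            read_de_table(path)

    def test_extra_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text("gene,log2fc,padj,stat\ng1,2.0,0.01,5.5\n")
        det = read_de_table(path)
        assert "stat" in det.table.columns

    def test_invalid_padj_rejected(self):
        with pytest.raises(DEFormatError):
            de_from_values(["g1"], [1.0], [1.5])


class TestSignificanceAndPotency:
    def test_strict_boundaries(self):
        det = de_from_values(
            ["a", "b", "c"], [1.01, 3.0, -1.2], [0.049, 0.05, 0.001]
        )
        sig = set(significant_genes(det, 0.05, 1.0))
        assert sig == {"a", "c"}  # b excluded: padj not < 0.05; c included via |lfc|

    def test_potency_strictly_more_than_cutoff(self):
        genes = [f"g{i}" for i in range(60)]
        t51 = de_from_values(genes, [2.0] * 51 + [0.0] * 9, [0.01] * 51 + [0.9] * 9)
        t50 = de_from_values(genes, [2.0] * 50 + [0.0] * 10, [0.01] * 50 + [0.9] * 10)
        potent = select_potent({"c51": t51, "c50": t50}, min_genes=50)
        assert potent == ["c51"]

    def test_simulated_potent_recovery(self):
        # 10 of 40 compounds have 80 strong target genes; only those pass
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(500)]
        tables = {}
        for i in range(40):
            lfc = rng.normal(0, 0.1, 500)
            padj = rng.uniform(0.2, 1.0, 500)
            if i < 10:
                targets = rng.choice(500, 80, replace=False)
                lfc[targets] = 2.0
                padj[targets] = 0.001
            tables[f"cmp{i:02d}"] = de_from_values(genes, lfc, padj)
        potent = set(select_potent(tables, min_genes=50))
        assert potent == {f"cmp{i:02d}" for i in range(10)}


class TestQuantileNormalize:
    def test_worked_two_column_example(self):
        df = pd.DataFrame({"c1": [5.0, 1.0], "c2": [2.0, 4.0]}, index=["g1", "g2"])
        out = quantile_normalize(df)
        assert out["c1"].tolist() == [4.5, 1.5]
        assert out["c2"].tolist() == [1.5, 4.5]

    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(df), df)

    def test_single_row_gets_row_mean(self):
        df = pd.DataFrame({"a": [2.0], "b": [6.0]})
        out = quantile_normalize(df)
        assert (out.to_numpy() == 4.0).all()

    def test_columns_share_distribution_after_normalization(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            df = pd.DataFrame(rng.normal(size=(30, 4)))
            out = quantile_normalize(df).to_numpy()
            sorted_cols = np.sort(out, axis=0)
            for j in range(1, out.shape[1]):
                assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_ties_share_their_rank_mean(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_all_nan_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            quantile_normalize(df)


class TestCandidateSelection:
    def test_under_cap_returns_all_ranked(self):
        det = de_from_values(
            [f"g{i}" for i in range(10)],
            [2.0] * 10,
            list(np.linspace(0.001, 0.04, 10)),
        )
        assert select_candidates(det, 200) == [f"g{i}" for i in range(10)]

    def test_cap_keeps_smallest_padj(self):
        rng = np.random.default_rng(3)
        n = 300
        genes = [f"g{i:03d}" for i in range(n)]
        padj = rng.uniform(0, 0.049, n)
        det = de_from_values(genes, [2.0] * n, padj)
        picked = select_candidates(det, 200)
        assert len(picked) == 200
        # brute-force: the 200 smallest padj values
        expected = set(pd.Series(padj, index=genes).nsmallest(200).index)
        assert set(picked) == expected

    def test_padj_tie_broken_by_lfc_magnitude(self):
        det = de_from_values(["a", "b"], [1.5, -3.0], [0.01, 0.01])
        assert select_candidates(det, 1) == ["b"]

    def test_candidates_subset_of_significant(self):
        rng = np.random.default_rng(8)
        det = de_from_values(
            [f"g{i}" for i in range(100)],
            rng.normal(0, 2, 100),
            rng.uniform(0, 0.2, 100),
        )
        cand = select_candidates(det, 30)
        sig = set(significant_genes(det))
        assert set(cand) <= sig and len(cand) <= 30


def moa_tables(seed=0, n_groups=3, per_group=6, n_genes=400):
    """Compound DE tables with shared target genes within each group."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    group_targets = [
        rng.choice(n_genes, 60, replace=False) for _ in range(n_groups)
    ]
    tables, groups = {}, {}
    for g in range(n_groups):
        for m in range(per_group):
            lfc = rng.normal(0, 0.2, n_genes)
            padj = rng.uniform(0.2, 1.0, n_genes)
            signs = np.where(np.arange(60) % 2 == 0, 1.0, -1.0)
            lfc[group_targets[g]] = signs * (2.0 + rng.normal(0, 0.3, 60))
            padj[group_targets[g]] = 0.001
            name = f"moa{g}_c{m}"
            tables[name] = de_from_values(genes, lfc, padj, treatment=name)
            groups[name] = g
    return tables, groups


class TestFeatureMatrix:
    def test_disjoint_lists_union(self):
        t1 = de_from_values([f"a{i}" for i in range(5)], [2.0] * 5, [0.01] * 5)
        t2 = de_from_values([f"b{i}" for i in range(5)], [2.0] * 5, [0.01] * 5)
        fm = build_feature_matrix({"c1": t1, "c2": t2}, max_genes=200)
        assert len(fm.gene_union) == 10

    def test_identical_lists_do_not_duplicate(self):
        genes = [f"g{i}" for i in range(5)]
        t1 = de_from_values(genes, [2.0] * 5, [0.01] * 5)
        t2 = de_from_values(genes, [-2.0] * 5, [0.01] * 5)
        fm = build_feature_matrix({"c1": t1, "c2": t2}, max_genes=200)
        assert len(fm.gene_union) == 5

    def test_missing_genes_imputed_as_zero(self):
        t1 = de_from_values(["a", "b"], [2.0, 2.0], [0.01, 0.01])
        t2 = de_from_values(["c", "d"], [2.0, 2.0], [0.01, 0.01])
        fm = build_feature_matrix({"c1": t1, "c2": t2}, max_genes=200, normalize=False)
        assert fm.values.loc["c", "c1"] == 0.0
        assert fm.values.loc["a", "c2"] == 0.0

    def test_moa_groups_correlate_within(self):
        tables, groups = moa_tables(seed=5)
        fm = build_feature_matrix(tables, max_genes=200)
        corr = fm.values.corr()
        within, between = [], []
        names = list(corr.index)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                (within if groups[a] == groups[b] else between).append(corr.loc[a, b])
        assert np.mean(within) > np.mean(between)


def brute_force_agglomerate(points, labels, method="complete"):
    """Independent O(n^3) agglomeration on Euclidean distances."""
    clusters = {i: (labels[i],) for i in range(len(labels))}
    coords = {i: [points[i]] for i in range(len(labels))}
    merges = []
    nxt = len(labels)
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i >= j:
                    continue
                dists = [
                    np.linalg.norm(np.asarray(p) - np.asarray(q))
                    for p in coords[i]
                    for q in coords[j]
                ]
                d = max(dists) if method == "complete" else np.mean(dists)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i] + clusters[j]), d))
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        coords[nxt] = coords.pop(i) + coords.pop(j)
        nxt += 1
    return merges


class TestHierarchicalCluster:
    def test_two_columns_merge_at_their_distance(self):
        df = pd.DataFrame({"c1": [0.0, 0.0], "c2": [3.0, 4.0]})
        dend = hierarchical_cluster(df, linkage="complete")
        assert dend.linkage[0, 2] == pytest.approx(5.0)

    def test_identical_pair_merges_first_at_zero(self):
        df = pd.DataFrame({"c1": [1.0, 2.0], "c2": [5.0, 5.0], "c3": [1.0, 2.0]})
        dend = hierarchical_cluster(df)
        first = sorted(dend.linkage[0, :2].astype(int))
        assert first == [0, 2]
        assert dend.linkage[0, 2] == 0.0

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(4, 3))
        df = pd.DataFrame(pts.T, columns=["a", "b", "c", "d"])
        dend = hierarchical_cluster(df, linkage="complete")
        expected = brute_force_agglomerate(pts, ["a", "b", "c", "d"], "complete")
        got_heights = sorted(dend.linkage[:, 2])
        exp_heights = sorted(h for _, h in expected)
        assert np.allclose(got_heights, exp_heights)

    def test_newick_contains_all_labels(self):
        df = pd.DataFrame(np.eye(3), columns=["x", "y", "z"])
        nwk = hierarchical_cluster(df).to_newick()
        assert nwk.endswith(";")
        for label in ("x", "y", "z"):
            assert label in nwk

    def test_non_finite_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [0.0, 1.0]})
        with pytest.raises(ValueError):
            hierarchical_cluster(df)


class TestTsne:
    def test_shape_and_determinism(self):
        tables, _ = moa_tables(seed=2, n_groups=3, per_group=6)
        fm = build_feature_matrix(tables, max_genes=200)
        a = embed_tsne(fm, perplexity=5, max_iterations=300, seed=3)
        b = embed_tsne(fm, perplexity=5, max_iterations=300, seed=3)
        assert a.shape == (18, 2)
        pd.testing.assert_frame_equal(a, b)

    def test_groups_closer_within_than_between(self):
        tables, groups = moa_tables(seed=4, n_groups=3, per_group=6)
        fm = build_feature_matrix(tables, max_genes=200)
        coords = embed_tsne(fm, perplexity=5, max_iterations=500, seed=1)
        within, between = [], []
        names = list(coords.index)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = np.linalg.norm(coords.loc[a] - coords.loc[b])
                (within if groups[a] == groups[b] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_too_few_columns_rejected(self):
        df = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            embed_tsne(df, perplexity=10)
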