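"""BFT merging, Jaccard distances, Ward tree, clusters, confusion."""

import random

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from panflux.analysis import (DistanceMatrix, cluster_feature_frequencies,
                              confusion_metrics, extract_clusters,
                              jaccard_distance_matrix, merge_bfts,
                              ward_dendrogram)
from panflux.prediction import BFT


def _bft(data, strains):
    return BFT(pd.DataFrame(data, columns=strains))


class TestMergeBfts:
    def test_single_table_identity(self):
        t = _bft({"s1": [1, 0], "s2": [0, 1]}, ["s1", "s2"])
        assert merge_bfts([t]).frame.equals(t.frame[sorted(t.strains)])

    def test_row_concatenation(self):
        a = BFT(pd.DataFrame([[1, 0]], index=["f1"], columns=["s1", "s2"]))
        b = BFT(pd.DataFrame([[0, 1], [1, 1]], index=["f2", "f3"],
                             columns=["s2", "s1"]))
        merged = merge_bfts([a, b])
        assert list(merged.frame.index) == ["f1", "f2", "f3"]
        assert merged.frame.loc["f2", "s2"] == 0  # column aligned

    def test_strain_mismatch_rejected(self):
        a = BFT(pd.DataFrame([[1]], index=["f1"], columns=["s1"]))
        b = BFT(pd.DataFrame([[1]], index=["f2"], columns=["s2"]))
        with pytest.raises(ValueError, match="s2"):
            merge_bfts([a, b])

    def test_exclusion_list_removes_named_rows(self):
        a = BFT(pd.DataFrame([[1, 0], [0, 1]], index=["f1", "f2"],
                             columns=["s1", "s2"]))
        merged = merge_bfts([a], exclude_features=["f1"])
        assert list(merged.frame.index) == ["f2"]

    def test_drop_constant_rows(self):
        a = BFT(pd.DataFrame([[1, 1], [0, 1]], index=["f1", "f2"],
                             columns=["s1", "s2"]))
        assert list(merge_bfts([a], drop_constant=True).frame.index) == ["f2"]


class TestJaccard:
    def test_identical_columns_distance_zero(self):
        bft = BFT(pd.DataFrame([[1, 1], [0, 0]], index=["f1", "f2"],
                               columns=["s1", "s2"]))
        d = jaccard_distance_matrix(bft)
        assert d.values[0, 1] == 0

    def test_hand_example_two_thirds(self):
        bft = BFT(pd.DataFrame([[1, 1], [1, 0], [0, 1]],
                               index=["f1", "f2", "f3"],
                               columns=["s1", "s2"]))
        d = jaccard_distance_matrix(bft)
        assert d.values[0, 1] == pytest.approx(2 / 3)

    def test_both_empty_pair_distance_zero(self):
        bft = BFT(pd.DataFrame([[0, 0]], index=["f1"], columns=["s1", "s2"]))
        assert jaccard_distance_matrix(bft).values[0, 1] == 0

    def test_random_tables_equal_set_formula_oracle(self):
        rng = random.Random(19)
        for _ in range(30):
            n_f, n_s = rng.randint(1, 20), rng.randint(2, 6)
            frame = pd.DataFrame(
                [[rng.randint(0, 1) for _ in range(n_s)] for _ in range(n_f)],
                index=[f"f{i}" for i in range(n_f)],
                columns=[f"s{j}" for j in range(n_s)])
            d = jaccard_distance_matrix(BFT(frame))
            for i in range(n_s):
                for j in range(n_s):
                    a = {f for f in frame.index if frame.iloc[:, i][f]}
                    b = {f for f in frame.index if frame.iloc[:, j][f]}
                    expect = 0.0 if not (a | b) else 1 - len(a & b) / len(a | b)
                    assert d.values[i, j] == pytest.approx(expect)

    def test_constant_one_feature_never_increases_distances(self):
        rng = random.Random(29)
        frame = pd.DataFrame(
            [[rng.randint(0, 1) for _ in range(5)] for _ in range(10)],
            index=[f"f{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(5)])
        before = jaccard_distance_matrix(BFT(frame)).values
        frame2 = pd.concat([frame, pd.DataFrame(
            [[1] * 5], index=["const"], columns=frame.columns)])
        after = jaccard_distance_matrix(BFT(frame2)).values
        assert (after <= before + 1e-12).all()


def _random_dm(rng, n):
    labels = [f"s{i:02d}" for i in range(n)]
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = rng.uniform(0.05, 1.0)
    return DistanceMatrix(labels, v)


class TestWard:
    def test_two_strains_single_merge(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        dendro = ward_dendrogram(d)
        assert len(dendro.merges) == 1
        assert dendro.merges[0][2] == pytest.approx(0.4)

    def test_closest_pair_merges_first(self):
        v = np.array([[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]])
        dendro = ward_dendrogram(DistanceMatrix(["A", "B", "C"], v))
        assert set(dendro.merges[0][:2]) == {0, 1}

    def test_heights_non_decreasing(self):
        rng = random.Random(41)
        for _ in range(10):
            dendro = ward_dendrogram(_random_dm(rng, 10))
            heights = [m[2] for m in dendro.merges]
            assert all(a <= b + 1e-9 for a, b in zip(heights, heights[1:]))

    def test_matches_scipy_reference_on_20_random_matrices(self):
        """Merge memberships and heights must match SciPy's Ward
        linkage on random 8-strain distance matrices."""
        rng = random.Random(43)
        for _ in range(20):
            dm = _random_dm(rng, 8)
            ours = ward_dendrogram(dm).to_linkage()
            iu = np.triu_indices(8, 1)
            ref = linkage(dm.values[iu], method="ward")
            assert np.allclose(ours[:, 2], ref[:, 2], atol=1e-9)
            assert np.allclose(np.sort(ours[:, :2], axis=1),
                               np.sort(ref[:, :2], axis=1))

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            ward_dendrogram(DistanceMatrix(["a"], np.zeros((1, 1))))

    def test_newick_is_parseable_ultrametric(self):
        import io as _io

        from Bio import Phylo
        rng = random.Random(47)
        dendro = ward_dendrogram(_random_dm(rng, 6))
        tree = Phylo.read(_io.StringIO(dendro.to_newick()), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(dendro.labels)


class TestExtractClusters:
    def test_k_one_and_k_n(self):
        rng = random.Random(53)
        dendro = ward_dendrogram(_random_dm(rng, 6))
        assert set(extract_clusters(dendro, 1).values()) == {"Cluster_1"}
        assert len(set(extract_clusters(dendro, 6).values())) == 6

    def test_exactly_k_nonempty_groups(self):
        rng = random.Random(59)
        dendro = ward_dendrogram(_random_dm(rng, 9))
        for k in range(1, 10):
            values = extract_clusters(dendro, k).values()
            assert len(set(values)) == k

    def test_labels_ordered_by_size(self):
        v = np.array([[0, .05, .1, .9], [.05, 0, .1, .9],
                      [.1, .1, 0, .9], [.9, .9, .9, 0]])
        dendro = ward_dendrogram(DistanceMatrix(list("abcd"), v))
        assignment = extract_clusters(dendro, 2)
        assert assignment["d"] == "Cluster_2"  # singleton is the smaller

    def test_invalid_k_rejected(self):
        rng = random.Random(61)
        dendro = ward_dendrogram(_random_dm(rng, 4))
        for k in (0, 5):
            with pytest.raises(ValueError):
                extract_clusters(dendro, k)


class TestFrequencies:
    def test_constant_feature_scores_zero(self):
        bft = _bft({"s1": [1], "s2": [1]}, ["s1", "s2"])
        bft.frame.index = ["f"]
        freq, score = cluster_feature_frequencies(
            bft, {"s1": "Cluster_1", "s2": "Cluster_2"})
        assert (freq.loc["f"] == 1).all()
        assert (score.loc["f"] == 0).all()

    def test_exclusive_feature_scores_one(self):
        frame = pd.DataFrame([[1, 1, 0, 0]], index=["f"],
                             columns=["a", "b", "c", "d"])
        assign = {"a": "C1", "b": "C1", "c": "C2", "d": "C2"}
        _freq, score = cluster_feature_frequencies(BFT(frame), assign)
        assert score.loc["f", "C1"] == 1
        assert score.loc["f", "C2"] == -1

    def test_frequencies_equal_column_averages(self):
        rng = random.Random(67)
        frame = pd.DataFrame(
            [[rng.randint(0, 1) for _ in range(6)] for _ in range(8)],
            index=[f"f{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(6)])
        assign = {f"s{j}": f"C{j % 2}" for j in range(6)}
        freq, _ = cluster_feature_frequencies(BFT(frame), assign)
        for c in ("C0", "C1"):
            members = [s for s, a in assign.items() if a == c]
            assert np.allclose(freq[c], frame[members].mean(axis=1))


class TestConfusion:
    def test_perfect_prediction(self):
        pred = _bft({"s1": [1, 0]}, ["s1"])
        pred.frame.index = ["f1", "f2"]
        exp = pred.frame.astype(float)
        per_strain, summary = confusion_metrics(pred, exp)
        assert per_strain["s1"].accuracy == 1
        assert per_strain["s1"].fp == per_strain["s1"].fn == 0

    def test_complement_gives_zero_accuracy(self):
        pred = _bft({"s1": [1, 0]}, ["s1"])
        pred.frame.index = ["f1", "f2"]
        exp = (1 - pred.frame).astype(float)
        per_strain, _ = confusion_metrics(pred, exp)
        assert per_strain["s1"].accuracy == 0

    def test_missing_cells_excluded_and_nan_ratios(self):
        pred = _bft({"s1": [1, 1]}, ["s1"])
        pred.frame.index = ["f1", "f2"]
        exp = pd.DataFrame({"s1": [1.0, np.nan]}, index=["f1", "f2"])
        per_strain, _ = confusion_metrics(pred, exp)
        m = per_strain["s1"]
        assert (m.tp, m.tn, m.fp, m.fn) == (1, 0, 0, 0)
        assert np.isnan(m.specificity)  # no negatives tested

    def test_random_pairs_equal_bruteforce_counts(self):
        rng = random.Random(71)
        for _ in range(20):
            feats = [f"f{i}" for i in range(rng.randint(1, 10))]
            pred_frame = pd.DataFrame(
                [[rng.randint(0, 1)] for _ in feats], index=feats,
                columns=["s1"])
            exp = pd.DataFrame(
                [[rng.choice([0.0, 1.0, np.nan])] for _ in feats],
                index=feats, columns=["s1"])
            per_strain, _ = confusion_metrics(BFT(pred_frame), exp)
            tp = sum(1 for f in feats
                     if exp.loc[f, "s1"] == 1 and pred_frame.loc[f, "s1"] == 1)
            fn = sum(1 for f in feats
                     if exp.loc[f, "s1"] == 1 and pred_frame.loc[f, "s1"] == 0)
            assert per_strain["s1"].tp == tp
            assert per_strain["s1"].fn == fn

    def test_no_overlap_rejected(self):
        pred = _bft({"s1": [1]}, ["s1"])
        pred.frame.index = ["f1"]
        exp = pd.DataFrame({"s2": [1.0]}, index=["f9"])
        with pytest.raises(ValueError):
            confusion_metrics(pred, exp)
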