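"""Median matrices, clustering, filtering, voting, and metrics."""

import numpy as np
import pandas as pd
import pytest

from grammarscope import grammar_recover as gr
from grammarscope.attribution import SaliencyProfile


def _profile(values, motifs=None, grammars=None):
    n = len(values)
    meta = pd.DataFrame(
        {
            "sequence": [f"s{i}" for i in range(n)],
            "motif_id": motifs if motifs is not None else ["M"] * n,
            "grammar_id": grammars if grammars is not None else ["g"] * n,
            "start": range(n),
            "end": [i + 8 for i in range(n)],
            "class_id": [1] * n,
        }
    )
    return SaliencyProfile(np.asarray(values, dtype=float), meta, "penultimate")


class TestMedianMatrix:
    def test_median_is_robust_to_outliers(self):
        prof = _profile([[1.0], [2.0], [100.0]])
        mat = gr.median_tf_grammar_matrix(prof, scale=False)
        assert mat.values[0, 0] == 2.0

    def test_scaled_columns_are_zscored(self):
        rng = np.random.default_rng(0)
        vals = rng.random((30, 4))
        motifs = [f"M{i % 3}" for i in range(30)]
        grammars = [f"g{i % 2}" for i in range(30)]
        mat = gr.median_tf_grammar_matrix(_profile(vals, motifs, grammars), scale=True)
        assert np.allclose(mat.values.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(mat.values.std(axis=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        # both neurons see the same median for the single (motif, grammar)
        prof = _profile([[3.0, 3.0], [5.0, 5.0]], motifs=["A", "A"])
        mat = gr.median_tf_grammar_matrix(prof, scale=True)
        assert np.allclose(mat.values, 0)

    def test_column_count_matches_groupby_oracle(self):
        rng = np.random.default_rng(1)
        n = 200
        motifs = [f"M{i}" for i in rng.integers(0, 6, size=n)]
        grammars = [f"g{i}" for i in rng.integers(0, 4, size=n)]
        prof = _profile(rng.random((n, 5)), motifs, grammars)
        mat = gr.median_tf_grammar_matrix(prof, scale=False)
        oracle = pd.DataFrame({"m": motifs, "g": grammars}).groupby(["m", "g"]).size()
        assert len(mat.columns) == len(oracle)
        # values agree with a pandas groupby-median oracle
        df = pd.DataFrame(prof.values)
        df["m"], df["g"] = motifs, grammars
        med = df.groupby(["m", "g"]).median()
        for j, (m, g) in enumerate(mat.columns):
            assert np.allclose(mat.values[:, j], med.loc[(m, g)].to_numpy())


class TestHierarchical:
    def test_duplicated_columns_share_group(self):
        rng = np.random.default_rng(2)
        base = rng.random((10, 5))
        base[:, 4] = base[:, 0]
        mat = gr.MedianMatrix(base, [(f"M{i}", "g") for i in range(5)], scaled=False)
        for k in (2, 3, 4):
            _, col_groups, _, _ = gr.hierarchical_cluster(mat, 2, k)
            assert col_groups[0] == col_groups[4]

    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0.0], [5.0], [10.0]])
        cols = np.repeat(centers, 4, axis=0).T + rng.normal(0, 0.01, (8, 12))
        mat = gr.MedianMatrix(cols, [(f"M{i}", "g") for i in range(12)], scaled=False)
        _, col_groups, _, _ = gr.hierarchical_cluster(mat, 2, 3)
        blocks = [tuple(col_groups[i * 4 : (i + 1) * 4]) for i in range(3)]
        assert all(len(set(b)) == 1 for b in blocks)
        assert len({b[0] for b in blocks}) == 3

    def test_k_exceeding_dimension_rejected(self):
        mat = gr.MedianMatrix(np.eye(3), [("M", f"g{i}") for i in range(3)], scaled=False)
        with pytest.raises(ValueError):
            gr.hierarchical_cluster(mat, 5, 2)


class TestFilterTopFraction:
    def test_keeps_single_max_row(self):
        vals = np.arange(10)[:, None] * np.ones((10, 3))
        prof = _profile(vals)
        kept, mask = gr.filter_top_fraction(prof, 0.1)
        assert len(kept) == 1
        assert kept.meta["sequence"].iloc[0] == "s9"

    def test_q_one_is_identity(self):
        prof = _profile(np.random.default_rng(4).random((7, 2)))
        kept, mask = gr.filter_top_fraction(prof, 1.0)
        assert len(kept) == 7 and mask.all()

    def test_matches_sorting_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            vals = np.round(rng.random((50, 4)), 2)
            prof = _profile(vals)
            q = float(rng.uniform(0.1, 0.9))
            kept, mask = gr.filter_top_fraction(prof, q)
            keep_n = int(np.ceil(q * 50))
            sums = vals.sum(axis=1)
            order = sorted(range(50), key=lambda i: (-sums[i], i))
            assert set(np.nonzero(mask)[0]) == set(order[:keep_n])

    def test_invalid_fraction(self):
        prof = _profile(np.ones((3, 2)))
        with pytest.raises(ValueError):
            gr.filter_top_fraction(prof, 0.0)


class TestKMeans:
    def test_separates_two_point_masses(self):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        labels = gr.kmeans_cluster(_profile(X), 2, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_deterministic(self):
        X = np.random.default_rng(6).random((40, 3))
        a = gr.kmeans_cluster(_profile(X), 4, seed=9)
        b = gr.kmeans_cluster(_profile(X), 4, seed=9)
        assert np.array_equal(a, b)

    def test_beats_random_assignments(self):
        rng = np.random.default_rng(7)
        X = rng.random((60, 4))
        labels = gr.kmeans_cluster(_profile(X), 5, seed=0)

        def wcss(assign):
            tot = 0.0
            for c in np.unique(assign):
                pts = X[assign == c]
                tot += ((pts - pts.mean(axis=0)) ** 2).sum()
            return tot

        ours = wcss(labels)
        assert all(ours <= wcss(rng.integers(0, 5, size=60)) for _ in range(100))

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            gr.kmeans_cluster(_profile(np.ones((3, 2))), 5, seed=0)


class TestMajorityVote:
    def test_modal_label(self):
        mapping, pred = gr.majority_vote([0] * 7, ["A"] * 5 + ["B"] * 2)
        assert mapping == {0: "A"}
        assert list(pred) == ["A"] * 7

    def test_tie_breaks_lexicographically(self):
        mapping, _ = gr.majority_vote([0] * 6, ["B", "A"] * 3)
        assert mapping == {0: "A"}

    def test_pure_clusters_give_perfect_accuracy(self):
        truths = np.array(["x"] * 4 + ["y"] * 4)
        assign = np.array([0] * 4 + [1] * 4)
        _, pred = gr.majority_vote(assign, truths)
        acc, sens = gr.reconstruction_metrics(pred, truths)
        assert acc == 1.0 and set(sens.values()) == {1.0}


class TestMetrics:
    def test_hand_case(self):
        acc, sens = gr.reconstruction_metrics(
            np.array(["g1", "g2", "g2", "g2"]), np.array(["g1", "g1", "g2", "g2"])
        )
        assert acc == 0.75
        assert sens == {"g1": 0.5, "g2": 1.0}

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(8)
        labels = np.array([f"g{i}" for i in range(5)])
        for _ in range(5):
            true = labels[rng.integers(0, 5, size=80)]
            pred = labels[rng.integers(0, 5, size=80)]
            acc, sens = gr.reconstruction_metrics(pred, true)
            ct = pd.crosstab(pd.Series(true), pd.Series(pred))
            diag = sum(ct.loc[g, g] for g in ct.index if g in ct.columns)
            assert acc == pytest.approx(diag / 80)
            for g in np.unique(true):
                row_total = (true == g).sum()
                hit = ((true == g) & (pred == g)).sum()
                assert sens[g] == pytest.approx(hit / row_total)


class TestEmbedAndSilhouette:
    def test_embedding_shape_and_determinism(self):
        X = np.random.default_rng(9).random((40, 6))
        a = gr.embed_2d(_profile(X), seed=1)
        b = gr.embed_2d(_profile(X), seed=1)
        assert a.shape == (40, 2)
        assert np.allclose(a, b)

    def test_duplicate_rows_land_close(self):
        rng = np.random.default_rng(10)
        X = rng.random((30, 4))
        X[7] = X[3]
        xy = gr.embed_2d(_profile(X), seed=0)
        d_dup = np.linalg.norm(xy[7] - xy[3])
        others = [np.linalg.norm(xy[i] - xy[3]) for i in range(30) if i not in (3, 7)]
        assert d_dup < np.median(others)

    def test_three_blobs_select_k3(self):
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(c, 0.05, (20, 3)) for c in (0.0, 5.0, 10.0)])
        best, scores = gr.select_k_silhouette(_profile(X), range(2, 7), seed=0)
        assert best == 3
        assert all(-1 <= v <= 1 for v in scores.values())

    def test_identical_points_give_zero_silhouette(self):
        X = np.ones((12, 3))
        _, scores = gr.select_k_silhouette(_profile(X), range(2, 4), seed=0)
        assert set(scores.values()) == {0.0}

    def test_k_out_of_range(self):
        X = np.random.default_rng(12).random((6, 2))
        with pytest.raises(ValueError):
            gr.select_k_silhouette(_profile(X), range(2, 10), seed=0)


def test_recover_grammars_end_to_end_synthetic():
    """Well-separated per-grammar profiles are reconstructed perfectly."""
    rng = np.random.default_rng(13)
    rows, grammars = [], []
    for g in range(4):
        center = np.zeros(6)
        center[g] = 10.0
        rows.append(center + rng.normal(0, 0.05, (25, 6)))
        grammars += [f"g{g}"] * 25
    prof = _profile(np.vstack(rows), motifs=["M"] * 100, grammars=grammars)
    result = gr.recover_grammars(prof, k=4, seed=0)
    assert result.accuracy == 1.0
    assert set(result.sensitivity.values()) == {1.0}
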