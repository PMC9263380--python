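"""Unsupervised scorers: hand oracles, fixtures, and shared properties."""

import numpy as np
import pytest

from stabfs import build_affinity_graph
from stabfs.selectors import (LAPLACIAN_WORST, SCORE_CAP, LaplacianScoreRanker,
                              MCFSRanker, NDFSRanker, PearsonRedundancyRanker,
                              RandomRanker, SPECRanker, UDFSRanker,
                              laplacian_score, mcfs_score, ndfs_score,
                              pearson_redundancy_score, spec_score, udfs_score)


class TestLaplacianScore:
    def test_matches_dense_hand_oracle_on_complete_graph(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        W = np.ones((4, 4)) - np.eye(4)
        deg = W.sum(1)
        D, L = np.diag(deg), np.diag(deg) - W
        expected = np.zeros(3)
        for j in range(3):
            f = X[:, j]
            ft = f - (f @ deg) / deg.sum() * np.ones(4)
            expected[j] = -(ft @ L @ ft) / (ft @ D @ ft)
        assert np.allclose(laplacian_score(X, W), expected, rtol=1e-10)

    def test_constant_feature_worst(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        W = build_affinity_graph(rng.normal(size=(8, 2)), 3)
        scores = laplacian_score(X, W)
        assert scores[0] == LAPLACIAN_WORST
        assert scores[0] < scores[1]

    def test_duplicate_columns_equal_scores(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 3))
        Xd = np.column_stack([X, X[:, 0]])
        W = build_affinity_graph(X, 3)
        s = laplacian_score(Xd, W)
        assert np.isclose(s[0], s[3])


@pytest.fixture(scope="module")
def two_triangles():
    # two triangles joined by one edge; clear Fiedler structure
    W = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
        W[i, j] = W[j, i] = 1.0
    return W


class TestSPEC:
    def test_fiedler_feature_beats_noise(self, two_triangles):
        W = two_triangles
        deg = W.sum(1)
        dh = np.sqrt(deg)
        nL = np.eye(6) - W / np.outer(dh, dh)
        _, vecs = np.linalg.eigh(nL)
        fiedler_feature = vecs[:, 1] / dh
        noise = np.random.default_rng(1).normal(size=6)
        for variant in ("phi1", "phi2", "phi3"):
            s = spec_score(np.column_stack([fiedler_feature, noise]), W,
                           variant=variant)
            assert s[0] > s[1], variant

    def test_constant_feature_worst_default_variant(self, two_triangles):
        X = np.column_stack([np.ones(6),
                             np.random.default_rng(2).normal(size=6)])
        s = spec_score(X, two_triangles)
        assert s[0] == -SCORE_CAP and s[0] < s[1]

    def test_scores_invariant_to_feature_scaling(self, two_triangles):
        X = np.random.default_rng(3).normal(size=(6, 3))
        assert np.allclose(spec_score(X, two_triangles),
                           spec_score(X * np.array([2.0, 0.5, 11.0]),
                                      two_triangles))


class TestMCFS:
    def test_blob_feature_top(self, two_blobs):
        X, _ = two_blobs
        scores = MCFSRanker(n_select_hint=3).fit(X).scores_
        assert np.argmax(scores) == 0

    def test_zero_feature_scores_zero(self, two_blobs):
        X, _ = two_blobs
        Xz = np.column_stack([X, np.zeros(len(X))])
        W = build_affinity_graph(X, 5)
        assert mcfs_score(Xz, W, n_clusters=2, n_select_hint=3)[-1] == 0.0

    def test_duplicated_informative_column_representative_selected(self, two_blobs):
        X, _ = two_blobs
        Xd = np.column_stack([X, X[:, 0]])
        W = build_affinity_graph(X, 5)
        s = mcfs_score(Xd, W, n_clusters=2, n_select_hint=3)
        assert np.argmax(s) in (0, 6)


class TestNDFS:
    def test_objective_non_increasing(self, two_blobs):
        X, _ = two_blobs
        r = NDFSRanker(random_state=0, max_iter=60).fit(X)
        h = np.array(r.objective_history_)
        assert np.all(np.diff(h) <= 1e-8 * np.maximum(np.abs(h[:-1]), 1.0))

    def test_blob_feature_dominates_noise(self, two_blobs):
        X, _ = two_blobs
        scores = NDFSRanker(random_state=0).fit(X).scores_
        assert np.argmax(scores) == 0

    def test_seed_determinism(self, two_blobs):
        X, _ = two_blobs
        a = NDFSRanker(random_state=3).fit(X).scores_
        b = NDFSRanker(random_state=3).fit(X).scores_
        assert np.array_equal(a, b)


class TestUDFS:
    def test_objective_non_increasing(self, two_blobs):
        X, _ = two_blobs
        r = UDFSRanker(max_iter=60).fit(X)
        h = np.array(r.objective_history_)
        assert np.all(np.diff(h) <= 1e-8 * np.maximum(np.abs(h[:-1]), 1.0))

    def test_zero_feature_scores_zero(self, two_blobs):
        X, _ = two_blobs
        Xz = np.column_stack([X, np.zeros(len(X))])
        assert udfs_score(Xz)[-1] == 0.0

    def test_blob_feature_ranked_first(self, two_blobs):
        X, _ = two_blobs
        assert np.argmax(UDFSRanker().fit(X).scores_) == 0


class TestPearsonRedundancy:
    def test_independent_feature_beats_duplicated_pair(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        X = np.column_stack([a, a, b])
        s = pearson_redundancy_score(X)
        assert np.argmax(s) == 2

    def test_matches_corrcoef_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 5))
        R = np.corrcoef(X.T)
        expected = np.array([
            -np.mean([abs(R[f, g]) for g in range(5) if g != f])
            for f in range(5)
        ])
        assert np.allclose(pearson_redundancy_score(X), expected, rtol=1e-10)

    def test_vanishing_correlation_for_independent_noise(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20000, 2))
        assert np.all(np.abs(pearson_redundancy_score(X)) < 0.03)

    def test_constant_feature_treated_as_uncorrelated(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.full(30, 2.0), rng.normal(size=(30, 2))])
        with pytest.warns(RuntimeWarning):
            s = pearson_redundancy_score(X)
        assert s[0] == 0.0

    def test_duplicated_columns_equal_scores(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 3))
        Xd = np.column_stack([X, X[:, 1]])
        s = pearson_redundancy_score(Xd)
        assert np.isclose(s[1], s[3])


@pytest.mark.parametrize("ranker_cls", [
    LaplacianScoreRanker, SPECRanker, MCFSRanker, NDFSRanker, UDFSRanker,
    PearsonRedundancyRanker,
])
def test_orientation_blob_feature_above_median(ranker_cls, two_blobs):
    """Higher-is-better orientation: the structured feature is never ranked
    in the bottom half by any unsupervised scorer."""
    X, _ = two_blobs
    scores = ranker_cls().fit(X).scores_
    assert scores[0] >= np.median(scores)


def test_random_ranker_seeded():
    X = np.random.default_rng(0).normal(size=(10, 5))
    assert np.array_equal(RandomRanker(random_state=4).fit(X).scores_,
                          RandomRanker(random_state=4).fit(X).scores_)
    assert not np.array_equal(RandomRanker(random_state=4).fit(X).scores_,
                              RandomRanker(random_state=5).fit(X).scores_)
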