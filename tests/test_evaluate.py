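"""Bootstrap split contract, ridge AUC, and whole-combination evaluation."""

import dataclasses

import numpy as np
import pytest
from sklearn.linear_model import Ridge
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from stabfs import (EvalConfig, SplitError, bootstrap_split, get_selector_spec,
                    ridge_auc, run_combination, select_features_one_try)


@pytest.fixture(scope="module")
def cfg():
    return EvalConfig(M=10, k1=10, k2=5, base_seed=42)


class TestBootstrapSplit:
    def test_70_30_partition_stratified(self, cfg):
        y = np.repeat([0, 1], 50)
        train, test = bootstrap_split(100, y, cfg, try_index=0)
        assert len(train) == 70 and len(test) == 30
        assert set(train).isdisjoint(test)
        assert sorted(np.concatenate([train, test])) == list(range(100))
        assert (y[train] == 1).sum() == 35 and (y[test] == 1).sum() == 15

    def test_deterministic_per_try(self, cfg):
        y = np.repeat([0, 1], 20)
        a = bootstrap_split(40, y, cfg, 3)
        b = bootstrap_split(40, y, cfg, 3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = bootstrap_split(40, y, cfg, 4)
        assert not np.array_equal(a[0], c[0])

    def test_small_class_rejected(self, cfg):
        y = np.array([1] + [0] * 39)
        with pytest.raises(SplitError):
            bootstrap_split(40, y, cfg, 0)


class TestRidgeAUC:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        Xtr = np.vstack([rng.normal(0, 0.1, (10, 2)),
                         rng.normal(5, 0.1, (10, 2))])
        ytr = np.repeat([0, 1], 10)
        Xte = np.vstack([rng.normal(0, 0.1, (5, 2)),
                         rng.normal(5, 0.1, (5, 2))])
        yte = np.repeat([0, 1], 5)
        assert ridge_auc(Xtr, ytr, Xte, yte) == 1.0

    def test_matches_sklearn_pipeline_oracle(self):
        """Training-only standardisation: identical to a fit/transform pipeline."""
        rng = np.random.default_rng(1)
        Xtr, Xte = rng.normal(size=(40, 6)), rng.normal(size=(20, 6))
        ytr = rng.integers(0, 2, 40)
        yte = rng.integers(0, 2, 20)
        ytr[:2] = [0, 1]
        yte[:2] = [0, 1]
        pipe = make_pipeline(StandardScaler(), Ridge(alpha=1.0))
        pipe.fit(Xtr, 2.0 * ytr - 1)
        expected = roc_auc_score(yte, pipe.predict(Xte))
        assert ridge_auc(Xtr, ytr, Xte, yte, 1.0) == pytest.approx(expected, rel=1e-10)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 5))
        y = rng.integers(0, 2, 2000)
        auc = ridge_auc(X[:1400], y[:1400], X[1400:], y[1400:])
        assert 0.4 < auc < 0.6

    def test_constant_training_feature_dropped(self):
        rng = np.random.default_rng(3)
        Xtr = np.column_stack([np.ones(20), rng.normal(size=20)])
        Xte = np.column_stack([np.ones(10), rng.normal(size=10)])
        with pytest.warns(RuntimeWarning):
            auc = ridge_auc(Xtr, np.repeat([0, 1], 10), Xte, np.repeat([0, 1], 5))
        assert 0.0 <= auc <= 1.0


class TestSequentialSelection:
    def test_identity_when_k1_k2_equal_d(self, two_blobs):
        X, y = two_blobs
        sel = select_features_one_try(X, y, get_selector_spec("S1"),
                                      get_selector_spec("U6"), 6, 6)
        assert sel.tolist() == list(range(6))

    def test_indices_refer_to_original_space(self, strong_signal):
        ds = strong_signal
        sel = select_features_one_try(ds.features.values, ds.labels,
                                      get_selector_spec("S1"),
                                      get_selector_spec("U1"), 20, 10)
        assert set(ds.informative_idx.tolist()) <= set(sel.tolist())

    def test_redundant_duplicate_pair_never_both_kept(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 8))
        X[:, 7] = X[:, 0]
        y = np.repeat([0, 1], 25)
        sel = select_features_one_try(X, y, get_selector_spec("S1"),
                                      get_selector_spec("U6"), 8, 6)
        assert not {0, 7} <= set(sel.tolist())


class TestRunCombination:
    def test_z_rows_sum_to_k2(self, null_signal, cfg):
        res = run_combination(null_signal.features, null_signal.labels,
                              get_selector_spec("S1"), get_selector_spec("U6"),
                              cfg)
        assert res.Z.Z.shape == (cfg.M, null_signal.features.n_features)
        assert np.all(res.Z.Z.sum(axis=1) == cfg.k2)
        assert res.mean_auc == pytest.approx(
            np.mean([t.auc for t in res.tries]))

    def test_bit_reproducible_given_config(self, null_signal, cfg):
        args = (null_signal.features, null_signal.labels,
                get_selector_spec("S2"), get_selector_spec("U1"), cfg)
        a, b = run_combination(*args), run_combination(*args)
        assert np.array_equal(a.Z.Z, b.Z.Z)
        assert a.mean_auc == b.mean_auc
        assert a.stability.value == b.stability.value

    def test_strong_signal_high_auc_and_stability(self, strong_signal):
        cfg = EvalConfig(M=20, k1=10, k2=10, base_seed=7)
        res = run_combination(strong_signal.features, strong_signal.labels,
                              get_selector_spec("S2"), get_selector_spec("U6"),
                              cfg)
        assert res.mean_auc >= 0.95
        assert res.stability.value >= 0.9

    def test_null_signal_auc_near_chance(self, null_signal):
        cfg = EvalConfig(M=20, k1=20, k2=10, base_seed=3)
        res = run_combination(null_signal.features, null_signal.labels,
                              get_selector_spec("S1"), get_selector_spec("U6"),
                              cfg)
        assert 0.4 <= res.mean_auc <= 0.6

    def test_test_rows_do_not_influence_selection(self, null_signal, cfg):
        """Leakage guard: perturbing one try's test subjects leaves that
        try's selected feature set unchanged."""
        X = null_signal.features.values
        y = null_signal.labels
        train, test = bootstrap_split(len(y), y, cfg, try_index=0)
        from stabfs.evaluate import _scorer_seed
        seed = _scorer_seed(cfg.base_seed, 0, "S1U1")
        sel = select_features_one_try(X[train], y[train],
                                      get_selector_spec("S1"),
                                      get_selector_spec("U1"),
                                      cfg.k1, cfg.k2, seed=seed)
        X2 = X.copy()
        X2[test] += 1e6  # corrupt held-out subjects only
        sel2 = select_features_one_try(X2[train], y[train],
                                       get_selector_spec("S1"),
                                       get_selector_spec("U1"),
                                       cfg.k1, cfg.k2, seed=seed)
        assert np.array_equal(sel, sel2)

    def test_config_validation(self):
        with pytest.raises(Exception):
            EvalConfig(M=1).validate()
        with pytest.raises(Exception):
            EvalConfig(k1=5, k2=10).validate()
        with pytest.raises(Exception):
            EvalConfig(train_fraction=1.5).validate()
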