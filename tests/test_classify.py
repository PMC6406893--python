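"""Random-forest classifier, MCC/AUC metrics, cross-validation, importances."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from npscout.classify import (
    NPClassifier,
    evaluate,
    k_fold_cv,
    mcc,
    mcc_from_labels,
    roc_auc,
    train_rf,
)
from npscout.datasets import NP, SM
from npscout.features import FingerprintKind, featurize_matrix, maccs_key_names


def toy_matrix(n=60, seed=0):
    """Linearly separable: bit 7 is the class, the rest is noise."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, 20)).astype(np.uint8)
    y = np.array([NP] * (n // 2) + [SM] * (n - n // 2))
    X[:, 7] = y
    return X, y


class TestTraining:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = toy_matrix()
        clf = NPClassifier(feature_set="custom", random_state=0).fit(X, y)
        assert np.array_equal(clf.predict(X), y)

    def test_deterministic_given_seed(self):
        X, y = toy_matrix()
        probe = toy_matrix(n=30, seed=5)[0]
        p1 = NPClassifier(feature_set="custom", random_state=3).fit(X, y).predict_np_probability(probe)
        p2 = NPClassifier(feature_set="custom", random_state=3).fit(X, y).predict_np_probability(probe)
        assert np.array_equal(p1, p2)

    def test_single_class_raises(self):
        X = np.zeros((10, 5))
        with pytest.raises(ValueError):
            NPClassifier(feature_set="custom").fit(X, np.ones(10, dtype=int))

    def test_width_validation(self):
        X, y = toy_matrix()
        with pytest.raises(ValueError):
            NPClassifier(feature_set="maccs").fit(X, y)

    def test_metadata_records_hyperparameters(self, maccs_model):
        md = maccs_model.metadata_
        assert md["n_estimators"] == 100
        assert md["max_features"] == "sqrt"
        assert md["class_weight"] == "balanced"
        assert md["feature_set"] == "maccs"


class TestPrediction:
    def test_pure_leaf_probability_one(self):
        # single informative bit, no noise: every tree isolates pure leaves
        y = np.array([NP] * 30 + [SM] * 30)
        X = np.zeros((60, 20), dtype=np.uint8)
        X[:, 7] = y
        clf = NPClassifier(feature_set="custom", random_state=0).fit(X, y)
        assert clf.predict_np_probability(X[:1])[0] == pytest.approx(1.0)

    def test_probability_in_range_for_empty_pattern(self):
        X, y = toy_matrix()
        clf = NPClassifier(feature_set="custom", random_state=0).fit(X, y)
        p = clf.predict_np_probability(np.zeros((1, 20)))[0]
        assert 0.0 <= p <= 1.0

    def test_tie_at_threshold_classifies_sm(self):
        clf = NPClassifier(feature_set="custom")
        clf.forest_ = _ConstantForest(0.5)
        clf.classes_ = np.array([SM, NP])
        assert clf.predict(np.zeros((1, 4)))[0] == SM

    def test_held_out_auc_on_fixture_corpus(self, maccs_model, small_split):
        _, test = small_split
        X = featurize_matrix(test.molecules, FingerprintKind.MACCS166)
        assert evaluate(maccs_model, X, test.labels).auc >= 0.95


class _ConstantForest:
    def __init__(self, p):
        self.p = p
        self.classes_ = np.array([SM, NP])

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.column_stack([np.full(len(X), 1 - self.p), np.full(len(X), self.p)])


class TestMcc:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,expected",
        [
            (50, 0, 50, 0, 1.0),
            (50, 10, 40, 0, 2000 / math.sqrt(6_000_000)),
            (25, 25, 25, 25, 0.0),
            (0, 0, 50, 0, 0.0),  # degenerate marginal -> 0 by convention
        ],
    )
    def test_known_values(self, tp, fp, tn, fn, expected):
        assert mcc(tp, fp, tn, fn) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn_on_random_matrices(self, rng):
        for _ in range(50):
            y_true = rng.integers(0, 2, size=40)
            y_pred = rng.integers(0, 2, size=40)
            assert mcc_from_labels(y_true, y_pred) == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-12
            )


def pairwise_auc(scores, labels):
    """Exhaustive Mann-Whitney oracle; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == NP]
    neg = [s for s, l in zip(scores, labels) if l == SM]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.1], [NP, SM], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [NP, NP, SM, SM], 0.5),
            ([0.8, 0.4, 0.6, 0.2], [NP, NP, SM, SM], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [NP, NP])

    def test_agrees_with_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )


class TestCrossValidation:
    def test_separable_data_perfect_cv(self):
        X, y = toy_matrix(n=100)
        report = k_fold_cv(X, y, k=10, seed=0)
        assert report.mean_fold_auc == pytest.approx(1.0)

    def test_shuffled_labels_near_chance(self, rng):
        X = rng.integers(0, 2, size=(200, 20)).astype(np.uint8)
        y = np.array([NP, SM] * 100)
        aucs = []
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(200)
            aucs.append(k_fold_cv(X, y[perm], k=5, seed=seed, n_estimators=20).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_leave_one_out_runs_all_folds(self):
        X, y = toy_matrix(n=20)
        report = k_fold_cv(X, y, k=20, seed=0, n_estimators=10)
        assert len(report.fold_mccs) == 20

    def test_deterministic(self):
        X, y = toy_matrix(n=80)
        a = k_fold_cv(X, y, k=5, seed=4)
        b = k_fold_cv(X, y, k=5, seed=4)
        assert a.fold_aucs == b.fold_aucs and a.fold_mccs == b.fold_mccs


class TestFeatureImportances:
    def test_planted_bit_ranks_first(self):
        X, y = toy_matrix(n=200)
        clf = NPClassifier(feature_set="custom", random_state=0).fit(X, y)
        names = [f"bit{i}" for i in range(20)]
        ranked = clf.feature_importances(names)
        assert ranked[0][0] == "bit7"

    def test_importances_sum_to_one(self, maccs_model):
        total = sum(v for _, v in maccs_model.feature_importances())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_nitrogen_key_among_top_features(self, maccs_model):
        # the SM-like class is nitrogen-rich by construction, so a nitrogen
        # MACCS key must dominate the importance ranking
        top3 = [name for name, _ in maccs_model.feature_importances()[:3]]
        assert any("[#7]" in name for name in top3), top3


class TestSerialization:
    def test_roundtrip_identical_probabilities(self, tmp_path, maccs_model, small_split):
        _, test = small_split
        X = featurize_matrix(test.molecules[:50], FingerprintKind.MACCS166)
        path = tmp_path / "model.npsm"
        maccs_model.save(path)
        back = NPClassifier.load(path)
        assert np.array_equal(
            back.predict_np_probability(X), maccs_model.predict_np_probability(X)
        )


class TestMonotoneSanity:
    def test_adding_np_motif_never_decreases_probability(self, morgan_model, small_split):
        from npscout.fixtures import _attach

        _, test = small_split
        motif = "OC1OC(CO)C(O)C(O)C1O"
        checked = 0
        for m, lbl in zip(test.molecules, test.labels):
            if lbl != SM or checked >= 20:
                continue
            pos = [
                a.GetIdx()
                for a in m.mol.GetAtoms()
                if a.GetTotalNumHs() >= 1 and a.GetSymbol() == "C"
            ]
            if not pos:
                continue
            grown = _attach(m.mol, motif, pos[0])
            if grown is None:
                continue
            X = featurize_matrix([m.mol, grown], FingerprintKind.MORGAN2_1024)
            p = morgan_model.predict_np_probability(X)
            assert p[1] >= p[0]
            checked += 1
        assert checked >= 10
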