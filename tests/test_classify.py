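import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sigcollapse import (ClassifierResult, SignatureClassifier, build_features,
                         evaluate_timepoints, roc_auc, select_features_l1,
                         train_logistic, zscale_apply, zscale_fit)
from sigcollapse import mi_study
from sigcollapse.io_formats import ExpressionMatrix


def pairwise_auc(scores, labels):
    """Exhaustive pairwise-counting oracle."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in ctrls)
    return wins / (len(cases) * len(ctrls))


def _noise_matrix(genes, n_case, n_control, seed=0, shift=None):
    rng = np.random.default_rng(seed)
    samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_control)]
    vals = 7 + 0.5 * rng.standard_normal((len(genes), len(samples)))
    if shift:
        for g, delta in shift.items():
            vals[genes.index(g), :n_case] += delta
    group = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), group)


class TestBuildFeatures:
    def test_published_signatures_have_17_unique_features(self):
        sigs = mi_study.validated_signatures()
        assert sigs.n_slots == 18  # S100A12 sits in two signatures
        m = _noise_matrix(sigs.unique_genes, 3, 3)
        X, y = build_features(sigs, m)
        assert X.shape == (6, 17)
        assert list(X.columns) == sorted(set(X.columns))
        assert y.tolist() == [1, 1, 1, 0, 0, 0]

    def test_missing_gene_is_error(self):
        sigs = mi_study.validated_signatures()
        m = _noise_matrix(["ADAP2", "CD14"], 3, 3)
        with pytest.raises(KeyError):
            build_features(sigs, m)


class TestZScaling:
    def test_train_scaled_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(3, 2, size=(30, 4)), columns=list("ABCD"))
        Z = zscale_apply(zscale_fit(X), X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=0, ddof=0), 1, atol=1e-10)

    def test_scaling_already_scaled_data_is_identity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("ABC"))
        Z = zscale_apply(zscale_fit(X), X)
        Z2 = zscale_apply(zscale_fit(Z), Z)
        pd.testing.assert_frame_equal(Z, Z2)

    def test_constant_column_error_names_gene(self):
        X = pd.DataFrame({"CD14": [1.0, 1.0, 1.0], "TLR2": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="CD14"):
            zscale_fit(X)

    def test_shifted_test_data_keeps_nonzero_mean(self):
        train = pd.DataFrame({"A": [0.0, 2.0]})
        test = pd.DataFrame({"A": [3.0, 5.0]})
        scaler = zscale_fit(train)
        assert zscale_apply(scaler, test).to_numpy().mean() == pytest.approx(3.0)


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_and_ties(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, int)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.2, 0.3, 0.5], size=n)  # force ties
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(scores=st.lists(st.floats(min_value=-5, max_value=5,
                                     allow_nan=False), min_size=4, max_size=12))
    def test_score_negation_complements_auc(self, scores):
        n = len(scores)
        labels = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        s = np.asarray(scores)
        assert roc_auc(s, labels) + roc_auc(-s, labels) == pytest.approx(1.0)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3, 4], [1, 1, 1, 1])


class TestTrainLogistic:
    def _separable(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("ABC"))
        y = (X["A"] > 0).astype(int).to_numpy()
        X["A"] += 4 * y  # fully separable on A
        return X, y

    def test_separable_data_reaches_train_auc_one(self):
        X, y = self._separable()
        result = train_logistic(X, y, folds=10, seed=0)
        assert result.train_auc == 1.0

    def test_deterministic_under_fixed_seed(self):
        X, y = self._separable()
        a = train_logistic(X, y, folds=10, seed=3)
        b = train_logistic(X, y, folds=10, seed=3)
        assert a.C == b.C
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_single_class_is_error(self):
        X, _ = self._separable()
        with pytest.raises(ValueError):
            train_logistic(X, np.ones(len(X), int))

    def test_too_few_members_per_class_for_folds(self):
        X, y = self._separable(n=12)
        with pytest.raises(ValueError, match="10-fold"):
            train_logistic(X, y, folds=10)

    def test_result_roundtrips_through_json(self, tmp_path):
        X, y = self._separable()
        result = train_logistic(X, y, folds=10, seed=0)
        result.to_json(tmp_path / "model.json")
        back = ClassifierResult.from_json(tmp_path / "model.json")
        np.testing.assert_allclose(back.decision_function(X),
                                   result.decision_function(X))


class TestL1Selection:
    def test_zeroed_model_selects_nothing(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("ABCDE"))
        y = np.array([0, 1] * 30)
        result = train_logistic(X, y, penalty="l1", C_grid=[1e-6], folds=10)
        assert select_features_l1(result) == []

    def test_selection_ordered_by_coefficient_magnitude(self):
        result = ClassifierResult(
            feature_names=("A", "B", "C"),
            scaler=zscale_fit(pd.DataFrame(np.eye(3) + 0.1, columns=list("ABC"))),
            penalty="l1", C=1.0, coefficients=np.array([0.2, -1.5, 0.0]),
            intercept=0.0, cv_results=pd.DataFrame(), train_auc=1.0)
        assert select_features_l1(result) == ["B", "A"]

    def test_stronger_penalty_selects_no_more_features(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(80, 8)),
                         columns=[f"g{i}" for i in range(8)])
        y = ((X.iloc[:, 0] + 0.5 * X.iloc[:, 1]
              + 0.5 * rng.normal(size=80)) > 0).astype(int).to_numpy()
        strong = train_logistic(X, y, penalty="l1", C_grid=[0.01], folds=10)
        weak = train_logistic(X, y, penalty="l1", C_grid=[100.0], folds=10)
        assert len(select_features_l1(strong)) <= len(select_features_l1(weak))


class TestSignatureClassifierAndTimepoints:
    def test_fit_and_evaluate_timepoints_deterministic(self):
        sigs = mi_study.validated_signatures()
        genes = sigs.unique_genes
        shift = {g: 1.5 for g in genes[:8]}
        train = _noise_matrix(genes, 25, 25, seed=1, shift=shift)
        t0 = _noise_matrix(genes, 15, 15, seed=2, shift=shift)
        model = SignatureClassifier(sigs, penalty="l2", folds=10, seed=0)
        result = model.fit(train)
        aucs = evaluate_timepoints(result, {"t0": t0, "t0_again": t0})
        assert aucs["t0"] == aucs["t0_again"]
        assert result.timepoint_auc == aucs
        assert 0.9 < aucs["t0"] <= 1.0
        assert "ROC-AUC" in result.summary()
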