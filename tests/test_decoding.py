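"""Feature assembly, LOOCV, Cohen's kappa and multiclass ROC."""

import numpy as np
import pandas as pd
import pytest

from empathkit.decoding import (
    ClassifierSpec,
    FeatureMatrix,
    assemble_features_study1,
    cohens_kappa,
    ensemble_summary,
    loocv,
    roc_multiclass,
    run_families,
)
from empathkit.errors import InsufficientDataError, ValidationError


def blobs(n_per_class=12, sep=8.0, seed=0, classes=("a", "b")):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, cls in enumerate(classes):
        rows.append(rng.standard_normal((n_per_class, 3)) + k * sep)
        labels += [cls] * n_per_class
    X = np.concatenate(rows)
    return FeatureMatrix(
        features=pd.DataFrame(X, columns=["f1", "f2", "f3"]),
        labels=np.array(labels),
        group_ids=np.arange(len(labels)),
    )


class TestKappa:
    def test_hand_computed_value(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        assert cohens_kappa([[40, 10], [10, 40]]) == pytest.approx(0.6)

    def test_perfect_diagonal(self):
        assert cohens_kappa([[25, 0], [0, 25]]) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        margins_r = np.array([30.0, 70.0])
        margins_c = np.array([40.0, 60.0])
        confusion = np.outer(margins_r, margins_c) / 100.0
        assert cohens_kappa(confusion) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_margins_return_zero(self):
        assert cohens_kappa([[10, 0], [0, 0]]) == 0.0

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import cohen_kappa_score

        y1 = rng.integers(0, 3, 200)
        y2 = rng.integers(0, 3, 200)
        confusion = np.zeros((3, 3))
        for a, b in zip(y1, y2):
            confusion[a, b] += 1
        assert cohens_kappa(confusion) == pytest.approx(
            cohen_kappa_score(y1, y2), abs=1e-12
        )


class TestRocMulticlass:
    def test_one_hot_scores_give_unit_areas(self):
        labels = np.array(["x", "y", "z"] * 4)
        classes = np.array(["x", "y", "z"])
        scores = np.array([[1.0 if c == l else 0.0 for c in classes]
                           for l in labels])
        out = roc_multiclass(scores, labels, classes)
        assert out["macro_auc"] == pytest.approx(1.0)
        assert all(v["auc"] == pytest.approx(1.0)
                   for v in out["per_class"].values())

    def test_label_independent_scores_near_half(self, rng):
        labels = rng.choice(["x", "y"], 400)
        scores = rng.random((400, 2))
        out = roc_multiclass(scores, labels, np.array(["x", "y"]))
        assert out["macro_auc"] == pytest.approx(0.5, abs=0.1)

    def test_degenerate_class_skipped(self):
        labels = np.array(["x", "x", "y"])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7]])
        out = roc_multiclass(scores, labels, np.array(["x", "y", "z"]))
        assert "z" in out["skipped"]


class TestLoocv:
    @pytest.mark.parametrize("family", ["LR", "KNN", "RF", "SVM", "NB"])
    def test_separable_blobs_decode_perfectly(self, family):
        report = loocv(blobs(), ClassifierSpec(family=family, seed=0))
        assert report.accuracy == 100.0
        assert report.kappa == 1.0
        assert report.roc["macro_auc"] == pytest.approx(1.0)

    def test_three_class_case(self):
        report = loocv(blobs(classes=("a", "b", "c")), ClassifierSpec("LR"))
        assert report.accuracy == 100.0
        assert report.confusion.shape == (3, 3)

    def test_fold_count_equals_sample_count(self):
        feats = blobs(n_per_class=5)
        report = loocv(feats, ClassifierSpec("NB"))
        assert len(report.predictions) == feats.n_samples

    def test_kappa_consistent_with_confusion(self):
        feats = blobs(sep=1.0, seed=3)  # overlapping -> imperfect
        report = loocv(feats, ClassifierSpec("KNN"))
        assert report.kappa == pytest.approx(cohens_kappa(report.confusion))
        assert report.accuracy == pytest.approx(
            100.0 * np.trace(report.confusion) / report.confusion.sum()
        )

    def test_stochastic_family_deterministic_under_seed(self):
        feats = blobs(sep=1.0, seed=2)
        a = loocv(feats, ClassifierSpec("RF", seed=5,
                                        hyperparameters={"n_estimators": 30}))
        b = loocv(feats, ClassifierSpec("RF", seed=5,
                                        hyperparameters={"n_estimators": 30}))
        assert np.array_equal(a.predictions, b.predictions)
        assert a.accuracy == b.accuracy

    def test_permuted_labels_hover_at_chance(self, rng):
        """Mean accuracy over permutations must sit inside the Monte-Carlo
        band around 50%."""
        accs = []
        for seed in range(15):
            feats = blobs(n_per_class=12, sep=0.0, seed=seed)
            r = np.random.default_rng(seed)
            feats = FeatureMatrix(features=feats.features,
                                  labels=r.permutation(feats.labels),
                                  group_ids=feats.group_ids)
            accs.append(loocv(feats, ClassifierSpec("NB")).accuracy)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) < max(3 * se, 5.0)

    def test_too_few_per_class_rejected(self):
        feats = blobs(n_per_class=1)
        with pytest.raises(InsufficientDataError):
            loocv(feats, ClassifierSpec("LR"))

    def test_leave_one_participant_out_groups_rows(self):
        feats = blobs(n_per_class=6)
        # pair rows across classes into 6 participants
        feats = FeatureMatrix(features=feats.features, labels=feats.labels,
                              group_ids=np.tile(np.arange(6), 2))
        report = loocv(feats, ClassifierSpec("LR"), by_participant=True)
        assert len(report.predictions) == feats.n_samples

    def test_no_leakage_from_held_out_sample(self):
        """Each held-out prediction equals that of a model refit by hand on
        everything except that sample — the sample never trains its own
        predictor."""
        feats = blobs(sep=1.5, seed=4)
        report = loocv(feats, ClassifierSpec("LR"))
        X = feats.features.to_numpy()
        for i in (0, 5, feats.n_samples - 1):
            train = np.delete(np.arange(feats.n_samples), i)
            model = ClassifierSpec("LR").build(n_classes=2)
            model.fit(X[train], feats.labels[train])
            assert model.predict(X[[i]])[0] == report.predictions[i]


class TestEnsembleSummary:
    def test_mean_arithmetic_and_subsetting(self):
        feats = blobs()
        reports = run_families(feats, families=("LR", "NB", "KNN"), seed=0)
        full = ensemble_summary(reports)
        assert full["mean_accuracy_pct"] == pytest.approx(
            np.mean([r.accuracy for r in reports])
        )
        subset = ensemble_summary(reports, families=("LR", "NB"))
        assert subset["families"] == ["LR", "NB"]

    def test_empty_subset_rejected(self):
        reports = run_families(blobs(), families=("LR",), seed=0)
        with pytest.raises(ValidationError):
            ensemble_summary(reports, families=())


class TestAssembly:
    def test_row_count_bookkeeping(self, tiny_study1):
        from empathkit.erp import baseline_correct, lpp_table, rereference_average
        from empathkit.synth import simulate_epochs_study1, simulate_ratings_study1

        ratings = simulate_ratings_study1(tiny_study1)
        epochs, _ = simulate_epochs_study1(tiny_study1)
        lpp = lpp_table(rereference_average(baseline_correct(epochs)))
        feats = assemble_features_study1(ratings, lpp)
        # participants x 2 stimulation types
        assert feats.n_samples == 6 * 2
        assert list(feats.features.columns) == [
            "rating_self", "rating_other", "early_lpp", "late_lpp"
        ]
        assert set(feats.labels) == {"pain", "nonpain"}

    def test_missing_everything_rejected(self):
        ratings = pd.DataFrame(
            {"participant": [], "tdcs_target": [], "tdcs_type": [], "task": [],
             "stim_type": [], "scale": [], "value": []}
        )
        lpp = pd.DataFrame(
            {"participant": [], "stim_type": [], "early_lpp": [], "late_lpp": []}
        )
        with pytest.raises((InsufficientDataError, KeyError, ValueError)):
            assemble_features_study1(ratings, lpp)
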