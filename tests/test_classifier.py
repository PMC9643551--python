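"""Window classifier: training determinism, cross-validated accuracy,
ensembling, fine-tuning transfer, and recalibration-trial selection."""

import numpy as np
import pytest

from conftest import make_windows
from silentspell.classifier import (
    HAND,
    ClassifierHyperparams,
    ClassifierModel,
    TrialWindow,
    class_set_26,
    class_set_27,
    ensemble_predict,
    ensemble_predict_many,
    select_recalibration_trials,
    stratified_folds,
    train_classifier,
)

FAST = ClassifierHyperparams(epochs=12, patience=12, hidden=16, conv_filters=16)


@pytest.fixture(scope="module")
def small_train(small_synth):
    return make_windows(small_synth, 10, seed=0)


@pytest.fixture(scope="module")
def small_models(small_train, small_synth):
    return [
        train_classifier(small_train, FAST, seed=s, class_set=small_synth.class_set)
        for s in range(3)
    ]


class TestTraining:
    def test_deterministic_given_seed(self, small_synth):
        train = make_windows(small_synth, 4, seed=1, classes=small_synth.class_set[:5])
        hp = ClassifierHyperparams(epochs=3, hidden=8, conv_filters=8)
        m1 = train_classifier(train, hp, seed=7, class_set=small_synth.class_set[:5])
        m2 = train_classifier(train, hp, seed=7, class_set=small_synth.class_set[:5])
        assert m1.meta["val_accuracy"] == m2.meta["val_accuracy"]
        test = make_windows(small_synth, 2, seed=2, classes=small_synth.class_set[:5])
        assert np.array_equal(m1.predict_proba(test), m2.predict_proba(test))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_classifier([], FAST, seed=0)

    def test_label_outside_class_set_rejected(self, small_synth):
        w = make_windows(small_synth, 1, seed=0, classes=["alpha"])
        with pytest.raises(ValueError):
            train_classifier(w, FAST, seed=0, class_set=["bravo", "charlie"])

    def test_cross_validated_accuracy_on_separable_classes(self, small_synth):
        """10-fold accuracy above 90% in the generator's separable regime."""
        classes = small_synth.class_set[:8]
        windows = make_windows(small_synth, 12, seed=3, classes=classes)
        labels = [w.label for w in windows]
        folds = stratified_folds(labels, 10, seed=0)
        hp = ClassifierHyperparams(epochs=30, patience=30, hidden=16, conv_filters=16)
        hits = total = 0
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(len(windows)), test_idx)
            model = train_classifier([windows[i] for i in train_idx], hp,
                                     seed=0, class_set=classes)
            preds = model.predict([windows[i] for i in test_idx])
            hits += sum(p == labels[i] for p, i in zip(preds, test_idx))
            total += len(test_idx)
        assert hits / total > 0.90

    def test_shuffled_labels_fall_to_chance(self, small_synth):
        """27-class chance is 3.7%; label-shuffled training cannot beat it
        by a margin."""
        windows = make_windows(small_synth, 6, seed=4)
        rng = np.random.default_rng(0)
        labels = [w.label for w in windows]
        rng.shuffle(labels)
        shuffled = [TrialWindow(w.features, label=l) for w, l in zip(windows, labels)]
        model = train_classifier(shuffled, FAST, seed=0,
                                 class_set=small_synth.class_set)
        test = make_windows(small_synth, 3, seed=5)
        acc = np.mean([p == w.label for p, w in zip(model.predict(test), test)])
        assert acc < 0.037 * 3 + 0.05  # chance 3.7% within sampling slack

    def test_fine_tuning_transfers_across_correlated_conditions(self, small_synth):
        """Train-on-A / test-on-B accuracy is above chance for correlated
        template sets and increases with the correlation (silent vs overt
        speech attempts)."""
        classes = small_synth.class_set[:6]
        train = make_windows(small_synth, 10, seed=6, classes=classes)
        model = train_classifier(train, FAST, seed=0, class_set=classes)
        accs = {}
        for rho in (0.3, 0.9):
            other = small_synth.variant(rho, seed=17)
            test = make_windows(other, 8, seed=7, classes=classes)
            accs[rho] = np.mean([p == w.label
                                 for p, w in zip(model.predict(test), test)])
        assert accs[0.3] > 1.0 / len(classes)
        assert accs[0.9] > accs[0.3]

    def test_init_from_warm_start(self, small_synth):
        classes = small_synth.class_set[:5]
        a = make_windows(small_synth, 6, seed=8, classes=classes)
        pre = train_classifier(a, FAST, seed=0, class_set=classes)
        fine = train_classifier(a, ClassifierHyperparams(epochs=1, hidden=16,
                                                         conv_filters=16),
                                seed=1, init_from=pre)
        assert fine.class_set == classes

    def test_init_from_class_set_mismatch_rejected(self, small_synth):
        a = make_windows(small_synth, 4, seed=9, classes=["alpha", "bravo"])
        pre = train_classifier(a, FAST, seed=0, class_set=["alpha", "bravo"])
        with pytest.raises(ValueError):
            train_classifier(a, FAST, seed=0, class_set=["alpha", "bravo"],
                             init_from=ClassifierModel(
                                 a[0].features.shape[1], a[0].features.shape[0],
                                 ["x", "y"], FAST, 0))


class TestClassSets:
    def test_27_and_26_class_sets(self):
        assert len(class_set_27()) == 27 and class_set_27()[-1] == HAND
        assert len(class_set_26()) == 26 and HAND not in class_set_26()

    def test_stratified_folds_balanced(self):
        labels = ["a"] * 23 + ["b"] * 21 + ["c"] * 20
        folds = stratified_folds(labels, 10, seed=0)
        assert sorted(np.concatenate(folds).tolist()) == list(range(64))
        for c in "abc":
            per_fold = [sum(labels[i] == c for i in f) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1


class TestEnsembling:
    def test_copies_of_one_model_equal_that_model(self, small_models, small_synth):
        w = make_windows(small_synth, 1, seed=10, classes=["alpha"])[0]
        single = small_models[0].predict_proba([w])[0]
        ens = ensemble_predict([small_models[0]] * 10, w)
        assert np.allclose(ens.probs, single, atol=1e-9)

    def test_probabilities_sum_to_one(self, small_models, small_synth):
        ws = make_windows(small_synth, 2, seed=11)
        for p in ensemble_predict_many(small_models, ws):
            assert abs(p.probs.sum() - 1.0) < 1e-6

    def test_mismatched_class_sets_rejected(self, small_models, small_synth):
        other = ClassifierModel(small_models[0].n_features,
                                small_models[0].n_time, ["x", "y"], FAST, 0)
        w = make_windows(small_synth, 1, seed=12, classes=["alpha"])[0]
        with pytest.raises(ValueError):
            ensemble_predict(small_models + [other], w)

    def test_ensemble_at_least_as_good_as_average_member(self, small_models,
                                                         small_synth):
        test = make_windows(small_synth, 5, seed=13)
        truth = [w.label for w in test]
        singles = []
        for m in small_models:
            preds = m.predict(test)
            singles.append(np.mean([p == t for p, t in zip(preds, truth)]))
        ens_preds = [p.top_class() for p in ensemble_predict_many(small_models, test)]
        ens_acc = np.mean([p == t for p, t in zip(ens_preds, truth)])
        assert ens_acc >= np.mean(singles) - 1e-9


class TestRecalibrationSelection:
    def _trial(self, decoded, truth):
        n = len([c for c in truth if c != " "]) + 1
        windows = [TrialWindow(np.zeros((4, 6))) for _ in range(n)]
        return (decoded, truth, windows)

    def test_perfect_trials_fully_labeled(self):
        out = select_recalibration_trials([self._trial("hi you", "hi you")])
        assert [w.label for w in out] == ["hotel", "india", "yankee", "oscar",
                                         "uniform", HAND]

    def test_single_substitution_excludes_trial(self):
        assert select_recalibration_trials([self._trial("hi yoo", "hi you")]) == []

    def test_mixed_batch_keeps_only_perfect(self):
        trials = [
            self._trial("ok", "ok"),
            self._trial("oks", "ok x"),
            self._trial("no", "no"),
            self._trial("nope", "rope"),
            self._trial("a b", "a c"),
        ]
        out = select_recalibration_trials(trials)
        # two perfect trials: "ok" (3 windows) and "no" (3 windows)
        assert len(out) == 6
        assert all(w.source == "sentence" for w in out)


class TestSerialization:
    def test_model_roundtrip(self, small_models, small_synth, tmp_path):
        m = small_models[0]
        path = str(tmp_path / "model.h5")
        m.save(path)
        m2 = ClassifierModel.load(path)
        ws = make_windows(small_synth, 2, seed=14)
        assert np.array_equal(m.predict_proba(ws), m2.predict_proba(ws))
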