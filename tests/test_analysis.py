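"""Electrode attribution, PCA dimensionality, smoothing sensitivity, and
nearest-class distances."""

import numpy as np
import pytest

from conftest import make_windows
from silentspell.analysis import (
    dimensionality_bootstrap,
    electrode_contributions,
    min_components_for_variance,
    nearest_class_distances,
    smoothing_sweep,
)
from silentspell.classifier import (
    ClassifierHyperparams,
    ClassifierModel,
    TrialWindow,
    train_classifier,
)
from silentspell.synthetic import SyntheticConfig


class TestElectrodeContributions:
    def test_constant_model_gives_zero_map(self, small_synth):
        hp = ClassifierHyperparams(hidden=8, conv_filters=8)
        model = ClassifierModel(2 * small_synth.n_channels, 83,
                                small_synth.class_set, hp, seed=0)
        model.conv.W.value[...] = 0.0  # logits no longer depend on the input
        trials = make_windows(small_synth, 2, seed=0, classes=["alpha"])
        contrib = electrode_contributions(model, trials)
        assert np.allclose(contrib, 0.0)

    def test_map_shape_is_channels_by_two(self):
        hp = ClassifierHyperparams(hidden=8, conv_filters=8)
        model = ClassifierModel(256, 83, ["a", "b"], hp, seed=0)
        trials = [TrialWindow(np.random.default_rng(0).normal(size=(83, 256)),
                              label="a")]
        assert electrode_contributions(model, trials).shape == (128, 2)

    def test_informative_channels_dominate(self, small_synth):
        """A trained model's attribution peaks on generator-designated
        informative channels."""
        classes = small_synth.class_set[:6]
        train = make_windows(small_synth, 12, seed=1, classes=classes)
        model = train_classifier(
            train, ClassifierHyperparams(epochs=30, patience=30, hidden=16,
                                         conv_filters=16),
            seed=0, class_set=classes)
        contrib = electrode_contributions(model, train)
        top_hga = int(np.argmax(contrib[:, 0]))
        top_lfs = int(np.argmax(contrib[:, 1]))
        assert top_hga in small_synth.informative_hga
        assert top_lfs in small_synth.informative_lfs
        assert np.all(contrib >= 0.0)

    def test_unlabeled_trial_rejected(self, small_synth):
        hp = ClassifierHyperparams(hidden=8, conv_filters=8)
        model = ClassifierModel(2 * small_synth.n_channels, 83,
                                small_synth.class_set, hp, seed=0)
        with pytest.raises(ValueError):
            electrode_contributions(model, [TrialWindow(np.zeros((83, 32)))])


class TestMinComponents:
    def test_rank_one_matrix_needs_one(self):
        u = np.outer(np.arange(1, 30, dtype=float), np.ones(5))
        assert min_components_for_variance(u + 0.0, threshold=0.8) == 1

    def test_isotropic_needs_nine_of_ten(self):
        """Ten exactly equal variance shares: 8 components explain exactly
        80%, so strictly exceeding 80% takes 9."""
        rng = np.random.default_rng(0)
        g = rng.normal(size=(200, 10))
        g -= g.mean(axis=0)  # column-centered before orthonormalization
        u, _ = np.linalg.qr(g)
        v, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        x = u @ v.T  # all singular values equal, zero column means
        assert min_components_for_variance(x, threshold=0.8) == 9

    def test_zero_threshold_gives_one(self):
        rng = np.random.default_rng(1)
        assert min_components_for_variance(rng.normal(size=(50, 4)), 0.0) == 1

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            min_components_for_variance(np.zeros((5, 5)))


class TestDimensionalityBootstrap:
    def test_noiseless_distribution_is_degenerate(self):
        sc = SyntheticConfig(n_channels=8, n_informative=2, n_hand_channels=2,
                             noise_sd=0.0, jitter_sd=0.0)
        trials = make_windows(sc, 3, seed=0, classes=sc.class_set[:5])
        counts = dimensionality_bootstrap(trials, "HGA+LFS", "spatial",
                                          n_boot=10, seed=0)
        assert len(set(counts.tolist())) == 1

    def test_seeded_determinism(self, small_synth):
        trials = make_windows(small_synth, 4, seed=1, classes=["alpha", "bravo"])
        a = dimensionality_bootstrap(trials, "LFS", "temporal", n_boot=5, seed=2)
        b = dimensionality_bootstrap(trials, "LFS", "temporal", n_boot=5, seed=2)
        assert np.array_equal(a, b)

    def test_combined_set_needs_at_least_max_of_singles(self, small_synth):
        """With disjoint informative channels, the combined HGA+LFS spatial
        dimensionality bounds each single set's from above."""
        trials = make_windows(small_synth, 8, seed=3,
                              classes=small_synth.class_set[:10])
        counts = {
            fs: dimensionality_bootstrap(trials, fs, "spatial", n_boot=50, seed=4)
            for fs in ("HGA", "LFS", "HGA+LFS")
        }
        both = counts["HGA+LFS"]
        single_max = np.maximum(counts["HGA"], counts["LFS"])
        assert np.mean(both >= single_max) >= 0.95


class TestSmoothingSweep:
    @staticmethod
    def _coded_trials(n_per_class=12, t=40, n_ch=6, seed=0):
        """HGA half amplitude-coded (class offsets, smoothing-proof); LFS
        half temporally coded (class-specific fast patterns)."""
        rng = np.random.default_rng(seed)
        classes = ["c0", "c1", "c2", "c3"]
        patterns = {}
        for c in classes:
            p = np.sign(rng.normal(size=(t, n_ch)))
            patterns[c] = p - p.mean(axis=0)  # zero temporal mean per channel
        offsets = {c: rng.normal(size=n_ch) for c in classes}
        trials = []
        for c in classes:
            for _ in range(n_per_class):
                hga = offsets[c][None, :] + 0.7 * rng.normal(size=(t, n_ch))
                lfs = patterns[c] + 0.7 * rng.normal(size=(t, n_ch))
                trials.append(TrialWindow(np.concatenate([hga, lfs], axis=1),
                                          label=c))
        return trials

    def test_zero_width_equals_unsmoothed_baseline(self):
        trials = self._coded_trials()
        rate = 16.0
        res = smoothing_sweep(trials, [0.0], rate, feature_sets=("HGA+LFS",),
                              cv_folds=4, seed=0)
        res2 = smoothing_sweep(trials, [0.0], rate, feature_sets=("HGA+LFS",),
                               cv_folds=4, seed=0)
        assert res == res2
        assert res["HGA+LFS"][0.0] > 0.5

    def test_heavy_smoothing_destroys_temporal_code(self):
        trials = self._coded_trials()
        rate = 16.0
        res = smoothing_sweep(trials, [0.0, 10.0], rate, feature_sets=("LFS",),
                              cv_folds=4, seed=0)
        assert res["LFS"][10.0] < res["LFS"][0.0] - 0.2
        assert res["LFS"][10.0] < 0.5  # toward 25% chance

    def test_smoothing_harms_temporal_code_more_than_amplitude_code(self):
        trials = self._coded_trials()
        rate = 16.0
        res = smoothing_sweep(trials, [0.0, 1.0], rate,
                              feature_sets=("HGA", "LFS"), cv_folds=4, seed=0)
        drop_hga = res["HGA"][0.0] - res["HGA"][1.0]
        drop_lfs = res["LFS"][0.0] - res["LFS"][1.0]
        assert drop_lfs > drop_hga

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            smoothing_sweep(self._coded_trials(), [-1.0], 16.0)


class TestNearestClassDistances:
    def test_identical_templates_give_zero(self):
        t = np.ones((10, 4))
        trials = [TrialWindow(t, label="a"), TrialWindow(t, label="b")]
        d = nearest_class_distances(trials, n_boot=5, trials_per_class=3, seed=0)
        assert d["a"] == pytest.approx(0.0) and d["b"] == pytest.approx(0.0)

    def test_orthogonal_templates_pythagorean(self):
        a = np.zeros((6, 4))
        a[:, 0] = 2.0
        b = np.zeros((6, 4))
        b[:, 1] = 3.0
        trials = [TrialWindow(a, label="a"), TrialWindow(b, label="b")]
        d = nearest_class_distances(trials, n_boot=3, trials_per_class=2, seed=0)
        expected = np.sqrt(np.sum(a**2) + np.sum(b**2))
        assert d["a"] == pytest.approx(expected)

    def test_code_words_more_distinct_than_letters(self):
        """Longer, unshortened templates (code words) have larger median
        nearest-class distance than the truncated letter templates across
        seeded generator draws."""
        wins = 0
        for seed in range(10):
            kw = dict(n_channels=8, n_informative=3, n_hand_channels=2,
                      template_seed=seed)
            cw = SyntheticConfig(**kw)
            lt = SyntheticConfig(mode="letters", **kw)
            d_cw = nearest_class_distances(
                make_windows(cw, 5, seed=seed, classes=cw.class_set[:12]),
                n_boot=20, trials_per_class=5, seed=0)
            d_lt = nearest_class_distances(
                make_windows(lt, 5, seed=seed, classes=lt.class_set[:12]),
                n_boot=20, trials_per_class=5, seed=0)
            wins += np.median(list(d_cw.values())) > np.median(list(d_lt.values()))
        assert wins >= 9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            nearest_class_distances([TrialWindow(np.ones((3, 2)), label="a")])
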