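"""Neural-feature characterizations of the trained decoder and features.

Covers gradient-based electrode attribution, bootstrapped PCA
dimensionality of the spatial and temporal structure of trial-averaged
responses, the effect of temporal smoothing on decodability, and
nearest-class Frobenius distances between class templates.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import LogisticRegression

from .classifier import ClassifierModel, TrialWindow, stratified_folds

__all__ = [
    "electrode_contributions",
    "min_components_for_variance",
    "dimensionality_bootstrap",
    "smoothing_sweep",
    "nearest_class_distances",
]

FEATURE_SETS = ("HGA", "LFS", "HGA+LFS")


def _select(features: np.ndarray, feature_set: str) -> np.ndarray:
    """Slice the HGA half, LFS half, or keep both (time x feature)."""
    n = features.shape[-1] // 2
    if feature_set == "HGA":
        return features[..., :n]
    if feature_set == "LFS":
        return features[..., n:]
    if feature_set == "HGA+LFS":
        return features
    raise ValueError(f"unknown feature set {feature_set!r}")


def electrode_contributions(
    model: ClassifierModel, trials: list[TrialWindow], batch_size: int = 128
) -> np.ndarray:
    """Gradient attribution map of shape (channels, 2): columns HGA, LFS.

    Computes the derivative of the classification loss with respect to the
    input features across time, takes the L2 norm over time per feature,
    and averages over trials.  Non-negative by construction.
    """
    if any(t.label is None for t in trials):
        raise ValueError("all trials must be labeled")
    n_feat = trials[0].features.shape[1]
    if n_feat % 2:
        raise ValueError("feature count must be 2 x channel count")
    acc = np.zeros(n_feat)
    for i in range(0, len(trials), batch_size):
        batch = trials[i : i + batch_size]
        grads = model.input_gradients(batch)  # (b, time, feature)
        acc += np.linalg.norm(grads, axis=1).sum(axis=0)
    contrib = acc / len(trials)
    n = n_feat // 2
    return np.stack([contrib[:n], contrib[n:]], axis=1)


def min_components_for_variance(matrix: np.ndarray, threshold: float = 0.8) -> int:
    """Smallest number of principal components explaining strictly more than
    ``threshold`` of the total variance.

    Rows are observations, columns are variables; columns are mean-centered
    before the decomposition.
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("need a 2-D matrix")
    xc = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    var = s * s
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has no variance")
    frac = np.cumsum(var) / total
    # tolerance so an exact tie (e.g. equal eigenvalue shares) does not
    # count as "strictly more" through float rounding
    return int(np.argmax(frac > threshold + 1e-9)) + 1


def _trial_average(
    trials: list[TrialWindow], rng: np.random.Generator | None
) -> dict[str, np.ndarray]:
    """Per-class trial averages; with an rng, trials are resampled with
    replacement per class (bootstrap semantics)."""
    by_class: dict[str, list[np.ndarray]] = {}
    for t in trials:
        by_class.setdefault(t.label, []).append(t.features)
    out = {}
    for c, feats in by_class.items():
        arr = np.stack(feats)
        if rng is not None:
            idx = rng.integers(0, len(arr), size=len(arr))
            arr = arr[idx]
        out[c] = arr.mean(axis=0)
    return out


def dimensionality_bootstrap(
    trials: list[TrialWindow],
    feature_set: str = "HGA+LFS",
    axis: str = "spatial",
    n_boot: int = 100,
    threshold: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Distribution of PC counts over bootstrap resamples of trial averages.

    Per iteration: resample trials with replacement within each class,
    trial-average, then arrange the averages as features x (time*classes)
    for the spatial axis or time x (features*classes) for the temporal
    axis, and count the PCs needed to pass the variance threshold.
    """
    if axis not in ("spatial", "temporal"):
        raise ValueError("axis must be 'spatial' or 'temporal'")
    if not trials:
        raise ValueError("no trials")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        averages = _trial_average(trials, rng)
        mats = [_select(m, feature_set) for m in averages.values()]  # each (T, N)
        if axis == "spatial":
            # variables = features; observations = time points of each class
            x = np.concatenate(mats, axis=0)  # (T*C, N)
        else:
            # variables = time points; observations = feature traces
            x = np.concatenate([m.T for m in mats], axis=0)  # (N*C, T)
        counts[b] = min_components_for_variance(x, threshold)
    return counts


def smoothing_sweep(
    trials: list[TrialWindow],
    widths_s: list[float],
    rate: float,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    cv_folds: int = 10,
    seed: int = 0,
) -> dict[str, dict[float, float]]:
    """Cross-validated accuracy after Gaussian temporal smoothing.

    ``widths_s`` are filter standard deviations in seconds (0 = no
    smoothing); kernels are truncated at 4 SDs.  The probe classifier is a
    multinomial logistic regression on the flattened window, which is fast
    enough to sweep and sensitive to the same temporal-resolution loss.
    """
    if any(w < 0 for w in widths_s):
        raise ValueError("widths must be nonnegative")
    labels = [t.label for t in trials]
    classes = sorted(set(labels))
    y = np.array([classes.index(label) for label in labels])
    folds = stratified_folds(labels, cv_folds, seed)
    x0 = np.stack([t.features for t in trials])
    results: dict[str, dict[float, float]] = {fs: {} for fs in feature_sets}
    for width in widths_s:
        if width > 0:
            xs = gaussian_filter1d(x0, width * rate, axis=1, mode="reflect", truncate=4.0)
        else:
            xs = x0
        for fs in feature_sets:
            xf = _select(xs, fs).reshape(len(trials), -1)
            correct = 0
            for k, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(np.arange(len(trials)), test_idx)
                clf = LogisticRegression(max_iter=200, C=1.0)
                clf.fit(xf[train_idx], y[train_idx])
                correct += int(np.sum(clf.predict(xf[test_idx]) == y[test_idx]))
            results[fs][width] = correct / len(trials)
    return results


def nearest_class_distances(
    trials: list[TrialWindow],
    classes: list[str] | None = None,
    n_boot: int = 1000,
    trials_per_class: int = 47,
    seed: int = 0,
) -> dict[str, float]:
    """Per-class minimum Frobenius distance to any other class template.

    Templates are averages over ``n_boot`` bootstrap iterations, each
    drawing ``trials_per_class`` trials with replacement; classes with fewer
    trials are simply resampled (bootstrap semantics).
    """
    by_class: dict[str, np.ndarray] = {}
    for t in trials:
        by_class.setdefault(t.label, []).append(t.features)
    if classes is None:
        classes = sorted(by_class)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    templates = {}
    for c in classes:
        arr = np.stack(by_class[c])
        acc = np.zeros_like(arr[0])
        for _ in range(n_boot):
            idx = rng.integers(0, len(arr), size=trials_per_class)
            acc += arr[idx].mean(axis=0)
        templates[c] = acc / n_boot
    out = {}
    for c in classes:
        d = min(
            float(np.linalg.norm(templates[c] - templates[o]))
            for o in classes
            if o != c
        )
        out[c] = d
    return out
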