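"""End-to-end SCCSP method and the CSP / ICA-CSP baselines.

The SCCSP flow per fit: band-pass (5-30 Hz, 4th-order Butterworth,
zero-phase) -> imagery window -> hemisphere split -> amplitude spectra of
the training trials -> spectral infomax per hemisphere (2 components) ->
demix every trial into the 4-row component matrix ``Y_k = [Y1l, Y2l, Y1r,
Y2r]`` -> CSP simultaneous diagonalization -> variance-ratio feature f ->
RBF-kernel SVM.  The CSP baseline skips the hemisphere split and ICA and
projects all channels directly; the ICA-CSP baseline fits infomax on
time-domain hemisphere signals (samples as observations) instead of
amplitude spectra.

Evaluation protocols: K-fold cross-validation with K = floor(n/2)
(stratified pairs, every trial tested exactly once), a half/half holdout,
and a learning-curve experiment over training-set sizes 2..50.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from . import csp_core, sica
from .errors import ConfigError, ValidationError
from .evaluation import EvalReport, accuracy
from .preprocess_io import (
    EpochSet,
    HemisphereSplit,
    bandpass_filter,
    extract_window,
    split_hemispheres,
)

__all__ = [
    "PipelineConfig",
    "ComponentEpochs",
    "FittedMethod",
    "fit_sccsp",
    "fit_csp_baseline",
    "fit_ica_csp_baseline",
    "fit_method",
    "predict",
    "crossvalidate",
    "holdout",
    "learning_curve",
    "make_cv_folds",
    "default_learning_sizes",
]

METHODS = ("sccsp", "csp", "ica_csp")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the full pipeline (all stages)."""

    band: tuple[float, float] = (5.0, 30.0)
    filter_order: int = 4
    zero_phase: bool = True
    window: tuple[float, float] | None = None
    split: HemisphereSplit | str = "auto"
    ica_lr: float = 0.01
    ica_max_iter: int = 500
    ica_tol: float = 1e-7
    ica_max_obs: int | None = 4096
    ica_fit_scope: str = "train-concat"  # or "per-trial"
    mu_band: tuple[float, float] = (8.0, 12.0)
    csp_n_pairs: int = 1
    csp_variance: str = "unbiased"
    svm_C: float = 1.0
    svm_gamma: float | str = "median"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ica_fit_scope not in ("train-concat", "per-trial"):
            raise ConfigError(f"unknown ica_fit_scope {self.ica_fit_scope!r}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if isinstance(self.split, HemisphereSplit):
            d["split"] = {
                "left_idx": self.split.left_idx,
                "right_idx": self.split.right_idx,
                "excluded_idx": self.split.excluded_idx,
            }
        return d


@dataclass(frozen=True)
class ComponentEpochs:
    """Per-trial 4 x T integrated temporal components [Y1l, Y2l, Y1r, Y2r]."""

    data: np.ndarray  # (trials, 4, samples), hemisphere-major
    labels: np.ndarray | None
    provenance: str  # "sccsp" or "ica_csp"

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != 4:
            raise ValidationError("ComponentEpochs data must be (trials, 4, samples)")


@dataclass(frozen=True)
class FittedMethod:
    """Frozen preprocessing + (optional) ICA + CSP + classifier state."""

    method: str
    config: PipelineConfig
    channel_names: tuple[str, ...]
    split: HemisphereSplit | None
    ica_left: sica.SpectralICAModel | None
    ica_right: sica.SpectralICAModel | None
    csp_model: csp_core.CSPModel
    classifier: SVC
    train_features: np.ndarray  # scalar f per training trial
    train_labels: np.ndarray
    train_accuracy: float


# ---------------------------------------------------------------------------
# preparation: per-trial, fold-independent transforms
# ---------------------------------------------------------------------------

@dataclass
class _Prepared:
    method: str
    cfg: PipelineConfig
    fs: float
    labels: np.ndarray | None
    channel_names: tuple[str, ...]
    split: HemisphereSplit | None
    full: np.ndarray | None  # (n, g, T), csp baseline
    left: np.ndarray | None  # (n, m_l, T)
    right: np.ndarray | None
    left_spectra: list | None  # per-trial AmplitudeSpectrum (sccsp)
    right_spectra: list | None

    @property
    def n_trials(self) -> int:
        arr = self.full if self.full is not None else self.left
        return arr.shape[0]


def _resolve_split(epochs: EpochSet, cfg: PipelineConfig) -> HemisphereSplit:
    if isinstance(cfg.split, HemisphereSplit):
        return cfg.split
    left, _ = split_hemispheres(epochs, cfg.split)  # validates; discard copies
    # recompute the index sets explicitly so the fitted model is portable
    from .preprocess_io import _auto_split

    return _auto_split(epochs.channel_positions)


def _prepare(epochs: EpochSet, method: str, cfg: PipelineConfig) -> _Prepared:
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; expected one of {METHODS}")
    filtered = bandpass_filter(
        epochs, cfg.band[0], cfg.band[1], cfg.filter_order, zero_phase=cfg.zero_phase
    )
    if cfg.window is not None:
        filtered = extract_window(filtered, cfg.window[0], cfg.window[1])
    if method == "csp":
        return _Prepared(
            method=method, cfg=cfg, fs=filtered.fs, labels=filtered.labels,
            channel_names=filtered.channel_names, split=None,
            full=filtered.data, left=None, right=None,
            left_spectra=None, right_spectra=None,
        )
    split = _resolve_split(filtered, cfg)
    left_ep, right_ep = split_hemispheres(filtered, split)
    left_spectra = right_spectra = None
    if method == "sccsp":
        left_spectra = [
            sica.amplitude_spectrum(left_ep.data[k], filtered.fs)
            for k in range(left_ep.n_trials)
        ]
        right_spectra = [
            sica.amplitude_spectrum(right_ep.data[k], filtered.fs)
            for k in range(right_ep.n_trials)
        ]
    return _Prepared(
        method=method, cfg=cfg, fs=filtered.fs, labels=filtered.labels,
        channel_names=filtered.channel_names, split=split,
        full=None, left=left_ep.data, right=right_ep.data,
        left_spectra=left_spectra, right_spectra=right_spectra,
    )


def _fit_hemisphere_ica(
    prep: _Prepared, hemi: str, train_idx: np.ndarray, seed: int
) -> sica.SpectralICAModel:
    cfg = prep.cfg
    kwargs = dict(
        n_components=2, seed=seed, lr=cfg.ica_lr, max_iter=cfg.ica_max_iter,
        tol=cfg.ica_tol, max_obs=cfg.ica_max_obs, mu_band=cfg.mu_band,
        hemisphere=hemi,
    )
    if prep.method == "sccsp":
        spectra = prep.left_spectra if hemi == "left" else prep.right_spectra
        return sica.fit_infomax([spectra[i] for i in train_idx], **kwargs)
    # ica_csp: time-domain infomax, samples as observations
    data = prep.left if hemi == "left" else prep.right
    concat = np.concatenate([data[i] for i in train_idx], axis=1)
    return sica.fit_infomax(concat, **kwargs)


def _per_trial_components(prep: _Prepared, idx: np.ndarray, seed: int) -> np.ndarray:
    """Literal per-trial ICA reading: one W per trial, canonical order/sign."""
    out = []
    for i in idx:
        mdl_l = _fit_hemisphere_ica(prep, "left", np.array([i]), seed)
        mdl_r = _fit_hemisphere_ica(prep, "right", np.array([i]), seed)
        out.append(
            np.vstack(
                [
                    sica.apply_components(mdl_l, prep.left[i]),
                    sica.apply_components(mdl_r, prep.right[i]),
                ]
            )
        )
    return np.stack(out)


@dataclass
class _Models:
    ica_left: sica.SpectralICAModel | None
    ica_right: sica.SpectralICAModel | None
    csp_model: csp_core.CSPModel
    classifier: SVC


def _components(prep: _Prepared, models: _Models | None, idx: np.ndarray) -> np.ndarray:
    if prep.method == "csp":
        return prep.full[idx]
    if prep.cfg.ica_fit_scope == "per-trial":
        return _per_trial_components(prep, idx, prep.cfg.seed)
    out = []
    for i in idx:
        out.append(
            np.vstack(
                [
                    sica.apply_components(models.ica_left, prep.left[i]),
                    sica.apply_components(models.ica_right, prep.right[i]),
                ]
            )
        )
    return np.stack(out)


def _feature_matrix(prep: _Prepared, csp_model, comps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(classifier features, scalar f per trial)."""
    cfg = prep.cfg
    f = np.array(
        [csp_core.feature(csp_model, c, cfg.csp_variance) for c in comps]
    )
    if cfg.csp_n_pairs == 1:
        X = f[:, None]
    else:
        X = np.stack(
            [
                csp_core.feature_vector(csp_model, c, cfg.csp_n_pairs, cfg.csp_variance)
                for c in comps
            ]
        )
    return X, f


def _median_gamma(X: np.ndarray) -> float:
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    d = d[np.triu_indices_from(d, k=1)]
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    sigma = float(np.median(d))
    return 1.0 / (2.0 * sigma**2)


def _fit_on_indices(prep: _Prepared, train_idx: np.ndarray, ica_seed: int) -> _Models:
    labels = prep.labels[train_idx]
    if len(np.unique(labels)) < 2:
        raise ValidationError("training set lost a class entirely")
    ica_left = ica_right = None
    if prep.method != "csp" and prep.cfg.ica_fit_scope == "train-concat":
        ica_left = _fit_hemisphere_ica(prep, "left", train_idx, ica_seed)
        ica_right = _fit_hemisphere_ica(prep, "right", train_idx, ica_seed)
    models = _Models(ica_left, ica_right, None, None)
    comps = _components(prep, models, train_idx)
    classes = np.unique(labels)
    c1 = csp_core.class_covariance([comps[i] for i in np.flatnonzero(labels == classes[0])])
    c2 = csp_core.class_covariance([comps[i] for i in np.flatnonzero(labels == classes[1])])
    models.csp_model = csp_core.simultaneous_diagonalize(c1, c2)
    X, _ = _feature_matrix(prep, models.csp_model, comps)
    gamma = prep.cfg.svm_gamma
    if gamma == "median":
        gamma = _median_gamma(X)
    clf = SVC(C=prep.cfg.svm_C, kernel="rbf", gamma=gamma)
    clf.fit(X, labels)
    models.classifier = clf
    return models


# ---------------------------------------------------------------------------
# public fitting / prediction API
# ---------------------------------------------------------------------------

def fit_method(train: EpochSet, method: str, config: PipelineConfig | None = None) -> FittedMethod:
    """Fit one of the three methods on a labeled two-class training set."""
    config = config or PipelineConfig()
    if train.labels is None:
        raise ValidationError("fit requires a labeled EpochSet")
    _, counts = np.unique(train.labels, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("need at least 2 trials per class in the training set")
    prep = _prepare(train, method, config)
    idx = np.arange(prep.n_trials)
    models = _fit_on_indices(prep, idx, config.seed)
    comps = _components(prep, models, idx)
    X, f = _feature_matrix(prep, models.csp_model, comps)
    train_pred = models.classifier.predict(X)
    return FittedMethod(
        method=method,
        config=config,
        channel_names=prep.channel_names,
        split=prep.split,
        ica_left=models.ica_left,
        ica_right=models.ica_right,
        csp_model=models.csp_model,
        classifier=models.classifier,
        train_features=f,
        train_labels=prep.labels.copy(),
        train_accuracy=accuracy(train_pred, prep.labels),
    )


def fit_sccsp(train: EpochSet, config: PipelineConfig | None = None) -> FittedMethod:
    """Spectral-component CSP: spectral infomax per hemisphere, then CSP."""
    return fit_method(train, "sccsp", config)


def fit_csp_baseline(train: EpochSet, config: PipelineConfig | None = None) -> FittedMethod:
    """Conventional CSP: band-pass only, projection on all channels."""
    return fit_method(train, "csp", config)


def fit_ica_csp_baseline(train: EpochSet, config: PipelineConfig | None = None) -> FittedMethod:
    """ICA-CSP: temporal infomax per hemisphere, then CSP."""
    return fit_method(train, "ica_csp", config)


def predict(model: FittedMethod, test: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Apply the frozen transforms and classifier; returns (labels, f values)."""
    if tuple(test.channel_names) != tuple(model.channel_names):
        raise ValidationError(
            "test montage does not match the montage the model was fitted on"
        )
    cfg = model.config
    if model.split is not None and not isinstance(cfg.split, HemisphereSplit):
        cfg = replace(cfg, split=model.split)
    prep = _prepare(test, model.method, cfg)
    models = _Models(model.ica_left, model.ica_right, model.csp_model, model.classifier)
    comps = _components(prep, models, np.arange(prep.n_trials))
    X, f = _feature_matrix(prep, model.csp_model, comps)
    return model.classifier.predict(X), f


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def make_cv_folds(labels: np.ndarray, seed: int = 0, max_attempts: int = 100) -> list[np.ndarray]:
    """Stratified K = floor(n/2) folds; each trial tested exactly once.

    Folds pair one trial of each class whenever counts allow; the
    construction scans a seeded permutation and is symmetric under
    relabeling the two classes.  Redraws (up to ``max_attempts``) if some
    fold would leave a class absent from its training complement.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 4:
        raise ConfigError("cross-validation needs at least 4 trials")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("labels must contain exactly 2 classes")
    K = n // 2
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        qa = [int(i) for i in perm if labels[i] == classes[0]]
        qb = [int(i) for i in perm if labels[i] == classes[1]]
        folds: list[list[int]] = []
        while qa and qb and len(folds) < K:
            folds.append([qa.pop(0), qb.pop(0)])
        leftovers = qa + qb
        while len(leftovers) >= 2 and len(folds) < K:
            folds.append([leftovers.pop(0), leftovers.pop(0)])
        for j, x in enumerate(leftovers):
            folds[-1 - (j % len(folds))].append(x)
        ok = all(
            len(np.unique(np.delete(labels, f))) == 2 for f in folds
        )
        if ok:
            return [np.asarray(sorted(f)) for f in folds]
    raise ConfigError(
        f"could not draw a valid K={K} fold partition in {max_attempts} attempts"
    )


def _evaluate_folds(
    prep: _Prepared, folds: list[np.ndarray], seed: int
) -> EvalReport:
    n = prep.n_trials
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=len(folds))
    all_idx = np.arange(n)
    predictions = np.zeros(n, dtype=np.int64)
    fvals = np.zeros(n)
    per_fold = []
    fold_accs = []
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        models = _fit_on_indices(prep, train_idx, int(fold_seeds[j]))
        comps = _components(prep, models, test_idx)
        X, f = _feature_matrix(prep, models.csp_model, comps)
        pred = models.classifier.predict(X)
        predictions[test_idx] = pred
        fvals[test_idx] = f
        acc = accuracy(pred, prep.labels[test_idx])
        fold_accs.append(acc)
        per_fold.append(
            {"fold": j, "test_idx": [int(i) for i in test_idx], "accuracy": acc}
        )
    classes = np.unique(prep.labels)
    return EvalReport.from_predictions(
        predictions,
        prep.labels,
        fvals[prep.labels == classes[0]],
        fvals[prep.labels == classes[1]],
        fold_accs,
        per_fold,
        config=prep.cfg.to_dict() | {"method": prep.method},
    )


def crossvalidate(
    epochs: EpochSet,
    method: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """K-fold cross-validation with K = floor(n/2).

    Every trial is used for training and for testing exactly once; all
    fitted transforms (ICA demixing, CSP filter, classifier) derive from the
    training folds only.
    """
    config = config or PipelineConfig()
    if epochs.labels is None:
        raise ValidationError("cross-validation requires labels")
    prep = _prepare(epochs, method, config)
    folds = make_cv_folds(prep.labels, seed)
    return _evaluate_folds(prep, folds, seed)


def holdout(
    epochs: EpochSet,
    method: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
    fraction: float = 0.5,
) -> EvalReport:
    """Single stratified train/test split (default half/half)."""
    config = config or PipelineConfig()
    if epochs.labels is None:
        raise ValidationError("holdout requires labels")
    if not 0 < fraction < 1:
        raise ConfigError("fraction must be in (0, 1)")
    prep = _prepare(epochs, method, config)
    rng = np.random.default_rng(seed)
    train_parts = []
    for c in np.unique(prep.labels):
        idx = rng.permutation(np.flatnonzero(prep.labels == c))
        train_parts.append(idx[: max(2, int(round(fraction * idx.size)))])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.setdiff1d(np.arange(prep.n_trials), train_idx)
    models = _fit_on_indices(prep, train_idx, config.seed)
    comps = _components(prep, models, test_idx)
    X, f = _feature_matrix(prep, models.csp_model, comps)
    pred = models.classifier.predict(X)
    classes = np.unique(prep.labels)
    test_labels = prep.labels[test_idx]
    return EvalReport.from_predictions(
        pred,
        test_labels,
        f[test_labels == classes[0]],
        f[test_labels == classes[1]],
        [accuracy(pred, test_labels)],
        config=config.to_dict() | {"method": method, "protocol": "holdout"},
    )


def default_learning_sizes() -> list[int]:
    """Ten training-set sizes spanning 2..50."""
    return [int(x) for x in np.round(np.linspace(2, 50, 10))]


def learning_curve(
    epochs: EpochSet,
    method: str,
    sizes: Sequence[int] | None = None,
    repeats: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> list[dict]:
    """Accuracy as a function of training-set size.

    For each size, ``repeats`` random class-balanced training subsets are
    drawn; the model is fitted on each subset and tested on all remaining
    trials.  Returns one record per size with mean and standard deviation
    of the test accuracy.
    """
    config = config or PipelineConfig()
    if epochs.labels is None:
        raise ValidationError("learning_curve requires labels")
    sizes = list(sizes) if sizes is not None else default_learning_sizes()
    n = epochs.n_trials
    if min(sizes) < 2:
        raise ConfigError("every size must be >= 2")
    if max(sizes) >= n:
        raise ConfigError(f"max size {max(sizes)} must be below the trial count {n}")
    prep = _prepare(epochs, method, config)
    rng = np.random.default_rng(seed)
    classes = np.unique(prep.labels)
    by_class = [np.flatnonzero(prep.labels == c) for c in classes]
    rows = []
    for size in sizes:
        accs = []
        for _ in range(repeats):
            n_a = size // 2 + (size % 2) * int(rng.integers(2))
            n_b = size - n_a
            n_a = min(n_a, by_class[0].size - 1)
            n_b = min(n_b, by_class[1].size - 1)
            if min(n_a, n_b) < 1:
                raise ConfigError(f"size {size} cannot be drawn class-balanced")
            train_idx = np.sort(
                np.concatenate(
                    [
                        rng.choice(by_class[0], n_a, replace=False),
                        rng.choice(by_class[1], n_b, replace=False),
                    ]
                )
            )
            test_idx = np.setdiff1d(np.arange(n), train_idx)
            models = _fit_on_indices(prep, train_idx, int(rng.integers(2**31 - 1)))
            comps = _components(prep, models, test_idx)
            X, _ = _feature_matrix(prep, models.csp_model, comps)
            pred = models.classifier.predict(X)
            accs.append(accuracy(pred, prep.labels[test_idx]))
        accs = np.asarray(accs)
        rows.append(
            {
                "size": int(size),
                "mean_accuracy": float(accs.mean()),
                "sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
            }
        )
    return rows
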