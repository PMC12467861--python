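"""End-to-end training and evaluation protocols.

The central estimator is :class:`IntentPipeline` — standardize, reduce
(kernel PCA by default), classify (RBF SVM with metaheuristic-tuned C and
g) — in three variants:

``kpca_issa_svm``
    z-score -> kernel PCA (95% contribution retention) -> SVM with (C, g)
    tuned by the improved sparrow search on 5-fold CV accuracy.
``pca_svm``
    z-score -> linear PCA (same retention rule) -> SVM tuned by grid search.
``svm``
    z-score -> SVM on raw features, grid-search tuned.

Around it sit the evaluation protocols: trial-level stratified bootstrap
with percentile confidence intervals, confusion matrices in the canonical
13-mode order, SNR robustness sweeps (train clean, test noisy), modality
ablation, and streaming per-window prediction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix, extract_features
from .issa import SsaConfig, optimize
from .kpca import GaitKPCA
from .modes import MODE_CODES
from .preprocess import (
    design_imu_filter,
    design_semg_filters,
    segment,
    zero_phase_filter,
)
from .svm import (
    LOG_C_BOUNDS,
    LOG_G_BOUNDS,
    RbfSvmClassifier,
    decode_position,
    default_search_space,
    make_cv_fitness,
)
from .synth import Recording, inject_awgn

__all__ = [
    "IntentPipeline",
    "EvalReport",
    "preprocess_recording",
    "recording_features",
    "dataset_features",
    "train_pipeline",
    "bootstrap_evaluate",
    "confusion",
    "snr_sweep",
    "modality_ablation",
    "stream_predict",
]

VARIANTS = ("kpca_issa_svm", "pca_svm", "svm")


# ---------------------------------------------------------------------------
# signal -> features


def preprocess_recording(rec: Recording):
    """Zero-phase filter both modalities and cut the 100 ms window grid."""
    bandpass, notch = design_semg_filters(rec.fs_semg)
    lowpass = design_imu_filter(rec.fs_imu)
    semg = zero_phase_filter(zero_phase_filter(rec.semg, bandpass), notch)
    imu = zero_phase_filter(rec.imu, lowpass)
    ws_semg = segment(semg, rec.fs_semg, labels=rec.window_labels)
    ws_imu = segment(imu, rec.fs_imu, labels=rec.window_labels)
    n = min(ws_semg.n_windows, ws_imu.n_windows)
    ws_semg.windows = ws_semg.windows[:, :n]
    ws_imu.windows = ws_imu.windows[:, :n]
    ws_semg.labels = ws_semg.labels[:n]
    ws_imu.labels = ws_imu.labels[:n]
    return ws_semg, ws_imu


def recording_features(rec: Recording, modality: str = "fusion") -> FeatureMatrix:
    """Preprocess one recording and extract its per-window feature matrix."""
    ws_semg, ws_imu = preprocess_recording(rec)
    return extract_features(ws_semg, ws_imu, modality=modality)


def dataset_features(
    dataset: list[Recording], modality: str = "fusion"
) -> tuple[FeatureMatrix, np.ndarray]:
    """Features for a whole dataset plus the trial index of every window."""
    mats, trial_ids = [], []
    for i, rec in enumerate(dataset):
        fm = recording_features(rec, modality=modality)
        mats.append(fm)
        trial_ids.append(np.full(fm.values.shape[0], i))
    merged = FeatureMatrix(
        values=np.vstack([m.values for m in mats]),
        names=mats[0].names,
        labels=[lab for m in mats for lab in m.labels],
        modality_mask=mats[0].modality_mask,
    )
    return merged, np.concatenate(trial_ids)


# ---------------------------------------------------------------------------
# the estimator


class IntentPipeline(BaseEstimator, ClassifierMixin):
    """Locomotion-intent classifier: standardizer -> reducer -> RBF SVM.

    Parameters
    ----------
    variant : {"kpca_issa_svm", "pca_svm", "svm"}
        Reduction and tuning strategy (see module docstring).
    variance_threshold : float, default 0.95
        Cumulative contribution-rate retention for KPCA and PCA alike.
    sigma : float or "median", default "median"
        KPCA bandwidth (median heuristic by default).
    issa_pop_size, issa_max_iter : int
        Sparrow-search budget for (C, g) tuning.
    tuning_max_samples : int, default 390
        Stratified cap on the CV-fitness tuning subset (full training data
        is always used for the final SVM fit).
    k_folds : int, default 5
        Stratified CV folds inside the tuning fitness.
    seed : int, default 0
        Controls tuning subsampling, CV shuffling and the optimizer.

    Attributes
    ----------
    scaler_ : fitted StandardScaler
    reducer_ : fitted GaitKPCA or PCA, or None for the plain-SVM variant
    svm_ : fitted RbfSvmClassifier
    hyperparams_ : the tuned (C, g)
    tuning_fitness_ : CV accuracy of the selected hyperparameters
    training_accuracy_ : accuracy on its own training windows
    """

    def __init__(
        self,
        variant: str = "kpca_issa_svm",
        variance_threshold: float = 0.95,
        sigma: float | str = "median",
        issa_pop_size: int = 10,
        issa_max_iter: int = 15,
        tuning_max_samples: int = 390,
        k_folds: int = 5,
        seed: int = 0,
    ):
        self.variant = variant
        self.variance_threshold = variance_threshold
        self.sigma = sigma
        self.issa_pop_size = issa_pop_size
        self.issa_max_iter = issa_max_iter
        self.tuning_max_samples = tuning_max_samples
        self.k_folds = k_folds
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _reduce_fit(self, X: np.ndarray) -> np.ndarray:
        if self.variant == "kpca_issa_svm":
            self.reducer_ = GaitKPCA(
                sigma=self.sigma, variance_threshold=self.variance_threshold
            )
            return self.reducer_.fit_transform(X)
        if self.variant == "pca_svm":
            self.reducer_ = PCA(n_components=self.variance_threshold, svd_solver="full")
            return self.reducer_.fit_transform(X)
        self.reducer_ = None
        return X

    def _tune(self, Z: np.ndarray, y: np.ndarray) -> tuple:
        fitness = make_cv_fitness(
            Z, y, k_folds=self.k_folds, seed=self.seed,
            max_samples=self.tuning_max_samples,
        )
        if self.variant == "kpca_issa_svm":
            cfg = SsaConfig(
                pop_size=self.issa_pop_size,
                max_iter=self.issa_max_iter,
                seed=self.seed,
            )
            res = optimize(fitness, default_search_space(), cfg, variant="issa")
            return decode_position(res.best_position), res.best_fitness
        # grid search baseline: integer log10 steps over the same box
        best, best_f = None, -np.inf
        for lc in np.arange(LOG_C_BOUNDS[0], LOG_C_BOUNDS[1] + 0.5):
            for lg in np.arange(LOG_G_BOUNDS[0], LOG_G_BOUNDS[1] + 0.5):
                f = fitness(np.array([lc, lg]))
                if f > best_f:
                    best, best_f = np.array([lc, lg]), f
        return decode_position(best), best_f

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.scaler_ = StandardScaler()
        Xs = self.scaler_.fit_transform(X)
        Z = self._reduce_fit(Xs)
        self.hyperparams_, self.tuning_fitness_ = self._tune(Z, y)
        self.svm_ = RbfSvmClassifier(C=self.hyperparams_.C, g=self.hyperparams_.g)
        self.svm_.fit(Z, y)
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = X.shape[1]
        self.training_accuracy_ = float(np.mean(self.svm_.predict(Z) == y))
        return self

    def _transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = self.scaler_.transform(X)
        return self.reducer_.transform(Xs) if self.reducer_ is not None else Xs

    def predict(self, X):
        check_is_fitted(self, "svm_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.svm_.predict(self._transform(X))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train_pipeline(
    dataset: list[Recording],
    modality: str = "fusion",
    variant: str = "kpca_issa_svm",
    seed: int = 0,
    **pipeline_params,
) -> IntentPipeline:
    """Extract features from a dataset and fit an :class:`IntentPipeline`."""
    if not dataset:
        raise ValueError("empty dataset")
    fm, _ = dataset_features(dataset, modality=modality)
    if np.unique(fm.y).size < 2:
        raise ValueError("dataset must cover at least 2 locomotion modes")
    pipe = IntentPipeline(variant=variant, seed=seed, **pipeline_params)
    pipe.fit(fm.values, fm.y)
    pipe.modality_ = modality
    return pipe


# ---------------------------------------------------------------------------
# evaluation protocols


@dataclass
class EvalReport:
    """Bootstrap evaluation summary.

    Accuracies are fractions in [0, 1]; ``confusion_`` rows (true modes,
    canonical order) are normalized to sum to 1 where non-empty.
    """

    accuracies: np.ndarray
    median_accuracy: float
    ci_low: float
    ci_high: float
    per_mode_accuracy: dict
    overall_accuracy: float
    confusion_matrix: np.ndarray
    n_iterations: int
    runtime_s: float = 0.0
    meta: dict = field(default_factory=dict)


def confusion(y_true, y_pred) -> np.ndarray:
    """Row-normalized 13 x 13 confusion matrix in canonical mode order."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for lab in np.unique(np.concatenate([y_true, y_pred])):
        if lab not in MODE_CODES:
            raise ValueError(f"unseen label {lab!r}")
    idx = {c: i for i, c in enumerate(MODE_CODES)}
    M = np.zeros((len(MODE_CODES), len(MODE_CODES)))
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    sums = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(sums > 0, M / np.where(sums > 0, sums, 1.0), 0.0)
    return out


def _stratified_trial_split(
    primary_modes: np.ndarray,
    train_frac: float,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices into train/test, stratified by primary mode.

    Default: sample ceil(train_frac * n_c) trials per mode without
    replacement; the rest are held out.  With ``with_replacement`` the
    training multiset is drawn with replacement and the held-out set is
    every trial never drawn.
    """
    train, test = [], []
    for mode in np.unique(primary_modes):
        members = np.flatnonzero(primary_modes == mode)
        n_train = max(1, int(round(train_frac * members.size)))
        if not with_replacement:
            n_train = min(n_train, members.size - 1) if members.size > 1 else 1
            chosen = rng.choice(members, n_train, replace=False)
        else:
            chosen = rng.choice(members, n_train, replace=True)
        train.append(chosen)
        test.append(np.setdiff1d(members, chosen))
    return np.concatenate(train), np.concatenate(test)


def _fit_eval_once(
    fm: FeatureMatrix,
    trial_ids: np.ndarray,
    primary_modes: np.ndarray,
    variant: str,
    seed: int,
    rng: np.random.Generator,
    train_frac: float,
    with_replacement: bool,
    classifier_factory=None,
    pipeline_params: dict | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One stratified trial-level split, fit and held-out evaluation."""
    y = fm.y
    for _ in range(20):
        tr, te = _stratified_trial_split(
            primary_modes, train_frac, rng, with_replacement
        )
        tr_mask = np.isin(trial_ids, tr)
        te_mask = np.isin(trial_ids, te)
        if te_mask.sum() == 0:
            continue
        if set(np.unique(y[te_mask])) <= set(np.unique(y[tr_mask])):
            break
        import warnings

        warnings.warn("training split missed a class; resampling", stacklevel=2)
    if te_mask.sum() == 0:
        raise ValueError(
            "cannot form a non-empty held-out split; the evaluation "
            "protocol needs at least 2 trials per mode"
        )
    X_tr, y_tr = fm.values[tr_mask], y[tr_mask]
    X_te, y_te = fm.values[te_mask], y[te_mask]
    if classifier_factory is not None:
        clf = classifier_factory(X_tr, y_tr, seed)
    else:
        clf = IntentPipeline(variant=variant, seed=seed, **(pipeline_params or {}))
        clf.fit(X_tr, y_tr)
    y_pred = clf.predict(X_te)
    acc = float(np.mean(y_pred == y_te))
    return acc, y_te, y_pred


def bootstrap_evaluate(
    dataset: list[Recording],
    modality: str = "fusion",
    variant: str = "kpca_issa_svm",
    n_iter: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    with_replacement: bool = False,
    classifier_factory=None,
    **pipeline_params,
) -> EvalReport:
    """Trial-level stratified bootstrap evaluation.

    Per iteration: split trials 80/20 stratified by each trial's primary
    mode, train the full pipeline on the training portion only (no
    statistics from held-out windows touch any fitting step) and score the
    held-out windows.  Reports the median accuracy and the nonparametric
    95% CI from the 2.5th/97.5th accuracy percentiles, plus the pooled
    confusion matrix over all iterations.
    """
    t0 = time.perf_counter()
    fm, trial_ids = dataset_features(dataset, modality=modality)
    primary_modes = np.array(
        [rec.meta.get("primary_mode", rec.window_labels[0].code) for rec in dataset]
    )
    counts = {}
    for lab in fm.y:
        counts[lab] = counts.get(lab, 0) + 1
    if min(counts.values()) < 2:
        raise ValueError("every mode needs at least 2 windows")

    ss = np.random.SeedSequence(seed)
    accs = []
    all_true, all_pred = [], []
    for it, child in enumerate(ss.spawn(n_iter)):
        rng = np.random.default_rng(child)
        it_seed = int(child.generate_state(1)[0] % (2**31))
        acc, y_te, y_pred = _fit_eval_once(
            fm, trial_ids, primary_modes, variant, it_seed, rng,
            train_frac, with_replacement, classifier_factory, pipeline_params,
        )
        accs.append(acc)
        all_true.append(y_te)
        all_pred.append(y_pred)

    accs = np.asarray(accs)
    y_true = np.concatenate(all_true)
    y_pred = np.concatenate(all_pred)
    per_mode = {}
    for code in MODE_CODES:
        mask = y_true == code
        if mask.any():
            per_mode[code] = float(np.mean(y_pred[mask] == code))
    overall = float(np.mean(y_pred == y_true))
    return EvalReport(
        accuracies=accs,
        median_accuracy=float(np.median(accs)),
        ci_low=float(np.percentile(accs, 2.5)),
        ci_high=float(np.percentile(accs, 97.5)),
        per_mode_accuracy=per_mode,
        overall_accuracy=overall,
        confusion_matrix=confusion(y_true, y_pred),
        n_iterations=n_iter,
        runtime_s=time.perf_counter() - t0,
        meta={"modality": modality, "variant": variant, "seed": seed},
    )


def snr_sweep(
    dataset: list[Recording],
    snr_list=(None, 10.0, 5.0, 0.0),
    modality: str = "fusion",
    variant: str = "kpca_issa_svm",
    train_frac: float = 0.8,
    seed: int = 0,
    **pipeline_params,
) -> dict:
    """Noise-robustness protocol: train on clean signals, test under AWGN.

    One stratified trial split; the pipeline is trained once on clean
    training trials, then the held-out trials are corrupted at each SNR
    (``None`` = no injection) and re-scored.  Returns {snr: accuracy}.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    primary_modes = np.array(
        [rec.meta.get("primary_mode", rec.window_labels[0].code) for rec in dataset]
    )
    tr, te = _stratified_trial_split(primary_modes, train_frac, rng)
    train_set = [dataset[i] for i in tr]
    test_set = [dataset[i] for i in te]
    pipe = train_pipeline(
        train_set, modality=modality, variant=variant, seed=seed, **pipeline_params
    )
    out = {}
    for k, snr in enumerate(snr_list):
        noisy = [
            inject_awgn(rec, snr, seed=seed + 7919 * (k + 1) + 31 * i)
            for i, rec in enumerate(test_set)
        ]
        fm, _ = dataset_features(noisy, modality=modality)
        out[snr] = float(np.mean(pipe.predict(fm.values) == fm.y))
    return out


def modality_ablation(
    dataset: list[Recording],
    variant: str = "kpca_issa_svm",
    n_iter: int = 10,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Identical bootstrap protocol per modality; returns median accuracies."""
    out = {}
    for modality in ("semg", "imu", "fusion"):
        rep = bootstrap_evaluate(
            dataset, modality=modality, variant=variant, n_iter=n_iter,
            seed=seed, **kwargs,
        )
        out[modality] = rep.median_accuracy
    return out


def stream_predict(
    pipe: IntentPipeline, stream: Recording, modality: str | None = None
) -> tuple[list[str], list[float]]:
    """Per-window streaming prediction over a recording.

    The stream is conditioned with the same zero-phase filters as training
    (forward-backward filtering is applied per acquisition buffer — here the
    recording), then windows are featurized and classified strictly in
    arrival order, one at a time.  Returns (labels, per-window inference
    latencies in seconds).  Output labels equal batch prediction on the
    same recording.
    """
    check_is_fitted(pipe, "svm_")
    modality = modality or getattr(pipe, "modality_", "fusion")
    ws_semg, ws_imu = preprocess_recording(stream)
    labels, latencies = [], []
    for w in range(ws_semg.n_windows):
        t0 = time.perf_counter()
        one_semg = _single_window(ws_semg, w)
        one_imu = _single_window(ws_imu, w)
        fm = extract_features(one_semg, one_imu, modality=modality)
        labels.append(str(pipe.predict(fm.values)[0]))
        latencies.append(time.perf_counter() - t0)
    return labels, latencies


def _single_window(ws, w):
    from .preprocess import WindowSet

    return WindowSet(
        windows=ws.windows[:, w : w + 1],
        fs=ws.fs,
        window_ms=ws.window_ms,
        taper=ws.taper,
        labels=None,
    )
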