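"""Decoding kernel-PCA factor scores from ERP activity.

The converse of encoding: ridge regression predicts each word's score on
the kernel-PCA components of the embedding space from its ERP, either
from the full sensors x timepoints pattern inside the N400 window or per
timepoint with only the sensor vector as features.  Window scores get
Bonferroni-style simultaneous bootstrap CIs (level 1 - alpha/k across
folds); time-resolved scores get uncorrected 68% CIs for display.
Decoder coefficients can be exported per electrode, either z-scored or
mapped to activation patterns (covariance times weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    DEFAULT_PENALTY,
    DEFAULT_WINDOW_MS,
    ERPDataset,
    FoldScheme,
    _signed_r2_items,
    ridge_solve,
    standardize_train,
)
from .spaces import ComponentScores
from .stats import bonferroni_level, bootstrap_ci_rows

__all__ = [
    "WindowFeatures",
    "DecodingResult",
    "DecoderPatterns",
    "extract_window_features",
    "decode_components_cv",
    "decode_timecourse",
    "fit_window_decoder",
    "decoder_patterns",
]

DEFAULT_CI_ALPHA = 0.05
TIMECOURSE_CI_LEVEL = 0.68


@dataclass
class WindowFeatures:
    """Flattened sensors x in-window timepoints per item, sensor-major."""

    matrix: np.ndarray  # items x (sensors * window_timepoints)
    sensor_labels: list[str]
    window_times_ms: np.ndarray

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_labels)

    @property
    def n_window_times(self) -> int:
        return self.window_times_ms.size

    def unflatten(self) -> np.ndarray:
        """Restore the items x sensors x window_timepoints sub-array."""
        n = self.matrix.shape[0]
        return self.matrix.reshape(n, self.n_sensors, self.n_window_times)


@dataclass
class DecodingResult:
    """Window and/or time-resolved decoding scores with their CIs."""

    window_scores: np.ndarray | None = None  # folds x components
    component_ci: np.ndarray | None = None  # components x 2
    ci_level: float | None = None
    significant: np.ndarray | None = None  # CI excludes 0, per component
    time_scores: np.ndarray | None = None  # folds x components x timepoints
    time_ci: np.ndarray | None = None  # components x timepoints x 2
    time_ci_level: float | None = None
    time_ms: np.ndarray | None = None
    folds: FoldScheme | None = None

    @property
    def mean_window_scores(self) -> np.ndarray:
        return self.window_scores.mean(axis=0)

    @property
    def mean_time_scores(self) -> np.ndarray:
        return self.time_scores.mean(axis=0)


def extract_window_features(
    erp: ERPDataset, t0_ms: float = DEFAULT_WINDOW_MS[0],
    t1_ms: float = DEFAULT_WINDOW_MS[1],
) -> WindowFeatures:
    """Per-item feature vectors from the ERP window (inclusive endpoints).

    Sensor-major flattening: feature ``s * n_window_times + t`` is sensor
    ``s`` at in-window timepoint ``t``.
    """
    mask = erp.window_mask(t0_ms, t1_ms)
    sub = erp.data[:, :, mask]
    return WindowFeatures(
        matrix=sub.reshape(erp.n_items, -1),
        sensor_labels=list(erp.sensor_labels),
        window_times_ms=erp.times_ms[mask],
    )


def _fit_predict_folds(
    features: np.ndarray, targets: np.ndarray, folds: FoldScheme, penalty: float
) -> np.ndarray:
    """Held-out ridge predictions of every target column, fold by fold.

    Features are standardized per training fold; targets are standardized
    per component on the training fold (correlation scoring is invariant
    to this, but it keeps one penalty meaningful across components).
    """
    preds = np.zeros_like(targets)
    for fold in range(folds.n_folds):
        train, test = folds.split(fold)
        if train.size < 2:
            raise ValueError(f"fold {fold} leaves fewer than 2 training items")
        Xs, _, _ = standardize_train(features, train)
        tm = targets[train].mean(axis=0)
        ts = targets[train].std(axis=0)
        ts = np.where(ts == 0.0, 1.0, ts)
        Yc = (targets[train] - tm) / ts
        n_tr, p = train.size, features.shape[1]
        if p <= n_tr:
            W = ridge_solve(Xs[train], Yc, penalty)
            pred = Xs[test] @ W
        else:
            # dual (kernel) form — identical predictions, cheaper when p > n
            from scipy.linalg import cho_factor, cho_solve

            K = Xs @ Xs.T
            A = cho_solve(
                cho_factor(K[np.ix_(train, train)] + penalty * np.eye(n_tr)), Yc
            )
            pred = K[np.ix_(test, train)] @ A
        preds[test] = pred * ts + tm
    return preds


def decode_components_cv(
    features: np.ndarray,
    targets: ComponentScores,
    folds: FoldScheme,
    penalty: float = DEFAULT_PENALTY,
    ci_level: float | None = None,
    n_boot: int = 10_000,
    ci_seed: int | None = None,
) -> DecodingResult:
    """Window decoding: one signed-r^2 per fold and component.

    ``ci_level`` defaults to the Bonferroni-adjusted 1 - 0.05/k across the
    k components (0.99375 at k = 8); a component is flagged significant
    when its fold-bootstrap CI excludes 0.
    """
    features = np.asarray(features, dtype=float)
    n, k = targets.scores.shape
    if features.shape[0] != n:
        raise ValueError(
            f"features rows ({features.shape[0]}) != target items ({n})"
        )
    if folds.n_items != n:
        raise ValueError("fold scheme does not match item count")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    if ci_level is None:
        ci_level = bonferroni_level(DEFAULT_CI_ALPHA, k)

    preds = _fit_predict_folds(features, targets.scores, folds, penalty)
    window_scores = np.zeros((folds.n_folds, k))
    for fold in range(folds.n_folds):
        _, test = folds.split(fold)
        window_scores[fold] = _signed_r2_items(preds[test], targets.scores[test])

    if ci_seed is None:
        ci_seed = folds.seed + 2
    ci = bootstrap_ci_rows(window_scores, ci_level, n_boot, ci_seed)
    significant = (ci[:, 0] > 0) | (ci[:, 1] < 0)
    return DecodingResult(
        window_scores=window_scores,
        component_ci=ci,
        ci_level=ci_level,
        significant=significant,
        folds=folds,
    )


def decode_timecourse(
    erp: ERPDataset,
    targets: ComponentScores,
    folds: FoldScheme,
    penalty: float = DEFAULT_PENALTY,
    ci_level: float = TIMECOURSE_CI_LEVEL,
    n_boot: int = 2_000,
    ci_seed: int | None = None,
) -> DecodingResult:
    """Time-resolved decoding: the same fit per timepoint, sensors as features.

    CIs are uncorrected (68% by default) — display-oriented, per the
    convention for time-course shading.
    """
    n, k = targets.scores.shape
    if erp.n_items != n:
        raise ValueError("ERP items do not match target items")
    if folds.n_items != n:
        raise ValueError("fold scheme does not match item count")
    T = erp.n_times
    time_scores = np.zeros((folds.n_folds, k, T))
    for t in range(T):
        preds = _fit_predict_folds(erp.data[:, :, t], targets.scores, folds, penalty)
        for fold in range(folds.n_folds):
            _, test = folds.split(fold)
            time_scores[fold, :, t] = _signed_r2_items(
                preds[test], targets.scores[test]
            )
    if ci_seed is None:
        ci_seed = folds.seed + 3
    time_ci = np.zeros((k, T, 2))
    for c in range(k):
        time_ci[c] = bootstrap_ci_rows(time_scores[:, c, :], ci_level, n_boot, ci_seed)
    return DecodingResult(
        time_scores=time_scores,
        time_ci=time_ci,
        time_ci_level=ci_level,
        time_ms=erp.times_ms,
        folds=folds,
    )


def fit_window_decoder(
    erp: ERPDataset,
    targets: ComponentScores,
    t0_ms: float = DEFAULT_WINDOW_MS[0],
    t1_ms: float = DEFAULT_WINDOW_MS[1],
    penalty: float = DEFAULT_PENALTY,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-electrode decoder refit on all items, for pattern export.

    Features are the window-averaged amplitude per electrode (one value
    per sensor), so the coefficients live on the sensor montage.  Returns
    ``(coefficients sensors x k, standardized feature matrix)``.  Display
    only — never used for scoring.
    """
    mask = erp.window_mask(t0_ms, t1_ms)
    X = erp.data[:, :, mask].mean(axis=2)
    all_items = np.arange(erp.n_items)
    Xs, _, _ = standardize_train(X, all_items)
    tm = targets.scores.mean(axis=0)
    ts = targets.scores.std(axis=0)
    ts = np.where(ts == 0.0, 1.0, ts)
    Yc = (targets.scores - tm) / ts
    W = ridge_solve(Xs, Yc, penalty)
    return W, Xs


@dataclass
class DecoderPatterns:
    """Per-component electrode values derived from decoder coefficients."""

    values: np.ndarray  # sensors x components
    mode: str
    sensor_labels: list[str]


def decoder_patterns(
    coefficients: np.ndarray,
    features: np.ndarray,
    mode: str = "zscore",
    sensor_labels: list[str] | None = None,
) -> DecoderPatterns:
    """Electrode-wise visualization values from a per-electrode decoder.

    ``zscore`` standardizes the raw backward weights across electrodes.
    ``haufe`` first converts weights to an activation (forward) pattern by
    multiplying with the feature covariance — the pattern of activity that
    covaries with the decoded component — then standardizes.  The two
    answer different questions (where the decoder reads vs. where the
    signal expresses), so both are shipped.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if mode not in ("zscore", "haufe"):
        raise ValueError(f"unknown pattern mode {mode!r}")
    if mode == "haufe":
        X = np.asarray(features, dtype=float)
        cov = np.cov(X, rowvar=False)
        values = cov @ coefficients
    else:
        values = coefficients.copy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    values = (values - mean) / sd
    if sensor_labels is None:
        sensor_labels = [f"E{i+1:03d}" for i in range(values.shape[0])]
    return DecoderPatterns(values=values, mode=mode, sensor_labels=sensor_labels)
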